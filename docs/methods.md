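# Methods

## The scientific problem

Under natural viewing, the visual stream is parsed into events and
event-segments. The question addressed by this pipeline is whether the
first stage of the multi-store memory hierarchy — sensory memory (SM),
a high-capacity store that decays within a few hundred milliseconds —
buffers the whole recent stream (a *Shared* allocation, which requires
tagging each stored item with its segment) or only the current event
segment (an *Exclusive* allocation, which needs no tags). The two
architectures agree about the current segment and disagree about the
previous one, so a bilinear-trajectory MOT paradigm with synchronized
mid-course deviations, probed with partial- vs full-report direction
judgements, can separate them.

## Stimulus model

Each of N ∈ {1..4} disks follows two equal-length straight segments
joined at a deviation vertex. Deviation magnitudes are uniform on a
configurable range (default 30–180°), signs equiprobable. Two
conventions relate the sampled magnitude to the motion-direction
change: `direction_change` (post = pre + deviation; the simulation
default) and `interior_angle` (direction change = 180° − magnitude;
used by the control analyses, for which a 30–180° range implies a mean
inter-segment direction difference of 75°). The two conventions are
both exposed because the deviation statistics and the direction-change
statistics cannot both have mean 105° under a single convention; all
analyses state which one they use.

Constraints are enforced by rejection sampling of whole direction sets
and whole start-point sets (preserving exchangeability): all 2N motion
directions pairwise ≥ 20° apart (circular), paths plus disk radius
inside the display, start points separated by more than one disk
diameter. Sampling is vectorised; infeasible constraint sets raise
after a configurable attempt budget (default 10,000 per requested
set) rather than silently clipping. Note one interaction: under the
`interior_angle` convention the 20° rule truncates deviation
magnitudes to ≤ 160°, because a disk's own pre- and post-directions
are 180° − magnitude apart. The 1,000 ms static pre-motion period and
rendering attributes are carried as metadata only.

Display defaults (22.5 × 17°, 800 × 600 px, 39.5 × 29.5 cm at 100 cm,
100 Hz) give a mean pixel subtense of 1.694 arcmin, computed by exact
arctangent.

## Experiment presets

Four within-subject designs, each crossing its stimulus conditions
with the four reporting conditions (pre/post-deviation × single/full
report), 10 blocks of 40 trials per condition level, randomly
interleaved within block and with level-blocks in random order:

| preset | levels | trials |
| --- | --- | --- |
| exp1a | durations 200/400/800/1200 ms at 5°/s | 1600 |
| exp1b | same durations at constant 4° length | 1600 |
| exp2 | post-cue delays 0/100/200/400/800/1600 ms (800 ms stimulus) | 2400 |
| exp3 | set sizes 1–4 (5°/s, 800 ms) | 1600 |

The report cue arrives at motion offset (plus the block's extra delay
in exp2). Because the pre-deviation segment ends half a stimulus
duration before offset, its effective cue delay is duration/2 — in
exp1b this yields pre-deviation delays of 100–600 ms, which is how
that design probes pre-deviation decay.

## Observer model

The generative observer is deliberately the minimal standard
psychophysics machinery that realises the qualitative predictions of
the two architectures; the architectures themselves are qualitative,
so no parameter is fitted to any empirical curve.

* **SM**: each item's trace survives an exponential lifetime with time
  constant `sm_tau_ms`, so it is retrievable at effective delay t with
  probability exp(−t/τ). Under `exclusive`, SM holds only
  post-deviation directions; under `shared`, both segments' (each
  clocked from its segment's end).
* **STM**: `stm_capacity` (K) items per segment, chosen uniformly at
  segment end; no within-trial decay (durability).
* **Report**: a retrieved item is reported as its true direction plus
  wrapped-Gaussian noise (`sm_sigma_deg` from SM, `stm_sigma_deg` from
  STM); an unretrieved item, and a `lapse_rate` fraction of all
  reports, is answered uniformly on the circle. Wrapped Gaussian is
  used rather than von Mises for direct RMS control; at these
  concentrations the difference is immaterial.
* **Full-report timing**: successive responses are separated by
  `inter_report_latency_ms`, so the k-th report probes SM at
  cue_delay + (k−1)·latency. The latency is a free parameter of the
  artifact (nothing in the paradigm pins it); it controls how strongly
  FR2–FR4 degrade.
* **Report order**: default policy `memory_first` — items still in SM
  at cue time first, then STM items, then the rest, ties at random.
  This is what strategic observers do when free to choose their order,
  and it is load-bearing: with a uniform order, pre-deviation SR and
  FR1 would be identically distributed under the exclusive
  architecture, erasing the observed SR ≠ FR1 difference for the
  previous segment. A `uniform` policy is selectable.
* **Degenerate controls**: `overwriting` always reports the
  post-deviation direction (+SM noise); `guessing` reports uniformly.

Defaults: `sm_sigma=15°`, `sm_tau=700 ms`, `K=2`, `stm_sigma=35°`,
`inter_report_latency=1500 ms`, `lapse=0.02`. Cohorts (default 4
observers, matching the behavioural sample sizes) apply multiplicative
log-normal jitter (default 10%) to the noise SDs and τ to induce
between-subject variance.

What the generator does *not* emulate: signal-strength growth with
stimulus duration (exp1a's duration effect), motion streaks/masking,
eye movements, attention, spatial confusions between disks, and
response biases. Passing tests therefore show that the analysis
battery recovers the generating architecture under this error model at
behavioural scale — not that any particular human dataset would
classify the same way.

## Scoring

δ = reported − true wrapped to (−180°, 180°] (the boundary maps to
+180 so |δ| ≤ 180); TP = 1 − |δ|/180. Cell means are arithmetic means
per (observer × condition × segment × scope), with FR1..FR4 order
breakdowns; the overall FR mean over all FR reports equals the
per-order mean in the balanced designs. Empty expected cells are
flagged and excluded with a warning, never imputed.

**RMS↔TP equivalence.** For each of 21 RMS levels (default evenly
spaced 1–90°), 1000 zero-mean Gaussian errors with σ = level are
drawn; the empirical RMS and the mean TP of the *same* sample are
recorded, and the Pearson correlation is computed between those two
columns. TP is applied to the raw draws by default (`tail="linear"`),
which preserves the exact linear mapping E[TP] = 1 − σ√(2/π)/180 and
reproduces the reference triple (0.995 at 1°, ≈0.60 at 90°,
r ≈ −0.9999); `wrap` and `clip` tail policies are available. Using the
empirical rather than nominal RMS as the correlate is what cancels the
shared Monte-Carlo noise and yields |r| ≈ 0.9999 at n = 1000 per
level.

## Signature battery

All tests run on subject-level cell means at α = 0.05, with no
correction across the battery (each signature is a separate a-priori
hypothesis; this mirrors standard practice for this battery and is a
documented limitation).

1. **Decay.** Where the design varies a segment's cue delay across
   conditions, the signature is decided by the focused one-sided
   linear-trend contrast (per-subject slope of SR TP on delay, t-test
   against zero), the appropriate test for a directional decay
   hypothesis; the omnibus RM-ANOVA delay effect is computed and
   reported alongside. Where the delay is constant by design (e.g. the
   post-deviation segment of exp1b), decay is probed across the
   within-trial inter-report delay: FR1 vs FR2, one-sided paired t.
   This order probe is capacity-neutral provided the durable store
   holds at least two items (true of the default K = 2; with K < 2 a
   capacity effect would masquerade as decay — a known limitation).
2. **SR > FR.** Report-scope main effect of a two-way RM-ANOVA
   (scope × condition; paired t when only one condition), requiring
   the means to be ordered SR > FR.
3. **SR = FR1.** Two-sided paired t on subject means; the signature is
   *non-rejection*, as conventional for this comparison — weak
   evidence by construction, so the raw mean difference is always
   reported next to it. Because equality is vacuous when nothing is
   recalled, the signature additionally requires SR performance to
   exceed chance (one-sided t vs TP = 0.5).

RM-ANOVA arithmetic is delegated to pingouin; a factor with more than
two levels is checked with Mauchly's test and Greenhouse-Geisser
corrected when sphericity is rejected (2-level factors are never
corrected; with as many levels as subjects the sphericity test is
undefined and the uncorrected p is used). A hand-computed
sums-of-squares fixture and the paired-t² identity guard the wrapper
in the test suite, and a null simulation confirms ≈5% type-I rate.

**Verdict.** A segment "shows SM" when a majority (≥2 of 3) of its
signatures are present. No SM evidence post-deviation →
`indeterminate`; SM in both segments → `shared`; SM post-deviation
only → `exclusive`. The majority rule (rather than all-or-none) keeps
the verdict robust to single α-level errors among the three tests;
with the defaults above, 100-replicate recovery runs classify
exclusive- and shared-generated cohorts correctly in ≥95% of
replicates and guessing cohorts as indeterminate.

One emergent subtlety: under the `shared` architecture with strategic
report ordering, pre-deviation FR1 slightly exceeds SR at long delays
(FR1 is the observer's best available item, SR is an externally chosen
one), so signature (iii) can fail pre-deviation even for shared data;
the majority rule absorbs this. The analogous effect post-deviation at
long cue delays reproduces the known breakdown of SR = FR1 there.

## Control analyses

* **Overwriting ceiling.** If pre-deviation queries were answered with
  post-deviation directions, expected TP = 1 − E[direction
  difference]/180. With interior-angle deviations uniform on 30–180°:
  E[diff] = 75°, ceiling 0.583. The Monte-Carlo companion simulates
  the overwriting reporter through each preset's constraint-truncated
  deviation distribution (the 20° rule lowers per-condition means to
  ≈0.53) and asserts the ≤-ceiling property; optional report noise
  strictly lowers TP.
* **Integration correlation.** Per observer, the least-squares slope
  and Pearson r of |post-deviation SR error| against the inter-segment
  angle (default selection: shortest-duration constant-length
  condition, 100 trials/observer). A full averager has slope 0.5 and
  strongly positive r; segmented processing predicts r ≈ 0. The
  summary is the mean of r² (the helper reproduces the 0.06 reference
  value from the four published coefficients).

## Numerical and interface choices

Angles in degrees everywhere (never serialized in radians); wrapped
differences in (−180°, 180°] with +180 at the boundary. A single seed
fans out via `numpy.random.SeedSequence.spawn` (one child per
observer). Trial logs are tidy UTF-8 CSV with a `#`-stamped schema
version; floats at 6 decimals; reading validates ranges and names the
offending column and row. The log carries one column beyond the core
schema (`inter_segment_angle_deg`) because the integration control
needs the angle between a disk's two segments, which is not otherwise
recoverable from a report row.

Problem sizes used by the shipped checks (chosen to estimate each
quantity well past its tolerance): 10³ stimulus sets for geometric
invariants, 10⁴ deviation samples for the uniformity test, 2×10⁵
draws for the chance level, the protocol's own 21 × 1000 trials for
the RMS↔TP table, 100 replicate cohorts per architecture (plus 60
guessing cohorts) for model recovery, 300–400 null replicates for
ANOVA calibration.

## Known limitations

* The architectures are qualitative; the chosen functional forms
  (exponential availability, fixed-K STM, wrapped-Gaussian noise) are
  one minimal realisation, and parameter defaults are illustrative,
  not estimates.
* SR = FR1 by non-rejection cannot affirm equality; it is reported
  with effect sizes and should be read as absence of evidence of a
  difference.
* The FR1-vs-FR2 decay probe conflates decay with capacity if the
  durable store holds fewer than two items.
* No multiple-testing correction across the battery.
* Human-data features not in the generator (see above) mean verdicts
  on real logs depend on assumptions the synthetic tests cannot check.
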