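"""Generative observer models for direction-report data.

The behavioural question is how a high-capacity but rapidly decaying
sensory store (SM) and a durable but capacity-limited short-term store
(STM) are allocated to the two segments of a bilinear-trajectory event.
The competing architectures differ only in which segment's directions
SM may hold:

``exclusive``
    SM holds only the current (post-deviation) segment's directions.
``shared``
    SM holds both segments' directions (decay clocked from the end of
    each segment).
``overwriting``
    Degenerate control: always reports the post-deviation direction,
    even when queried about the pre-deviation segment.
``guessing``
    Degenerate control: reports a uniform random direction.

The underlying memory machinery is the minimal standard psychophysics
mixture model. Each item's SM trace survives for an exponentially
distributed lifetime (time constant ``sm_tau_ms``), so the probability
that it is still retrievable at an effective delay t is exp(-t / tau).
STM stores ``stm_capacity`` items per segment, chosen at random at
segment end, and does not decay within a trial. A retrieved report is
the true direction plus wrapped-Gaussian noise (``sm_sigma_deg`` or
``stm_sigma_deg``); an unretrieved item is answered with a uniform
guess, as is a small ``lapse_rate`` fraction of all reports. In full
report, successive responses are separated by
``inter_report_latency_ms``, so later reports probe SM at longer
effective delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._angles import wrap_deg
from .design import TrialSpec, preset_config, build_experiment
from .geometry import DisplaySpec

__all__ = [
    "ObserverParams",
    "ARCHITECTURES",
    "simulate_responses",
    "report_order_policy",
    "make_cohort",
    "simulate_cohort",
    "LOG_COLUMNS",
]

ARCHITECTURES = ("exclusive", "shared", "overwriting", "guessing")

#: Column order of the tidy trial-log produced by the simulators.
LOG_COLUMNS = [
    "observer", "experiment", "stimulus_condition", "block", "trial",
    "segment", "scope", "set_size", "duration_ms", "cue_delay_ms",
    "disk_id", "report_order", "true_dir_deg", "reported_dir_deg",
    "error_deg", "tp", "inter_segment_angle_deg",
]


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one synthetic observer.

    Defaults realise the qualitative SM/STM signature pattern at the
    scale of the behavioural experiments; they are not fits to any
    empirical curve.
    """

    architecture: str = "exclusive"
    sm_sigma_deg: float = 15.0
    sm_tau_ms: float = 700.0
    stm_capacity: int = 2
    stm_sigma_deg: float = 35.0
    inter_report_latency_ms: float = 1500.0
    lapse_rate: float = 0.02
    report_policy: str = "memory_first"  # or "uniform"
    observer_id: str = "obs0"
    seed: int | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.sm_sigma_deg < 0 or self.stm_sigma_deg < 0:
            raise ValueError("report-noise SDs must be >= 0")
        if self.sm_tau_ms <= 0:
            raise ValueError("sm_tau_ms must be positive")
        if self.stm_capacity < 0 or int(self.stm_capacity) != self.stm_capacity:
            raise ValueError("stm_capacity must be a non-negative integer")
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.report_policy not in ("memory_first", "uniform"):
            raise ValueError(f"unknown report policy {self.report_policy!r}")


def report_order_policy(
    trial: TrialSpec,
    params: ObserverParams,
    rng: np.random.Generator,
    sm_available: np.ndarray | None = None,
    stm_stored: np.ndarray | None = None,
) -> np.ndarray:
    """Order in which a full-report observer reports the queried disks.

    With the ``uniform`` policy (or when no memory state is supplied)
    the order is a uniform random permutation. With ``memory_first``
    the observer reports items still available in SM first, then items
    held in STM, then the rest, breaking ties at random.
    """
    queried = np.asarray(trial.queried_disks)
    n = len(queried)
    tie = rng.random(n)
    if params.report_policy == "uniform" or (
        sm_available is None and stm_stored is None
    ):
        return queried[np.argsort(tie)]
    sm = np.zeros(n, bool) if sm_available is None else np.asarray(sm_available)[:n]
    stm = np.zeros(n, bool) if stm_stored is None else np.asarray(stm_stored)[:n]
    key = -2.0 * sm - 1.0 * stm + tie
    return queried[np.argsort(key)]


def _trials_to_arrays(trials: list[TrialSpec]):
    """Flatten a schedule into padded per-trial arrays (max 4 disks)."""
    nt = len(trials)
    max_n = max(t.set_size for t in trials)
    pre = np.zeros((nt, max_n))
    post = np.zeros((nt, max_n))
    meta = {
        "stimulus_condition": np.empty(nt, object),
        "block": np.empty(nt, int),
        "trial": np.empty(nt, int),
        "segment": np.empty(nt, object),
        "scope": np.empty(nt, object),
        "set_size": np.empty(nt, int),
        "duration_ms": np.empty(nt, float),
        "cue_delay_ms": np.empty(nt, float),
    }
    sr_target = np.full(nt, -1, int)
    for i, t in enumerate(trials):
        n = t.set_size
        pre[i, :n] = t.stimulus.pre_directions
        post[i, :n] = t.stimulus.post_directions
        meta["stimulus_condition"][i] = t.stimulus_condition
        meta["block"][i] = t.block_index
        meta["trial"][i] = t.trial_index
        meta["segment"][i] = t.report_condition.segment
        meta["scope"][i] = t.report_condition.scope
        meta["set_size"][i] = n
        meta["duration_ms"][i] = t.stimulus.trajectories[0].duration_ms
        meta["cue_delay_ms"][i] = t.cue_delay_ms
        if t.report_condition.scope == "single_report":
            if len(t.queried_disks) != 1:
                raise ValueError("single-report trial must query exactly one disk")
            sr_target[i] = t.queried_disks[0]
        elif len(t.queried_disks) != n:
            raise ValueError("full-report trial must query all disks")
    return pre, post, meta, sr_target, max_n


def simulate_responses(
    trials: list[TrialSpec],
    params: ObserverParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one observer's reports for a trial schedule.

    Returns a tidy DataFrame with one row per report (see
    :data:`LOG_COLUMNS`). Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if not trials:
        return pd.DataFrame(columns=LOG_COLUMNS)
    experiment = trials[0].experiment_id
    pre, post, meta, sr_target, max_n = _trials_to_arrays(trials)
    nt = len(trials)
    n_disks = meta["set_size"]
    is_post = meta["segment"] == "post_deviation"
    is_fr = meta["scope"] == "full_report"
    cue_delay = meta["cue_delay_ms"]
    valid = np.arange(max_n)[None, :] < n_disks[:, None]  # (nt, max_n)

    arch = params.architecture
    # latent memory state, per trial x disk
    lifetimes = rng.exponential(params.sm_tau_ms, size=(nt, max_n))
    sm_eligible = np.broadcast_to(
        (is_post | (arch == "shared"))[:, None], (nt, max_n)
    ) & (arch in ("exclusive", "shared"))
    # STM: `stm_capacity` items per segment, chosen uniformly at segment end
    stm_rank = np.argsort(rng.random((nt, max_n)) + np.where(valid, 0.0, 10.0), axis=1)
    stm_stored = np.zeros((nt, max_n), bool)
    if arch in ("exclusive", "shared") and params.stm_capacity > 0:
        stored_cols = stm_rank[:, : params.stm_capacity]
        np.put_along_axis(
            stm_stored, stored_cols, True, axis=1
        )
        stm_stored &= valid

    # report order
    order = np.zeros((nt, max_n), int)  # order[i, j] = disk reported j-th
    tie = rng.random((nt, max_n)) + np.where(valid, 0.0, 10.0)
    sm_at_cue = sm_eligible & (lifetimes > cue_delay[:, None])
    if params.report_policy == "memory_first":
        key = -2.0 * sm_at_cue - 1.0 * stm_stored + tie
    else:
        key = tie
    order_fr = np.argsort(key, axis=1)
    order[is_fr] = order_fr[is_fr]
    order[~is_fr, 0] = sr_target[~is_fr]

    # flatten to report rows
    n_reports_per_trial = np.where(is_fr, n_disks, 1)
    trial_idx = np.repeat(np.arange(nt), n_reports_per_trial)
    rank = np.concatenate([np.arange(k) for k in n_reports_per_trial])
    disk = order[trial_idx, rank]
    report_order = rank + 1

    t_eff = cue_delay[trial_idx] + rank * params.inter_report_latency_ms
    true_dir = np.where(is_post[trial_idx], post[trial_idx, disk], pre[trial_idx, disk])

    n_rows = len(trial_idx)
    reported = rng.uniform(0.0, 360.0, n_rows)  # default: uniform guess
    if arch in ("exclusive", "shared"):
        in_sm = sm_eligible[trial_idx, disk] & (lifetimes[trial_idx, disk] > t_eff)
        in_stm = stm_stored[trial_idx, disk]
        noise_sm = rng.normal(0.0, params.sm_sigma_deg, n_rows)
        noise_stm = rng.normal(0.0, params.stm_sigma_deg, n_rows)
        reported = np.where(
            in_sm, true_dir + noise_sm,
            np.where(in_stm, true_dir + noise_stm, reported),
        )
    elif arch == "overwriting":
        # always reproduces the post-deviation direction
        reported = post[trial_idx, disk] + rng.normal(0.0, params.sm_sigma_deg, n_rows)
    # guessing: keep the uniform draw
    if params.lapse_rate > 0:
        lapse = rng.random(n_rows) < params.lapse_rate
        reported = np.where(lapse, rng.uniform(0.0, 360.0, n_rows), reported)
    reported = np.mod(reported, 360.0)

    error = wrap_deg(reported - true_dir)
    seg_angle = np.abs(wrap_deg(post[trial_idx, disk] - pre[trial_idx, disk]))

    return pd.DataFrame(
        {
            "observer": params.observer_id,
            "experiment": experiment,
            "stimulus_condition": meta["stimulus_condition"][trial_idx],
            "block": meta["block"][trial_idx],
            "trial": meta["trial"][trial_idx],
            "segment": meta["segment"][trial_idx],
            "scope": meta["scope"][trial_idx],
            "set_size": n_disks[trial_idx],
            "duration_ms": meta["duration_ms"][trial_idx],
            "cue_delay_ms": cue_delay[trial_idx],
            "disk_id": disk,
            "report_order": report_order,
            "true_dir_deg": true_dir,
            "reported_dir_deg": reported,
            "error_deg": error,
            "tp": 1.0 - np.abs(error) / 180.0,
            "inter_segment_angle_deg": seg_angle,
        }
    )[LOG_COLUMNS]


def make_cohort(
    n_observers: int,
    params_template: ObserverParams | None = None,
    jitter: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list[ObserverParams]:
    """Create a cohort of observers with between-subject parameter jitter.

    Noise SDs and the SM time constant receive multiplicative
    log-normal jitter with the given coefficient (0 disables it); each
    observer gets an independent seed drawn from ``rng``.
    """
    if n_observers < 2:
        warnings.warn("cohorts of fewer than 2 observers cannot enter RM-ANOVA")
    params_template = params_template or ObserverParams()
    rng = rng or np.random.default_rng()
    cohort = []
    for i in range(n_observers):
        factors = np.exp(rng.normal(0.0, jitter, 3)) if jitter > 0 else np.ones(3)
        cohort.append(
            replace(
                params_template,
                sm_sigma_deg=params_template.sm_sigma_deg * factors[0],
                stm_sigma_deg=params_template.stm_sigma_deg * factors[1],
                sm_tau_ms=params_template.sm_tau_ms * factors[2],
                observer_id=f"obs{i}",
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return cohort


def simulate_cohort(
    preset: str,
    cohort: list[ObserverParams],
    seed: int | None = None,
    deviation_convention: str = "direction_change",
    display: DisplaySpec | None = None,
) -> pd.DataFrame:
    """Build per-observer schedules for a preset and simulate the cohort.

    Each observer receives an independently randomised schedule (block
    order, interleaving and stimuli differ between observers), as in a
    within-subject behavioural session.
    """
    ss = np.random.SeedSequence(seed)
    config = preset_config(preset, deviation_convention=deviation_convention)
    logs = []
    for params, child in zip(cohort, ss.spawn(len(cohort))):
        rng = np.random.default_rng(child)
        trials = build_experiment(config, rng, display=display)
        logs.append(simulate_responses(trials, params, rng))
    return pd.concat(logs, ignore_index=True)
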