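"""Statistical battery for the sensory-memory signatures.

Three classic hallmarks distinguish retrieval from a fast-decaying,
high-capacity sensory store (SM) from retrieval out of durable but
capacity-limited short-term memory (STM):

(i)   performance decays as the report cue is delayed;
(ii)  single-report (partial-report) performance exceeds full-report
      performance, TP_SR > TP_FR;
(iii) single-report performance matches the first full-report
      response, TP_SR = TP_FR1.

The battery evaluates all three per event segment (pre- vs
post-deviation) with repeated-measures ANOVA (Mauchly sphericity check
and Greenhouse-Geisser correction where a factor has more than two
levels) or paired t-tests where a factor is two-level. The resulting
signature matrix is compared against the predictions of the two
candidate architectures: the Shared model (SM holds both segments:
signatures in both) and the Exclusive model (SM holds only the
current segment: signatures post-deviation only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "SegmentSignatures",
    "SignatureMatrix",
    "ModelVerdict",
    "rm_anova",
    "signature_battery",
    "classify_model",
]

SEGMENTS = ("pre_deviation", "post_deviation")


@dataclass(frozen=True)
class AnovaResult:
    """One effect from a repeated-measures ANOVA."""

    effect: str
    df_num: float
    df_den: float
    F: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None
    mauchly_p: float | None = None
    corrected: bool = False


def _check_balanced(data: pd.DataFrame, dv: str, within: list[str], subject: str):
    counts = data.groupby([subject] + within, observed=True)[dv].size()
    full = counts.index.to_frame(index=False)
    subjects = data[subject].unique()
    levels = [data[w].unique() for w in within]
    expect = len(subjects) * int(np.prod([len(lv) for lv in levels]))
    if len(counts) != expect or counts.nunique() != 1:
        # name one offending cell for the error message
        grid = pd.MultiIndex.from_product([subjects] + levels, names=[subject] + within)
        present = pd.MultiIndex.from_frame(full)
        missing = grid.difference(present)
        if len(missing):
            raise ValueError(f"unbalanced design: no observation for cell {missing[0]}")
        sizes = counts[counts != counts.iloc[0]]
        raise ValueError(
            f"unbalanced design: cell {sizes.index[0]} has {sizes.iloc[0]} observations"
        )


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    alpha_sphericity: float = 0.05,
) -> list[AnovaResult]:
    """Repeated-measures ANOVA (one or two within factors).

    The decomposition itself is delegated to pingouin. For any factor
    with more than two levels, Mauchly's test is run; when it rejects
    at ``alpha_sphericity`` the Greenhouse-Geisser correction is
    applied to that effect's degrees of freedom and p-value. Partial
    eta-squared is SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    within_list = [within] if isinstance(within, str) else list(within)
    if len(within_list) not in (1, 2):
        raise ValueError("rm_anova supports one or two within factors")
    if data[subject].nunique() < 2:
        raise ValueError("need at least two subjects")
    _check_balanced(data, dv, within_list, subject)
    # collapse replicates within subject x cell to cell means
    cellmeans = (
        data.groupby([subject] + within_list, observed=True)[dv].mean().reset_index()
    )

    table = pg.rm_anova(
        data=cellmeans, dv=dv, within=within_list if len(within_list) > 1 else within_list[0],
        subject=subject, correction=True, detailed=True, effsize="np2",
    )

    def _mauchly(factor: str) -> float:
        if cellmeans[factor].nunique() <= 2:
            return np.nan
        collapsed = cellmeans.groupby([subject, factor], observed=True)[dv].mean().reset_index()
        try:
            res = pg.sphericity(data=collapsed, dv=dv, subject=subject, within=factor)
            return float(res.pval)
        except Exception:
            return np.nan

    mauchly = {f: _mauchly(f) for f in within_list}
    results = []
    for _, row in table.iterrows():
        effect = str(row["Source"])
        if effect.lower() == "error":
            continue
        df1 = float(row.get("ddof1", row.get("DF", np.nan)))
        df2 = float(row.get("ddof2", (cellmeans[subject].nunique() - 1) * df1))
        eps = float(row["eps"]) if "eps" in row and np.isfinite(row.get("eps", np.nan)) else None
        factors = [f for f in within_list if f in effect.split(" * ")] or (
            [effect] if effect in within_list else []
        )
        n_levels = int(np.prod([cellmeans[f].nunique() for f in factors])) if factors else 2
        m_p = np.nan
        if len(factors) == 1:
            m_p = mauchly[factors[0]]
        corrected = bool(
            eps is not None
            and n_levels > 2
            and np.isfinite(m_p)
            and m_p < alpha_sphericity
        )
        if corrected:
            p = float(row["p-GG-corr"]) if "p-GG-corr" in row else float(row["p_GG_corr"])
            df1c, df2c = eps * df1, eps * df2
        else:
            p = float(row["p-unc"]) if "p-unc" in row else float(row["p_unc"])
            df1c, df2c = df1, df2
        results.append(
            AnovaResult(
                effect=effect,
                df_num=df1c,
                df_den=df2c,
                F=float(row["F"]),
                p=p,
                partial_eta_sq=float(row["np2"]),
                gg_epsilon=eps if corrected else (eps if n_levels > 2 else None),
                mauchly_p=None if not np.isfinite(m_p) else m_p,
                corrected=corrected,
            )
        )
    return results


# ---------------------------------------------------------------------------
# the signature battery


@dataclass(frozen=True)
class SegmentSignatures:
    decay_with_delay: bool
    sr_gt_fr: bool
    sr_eq_fr1: bool

    def as_tuple(self):
        return (self.decay_with_delay, self.sr_gt_fr, self.sr_eq_fr1)


@dataclass
class SignatureMatrix:
    """Per-segment presence of the three SM signatures."""

    segments: dict[str, SegmentSignatures]
    alpha: float
    tests: pd.DataFrame  # tidy record of every statistic computed

    def __getitem__(self, segment: str) -> SegmentSignatures:
        return self.segments[segment]


@dataclass
class ModelVerdict:
    verdict: str  # "exclusive" | "shared" | "indeterminate"
    agreement: pd.DataFrame  # per cell: observed vs each model's prediction


def _subject_means(log: pd.DataFrame, segment: str) -> pd.DataFrame:
    sub = log[log["segment"] == segment]
    if sub.empty:
        raise ValueError(f"response log has no {segment} reports")
    return sub


def _paired_t(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"):
    res = stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue), float(len(x) - 1)


def signature_battery(
    log: pd.DataFrame, alpha: float = 0.05
) -> SignatureMatrix:
    """Run the three SM tests for both segments of one experiment's log.

    Decay (i) is tested on single-report TP across stimulus conditions
    whenever the segment's cue delay varies between conditions: the
    focused one-sided linear-trend contrast (per-subject slope of TP
    on delay tested against zero) decides the signature, with the
    omnibus delay main effect recorded alongside. When the design
    holds the segment's cue delay constant, the within-trial effective
    delay is probed instead: the first versus second full-report
    response (one-sided), which is capacity-neutral as long as the
    durable store holds at least two items. SR > FR (ii) uses the
    report-scope main effect of a two-way RM-ANOVA (scope x condition)
    and requires the means to be ordered SR > FR. SR = FR1 (iii) is
    declared present on *non-rejection* of a paired two-sided test, as
    is conventional for this signature; the raw mean difference is
    recorded alongside. Because equality is vacuously non-rejected
    when nothing is recalled, signature (iii) additionally requires
    single-report performance to exceed chance (TP > 0.5, one-sided).
    """
    if log.empty:
        raise ValueError("empty response log")
    required_scopes = {"single_report", "full_report"}
    rows = []
    sigs: dict[str, SegmentSignatures] = {}
    for segment in SEGMENTS:
        sub = _subject_means(log, segment)
        missing = required_scopes - set(sub["scope"].unique())
        if missing:
            raise ValueError(f"{segment}: missing report scopes {sorted(missing)}")

        # --- decay
        delays = sub.groupby("stimulus_condition", observed=True)["cue_delay_ms"].first()
        sr = sub[sub["scope"] == "single_report"]
        if delays.nunique() > 1:
            cell = (
                sr.groupby(["observer", "stimulus_condition"], observed=True)["tp"]
                .mean().reset_index()
            )
            # focused test: per-subject linear trend of TP on cue delay,
            # one-sided for decay (negative slope)
            cell["delay"] = delays[cell["stimulus_condition"]].to_numpy()
            slopes = (
                cell.groupby("observer", observed=True)
                .apply(lambda g: np.polyfit(g["delay"], g["tp"], 1)[0],
                       include_groups=False)
                .to_numpy()
            )
            tres = stats.ttest_1samp(slopes, 0.0, alternative="less")
            decay = bool(tres.pvalue < alpha)
            rows.append(
                dict(comparison="decay_with_delay", segment=segment,
                     test="trend_t(slope < 0)", df1=float(len(slopes) - 1), df2=np.nan,
                     statistic=float(tres.statistic), p=float(tres.pvalue),
                     partial_eta_sq=np.nan, gg_epsilon=np.nan, mauchly_p=np.nan,
                     effect_direction=float(slopes.mean()), significant=decay)
            )
            # omnibus cue-delay main effect, recorded alongside
            res = rm_anova(cell, "tp", "stimulus_condition", "observer")[0]
            rows.append(
                dict(comparison="decay_omnibus", segment=segment,
                     test="rm_anova(cue delay factor)", df1=res.df_num, df2=res.df_den,
                     statistic=res.F, p=res.p, partial_eta_sq=res.partial_eta_sq,
                     gg_epsilon=res.gg_epsilon, mauchly_p=res.mauchly_p,
                     effect_direction=float(slopes.mean()), significant=res.p < alpha)
            )
        else:
            fr = sub[(sub["scope"] == "full_report") & (sub["set_size"] >= 2)]
            if fr.empty:
                raise ValueError(f"{segment}: no full-report data with set size >= 2")
            om = (
                fr[fr["report_order"].isin([1, 2])]
                .pivot_table(index="observer", columns="report_order", values="tp")
            )
            t, p, df = _paired_t(om[1].to_numpy(), om[2].to_numpy(), "greater")
            decay = bool(p < alpha)
            rows.append(
                dict(comparison="decay_with_delay", segment=segment,
                     test="paired_t(FR1 > FR2)", df1=df, df2=np.nan, statistic=t,
                     p=p, partial_eta_sq=np.nan, gg_epsilon=np.nan, mauchly_p=np.nan,
                     effect_direction=float(om[2].mean() - om[1].mean()),
                     significant=p < alpha)
            )

        # --- SR > FR
        cell = (
            sub.groupby(["observer", "stimulus_condition", "scope"], observed=True)["tp"]
            .mean().reset_index()
        )
        sr_mean = cell.loc[cell["scope"] == "single_report", "tp"].mean()
        fr_mean = cell.loc[cell["scope"] == "full_report", "tp"].mean()
        if cell["stimulus_condition"].nunique() > 1:
            res = rm_anova(cell, "tp", ["scope", "stimulus_condition"], "observer")
            scope_res = next(r for r in res if r.effect == "scope")
            p_scope, stat, df1, df2 = scope_res.p, scope_res.F, scope_res.df_num, scope_res.df_den
            test_name, eta = "rm_anova(scope x condition)", scope_res.partial_eta_sq
        else:
            piv = cell.pivot_table(index="observer", columns="scope", values="tp")
            t, p_scope, df1 = _paired_t(
                piv["single_report"].to_numpy(), piv["full_report"].to_numpy()
            )
            stat, df2, test_name, eta = t, np.nan, "paired_t(SR vs FR)", np.nan
        sr_gt_fr = bool(p_scope < alpha and sr_mean > fr_mean)
        rows.append(
            dict(comparison="sr_gt_fr", segment=segment, test=test_name,
                 df1=df1, df2=df2, statistic=stat, p=p_scope,
                 partial_eta_sq=eta, gg_epsilon=np.nan, mauchly_p=np.nan,
                 effect_direction=float(sr_mean - fr_mean), significant=p_scope < alpha)
        )

        # --- SR = FR1 (presence = non-rejection)
        sr_subj = (
            sub[sub["scope"] == "single_report"]
            .groupby("observer", observed=True)["tp"].mean()
        )
        fr1_subj = (
            sub[(sub["scope"] == "full_report") & (sub["report_order"] == 1)]
            .groupby("observer", observed=True)["tp"].mean()
        )
        joined = pd.concat([sr_subj.rename("sr"), fr1_subj.rename("fr1")], axis=1).dropna()
        t, p, df = _paired_t(joined["sr"].to_numpy(), joined["fr1"].to_numpy())
        # equality is vacuous at chance level: require SR above chance
        res_chance = stats.ttest_1samp(joined["sr"].to_numpy(), 0.5, alternative="greater")
        above_chance = bool(res_chance.pvalue < alpha)
        sr_eq_fr1 = bool(p >= alpha and above_chance)
        rows.append(
            dict(comparison="sr_above_chance", segment=segment,
                 test="one_sample_t(SR > 0.5)", df1=float(len(joined) - 1), df2=np.nan,
                 statistic=float(res_chance.statistic), p=float(res_chance.pvalue),
                 partial_eta_sq=np.nan, gg_epsilon=np.nan, mauchly_p=np.nan,
                 effect_direction=float(joined["sr"].mean() - 0.5),
                 significant=above_chance)
        )
        rows.append(
            dict(comparison="sr_eq_fr1", segment=segment, test="paired_t(SR vs FR1)",
                 df1=df, df2=np.nan, statistic=t, p=p, partial_eta_sq=np.nan,
                 gg_epsilon=np.nan, mauchly_p=np.nan,
                 effect_direction=float((joined["sr"] - joined["fr1"]).mean()),
                 significant=p < alpha)
        )

        sigs[segment] = SegmentSignatures(
            decay_with_delay=decay, sr_gt_fr=sr_gt_fr, sr_eq_fr1=sr_eq_fr1
        )
    return SignatureMatrix(segments=sigs, alpha=alpha, tests=pd.DataFrame(rows))


#: Figure-style prediction templates: does each model predict the
#: signature in each segment?
MODEL_TEMPLATES = {
    "shared": {"pre_deviation": (True, True, True), "post_deviation": (True, True, True)},
    "exclusive": {"pre_deviation": (False, False, False), "post_deviation": (True, True, True)},
}


def classify_model(matrix: SignatureMatrix) -> ModelVerdict:
    """Adjudicate between the Shared and Exclusive architectures.

    A segment counts as showing SM involvement when a majority (at
    least two of three) of its signatures are present. No SM evidence
    in the current (post-deviation) segment leaves the data
    ``indeterminate``; otherwise the pre-deviation segment decides:
    SM involvement there as well means ``shared``, its absence means
    ``exclusive``.
    """
    names = ["decay_with_delay", "sr_gt_fr", "sr_eq_fr1"]
    obs = {seg: matrix[seg].as_tuple() for seg in SEGMENTS}
    post_present = sum(obs["post_deviation"]) >= 2
    pre_present = sum(obs["pre_deviation"]) >= 2
    if not post_present:
        verdict = "indeterminate"
    elif pre_present:
        verdict = "shared"
    else:
        verdict = "exclusive"
    rows = []
    for seg in SEGMENTS:
        for i, name in enumerate(names):
            rows.append(
                dict(
                    segment=seg,
                    signature=name,
                    observed=obs[seg][i],
                    shared_predicts=MODEL_TEMPLATES["shared"][seg][i],
                    exclusive_predicts=MODEL_TEMPLATES["exclusive"][seg][i],
                    agrees_shared=obs[seg][i] == MODEL_TEMPLATES["shared"][seg][i],
                    agrees_exclusive=obs[seg][i] == MODEL_TEMPLATES["exclusive"][seg][i],
                )
            )
    return ModelVerdict(verdict=verdict, agreement=pd.DataFrame(rows))
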