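"""Transformed-performance (TP) scoring and aggregation.

The per-report error delta is the signed circular difference between
the reported and true directions, wrapped to (-180, 180]. It is mapped
to the probability-like score

    TP = 1 - |delta| / 180

so that 1.0 is a perfect report, 0.5 is chance (a report unrelated to
the true direction) and 0.0 is a maximally wrong report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._angles import wrap_deg

__all__ = [
    "circular_error",
    "tp",
    "ConditionSummary",
    "aggregate",
    "simulate_tp_at_rms",
    "rms_tp_equivalence",
]

DEFAULT_KEYS = ["observer", "experiment", "stimulus_condition", "segment", "scope"]


def circular_error(reported_deg, true_deg):
    """Signed report error delta = reported - true, wrapped to (-180, 180]."""
    reported = np.asarray(reported_deg, dtype=float)
    true = np.asarray(true_deg, dtype=float)
    if not (np.all(np.isfinite(reported)) and np.all(np.isfinite(true))):
        raise ValueError("angles must be finite")
    return wrap_deg(reported - true)


def tp(delta):
    """Transformed performance of a wrapped error delta (|delta| <= 180)."""
    d = np.abs(np.asarray(delta, dtype=float))
    if np.any(d > 180):
        raise ValueError("|delta| exceeds 180; wrap errors with circular_error first")
    out = 1.0 - d / 180.0
    if np.ndim(delta) == 0:
        return float(out)
    return out


@dataclass
class ConditionSummary:
    """Mean TP per design cell, with the full-report order breakdown.

    ``cells`` has one row per (group keys) cell with columns mean_tp
    and n_reports; ``fr_orders`` additionally splits full-report cells
    by report order (FR1..FR4). ``missing`` lists expected cells that
    had no reports.
    """

    cells: pd.DataFrame
    fr_orders: pd.DataFrame
    group_keys: list[str]
    missing: list[tuple] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.cells.assign(report_order="all").pipe(
            lambda c: pd.concat([c, self.fr_orders], ignore_index=True)
        ).to_csv(path, index=False)


def aggregate(
    log: pd.DataFrame,
    group_keys: list[str] | None = None,
    expected_cells: pd.DataFrame | None = None,
) -> ConditionSummary:
    """Average TP per design cell.

    The full-report cell mean is the mean over all FR reports, which
    in a balanced design equals the set-size-weighted mean of the
    per-order means. Expected cells with no reports are flagged as
    missing (with a warning), never imputed.
    """
    keys = list(group_keys or DEFAULT_KEYS)
    if log.empty:
        raise ValueError("cannot aggregate an empty response log")
    df = log.copy()
    if "tp" not in df.columns:
        df["tp"] = tp(circular_error(df["reported_dir_deg"], df["true_dir_deg"]))
    cells = (
        df.groupby(keys, observed=True, sort=True)["tp"]
        .agg(mean_tp="mean", n_reports="size")
        .reset_index()
    )
    fr = df[df["scope"] == "full_report"] if "scope" in df.columns else df
    fr_orders = (
        fr
        .groupby(keys + ["report_order"], observed=True, sort=True)["tp"]
        .agg(mean_tp="mean", n_reports="size")
        .reset_index()
    )
    missing: list[tuple] = []
    if expected_cells is not None:
        have = set(map(tuple, cells[keys].itertuples(index=False)))
        for row in map(tuple, expected_cells[keys].drop_duplicates().itertuples(index=False)):
            if row not in have:
                missing.append(row)
        if missing:
            warnings.warn(f"{len(missing)} expected cells have no reports: {missing[:5]}")
    return ConditionSummary(cells=cells, fr_orders=fr_orders, group_keys=keys, missing=missing)


# ---------------------------------------------------------------------------
# RMS <-> TP equivalence


def simulate_tp_at_rms(
    rms_deg: float,
    n_trials: int,
    rng: np.random.Generator,
    tail: str = "linear",
):
    """Simulate reports with zero-mean Gaussian error of the given RMS.

    Returns ``(errors, mean_tp)``. ``tail`` controls the rare draws
    beyond +-180 deg: ``linear`` keeps them (TP extrapolates linearly,
    preserving the exact linear RMS<->TP mapping), ``wrap`` folds them
    onto the circle, ``clip`` saturates them at +-180.
    """
    if not 0 < rms_deg:
        raise ValueError("rms_deg must be positive")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    x = rng.normal(0.0, rms_deg, n_trials)
    if tail == "wrap":
        x = wrap_deg(x)
    elif tail == "clip":
        x = np.clip(x, -180.0, 180.0)
    elif tail != "linear":
        raise ValueError(f"unknown tail policy {tail!r}")
    return x, float(np.mean(1.0 - np.abs(x) / 180.0))


def rms_tp_equivalence(
    rms_levels_deg=None,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    tail: str = "linear",
):
    """Table of simulated (RMS error, mean TP) pairs and their correlation.

    For each nominal RMS level, ``n_trials`` zero-mean Gaussian errors
    are drawn and both the empirical RMS and the mean TP of the *same*
    sample are recorded. The returned Pearson r correlates the
    empirical RMS with the mean TP, which is how near-perfect
    linearity between the two measures is established.

    Returns ``(table, r)`` where table has columns nominal_rms_deg,
    empirical_rms_deg, mean_tp.
    """
    if rms_levels_deg is None:
        rms_levels_deg = np.linspace(1.0, 90.0, 21)
    levels = np.asarray(rms_levels_deg, dtype=float)
    if np.any((levels <= 0) | (levels >= 180)):
        raise ValueError("RMS levels must lie in (0, 180)")
    rng = rng or np.random.default_rng()
    rows = []
    for level in levels:
        errors, mean_tp = simulate_tp_at_rms(level, n_trials, rng, tail=tail)
        rows.append((level, float(np.sqrt(np.mean(errors**2))), mean_tp))
    table = pd.DataFrame(rows, columns=["nominal_rms_deg", "empirical_rms_deg", "mean_tp"])
    r = float(stats.pearsonr(table["empirical_rms_deg"], table["mean_tp"]).statistic)
    return table, r
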