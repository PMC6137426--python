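"""Control analyses for the event-segmentation memory experiments.

Two alternative explanations of poor pre-deviation recall are examined
and bounded:

* **Overwriting** — the post-deviation direction systematically
  replaces the pre-deviation direction in memory. Because deviation
  magnitudes are drawn uniformly from 30-180 deg (interior angle), the
  expected inter-segment direction difference is 75 deg, so an
  observer who accurately reports the post-deviation direction when
  queried pre-deviation can score at best TP = 1 - 75/180 = 0.583.
* **Pre/post integration** — the two segments are blended rather than
  segmented, which would make the post-deviation report error track
  the inter-segment angle. The per-observer linear correlation between
  |post-deviation SR error| and the inter-segment angle quantifies
  this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._angles import wrap_deg
from .design import ExperimentConfig, preset_config
from .geometry import sample_direction_sets

__all__ = [
    "OverwritingBound",
    "IntegrationCorrelation",
    "overwriting_bound",
    "overwriting_simulation",
    "integration_correlation",
    "mean_r_squared",
]


@dataclass(frozen=True)
class OverwritingBound:
    """Analytic ceiling on TP for a pure overwriting reporter."""

    mean_deviation_deg: float
    mean_direction_diff_deg: float
    tp_bound: float
    convention: str


def overwriting_bound(
    deviation_range_deg: tuple[float, float] = (30.0, 180.0),
    convention: str = "interior_angle",
) -> OverwritingBound:
    """Expected TP of an observer reporting the post-deviation direction
    when queried about the pre-deviation direction.

    Deviation magnitudes are uniform on the given range. Under the
    ``interior_angle`` convention the inter-segment direction
    difference is 180 deg minus the deviation; under
    ``direction_change`` it is the deviation itself.
    """
    lo, hi = deviation_range_deg
    if not 0 <= lo <= hi <= 180:
        raise ValueError("deviation range must lie within [0, 180]")
    mean_dev = (lo + hi) / 2.0
    if convention == "interior_angle":
        mean_diff = 180.0 - mean_dev
    elif convention == "direction_change":
        mean_diff = mean_dev
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return OverwritingBound(
        mean_deviation_deg=mean_dev,
        mean_direction_diff_deg=mean_diff,
        tp_bound=1.0 - mean_diff / 180.0,
        convention=convention,
    )


def overwriting_simulation(
    configs: list[ExperimentConfig] | None = None,
    n_trials: int = 10_000,
    rng: np.random.Generator | None = None,
    sm_sigma_deg: float = 0.0,
    deviation_convention: str = "interior_angle",
) -> pd.DataFrame:
    """Monte-Carlo TP of the overwriting reporter across conditions.

    For every stimulus-condition level of every config, direction sets
    are sampled under that condition's constraints (so the direction-
    separation rule truncates the effective deviation distribution),
    the pre-deviation query is answered with the post-deviation
    direction plus optional report noise, and mean TP is recorded.

    Returns a tidy frame (experiment, stimulus_condition, mean_tp, n).
    """
    rng = rng or np.random.default_rng()
    if configs is None:
        configs = [
            preset_config(p, deviation_convention=deviation_convention)
            for p in ("exp1a", "exp1b", "exp2", "exp3")
        ]
    rows = []
    for config in configs:
        for level in config.levels:
            spec = level.stimulus
            n_sets = int(np.ceil(n_trials / spec.n_disks))
            pre, _dev, post = sample_direction_sets(spec, n_sets, rng)
            noise = rng.normal(0.0, sm_sigma_deg, pre.shape) if sm_sigma_deg > 0 else 0.0
            delta = wrap_deg(post + noise - pre)
            tp = 1.0 - np.abs(delta) / 180.0
            rows.append(
                dict(
                    experiment=config.preset,
                    stimulus_condition=level.label,
                    mean_tp=float(tp.mean()),
                    n=int(tp.size),
                )
            )
    return pd.DataFrame(rows)


@dataclass
class IntegrationCorrelation:
    """Per-observer error-vs-angle correlation and the mean r-squared."""

    per_observer: pd.DataFrame  # observer, r, slope, n
    mean_r_squared: float


def mean_r_squared(r_values) -> float:
    """Mean of the squared correlation coefficients."""
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("|r| cannot exceed 1")
    return float(np.mean(r**2))


def integration_correlation(
    log: pd.DataFrame,
    query: str = (
        "experiment == 'exp1b' and stimulus_condition == 'dur200' "
        "and segment == 'post_deviation' and scope == 'single_report'"
    ),
    min_reports: int = 10,
) -> IntegrationCorrelation:
    """Correlate |post-deviation report error| with the inter-segment angle.

    If the two segments were integrated rather than treated as
    separate events, the post-deviation report would be biased toward
    the pre-deviation direction and its absolute error would grow with
    the angle between the segments (a full averager has slope 0.5).
    Computed per observer on the selected condition; the summary is
    the mean of the squared correlation coefficients.
    """
    sel = log.query(query) if query else log
    if sel.empty:
        raise ValueError("condition selector matched no reports")
    rows = []
    for obs, grp in sel.groupby("observer", observed=True):
        if len(grp) < min_reports:
            raise ValueError(
                f"observer {obs!r} has only {len(grp)} qualifying reports "
                f"(minimum {min_reports})"
            )
        x = grp["inter_segment_angle_deg"].to_numpy(dtype=float)
        y = np.abs(grp["error_deg"].to_numpy(dtype=float))
        fit = stats.linregress(x, y)
        rows.append(dict(observer=obs, r=float(fit.rvalue), slope=float(fit.slope), n=len(grp)))
    per_observer = pd.DataFrame(rows)
    return IntegrationCorrelation(
        per_observer=per_observer,
        mean_r_squared=mean_r_squared(per_observer["r"]),
    )
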