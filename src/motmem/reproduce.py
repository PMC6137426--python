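"""Recompute the pipeline's reference control quantities.

These are the analytic and simulation-based control numbers that the
pipeline should reproduce from scratch: the overwriting TP ceiling and
its ingredients, chance- and perfect-performance levels, the RMS<->TP
equivalence simulation, pixel geometry and trial-count arithmetic.
Each entry reports the freshly computed value; the CLI ``reproduce``
command additionally compares against the expected reference value.
"""

from __future__ import annotations

import numpy as np

from .controls import overwriting_bound, mean_r_squared
from .design import preset_config
from .geometry import DisplaySpec, pixel_subtense
from .scoring import simulate_tp_at_rms, rms_tp_equivalence, tp

__all__ = ["REFERENCE_VALUES", "compute_reference_quantities"]

#: Expected values: analytic where a closed form exists, otherwise the
#: reference simulation outcome for this protocol, with comparison
#: tolerances.
REFERENCE_VALUES = {
    "mean_abs_deviation_deg": (105.0, 1.0),
    "mean_direction_diff_deg": (75.0, 1.0),
    "overwriting_tp_bound": (0.583, 0.001),
    "chance_tp": (0.5, 0.01),
    "perfect_tp": (1.0, 1e-12),
    "tp_at_rms_1deg": (0.995, 0.002),
    "tp_at_rms_90deg": (0.597, 0.02),
    "rms_tp_pearson_r": (-0.9999, 0.001),
    "mean_r_squared_integration": (0.06, 0.005),
    "exp1_trials": (1600, 0),
    "exp2_trials": (2400, 0),
    "pixel_subtense_arcmin": (1.694, 0.001),
}

#: Per-observer error-vs-angle correlations reported for the 200 ms
#: single-report integration control.
INTEGRATION_R_VALUES = (0.23, 0.09, 0.36, 0.24)


def compute_reference_quantities(seed: int = 0) -> dict[str, float]:
    """Recompute every reference quantity from the pipeline itself."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: dict[str, float] = {}

    bound = overwriting_bound((30.0, 180.0), "interior_angle")
    out["mean_abs_deviation_deg"] = bound.mean_deviation_deg
    out["mean_direction_diff_deg"] = bound.mean_direction_diff_deg
    out["overwriting_tp_bound"] = round(bound.tp_bound, 3)

    # chance: reports uniform on the circle, independent of the truth
    errors = rng.uniform(-180.0, 180.0, 200_000)
    out["chance_tp"] = float(np.mean(tp(errors)))
    out["perfect_tp"] = tp(0.0)

    _, tp1 = simulate_tp_at_rms(1.0, 1000, rng)
    _, tp90 = simulate_tp_at_rms(90.0, 1000, rng)
    out["tp_at_rms_1deg"] = round(tp1, 3)
    out["tp_at_rms_90deg"] = round(tp90, 3)
    _, r = rms_tp_equivalence(np.linspace(1.0, 90.0, 21), 1000, rng)
    out["rms_tp_pearson_r"] = round(r, 4)

    out["mean_r_squared_integration"] = round(mean_r_squared(INTEGRATION_R_VALUES), 2)
    out["exp1_trials"] = preset_config("exp1a").n_trials
    out["exp2_trials"] = preset_config("exp2").n_trials
    out["pixel_subtense_arcmin"] = round(pixel_subtense(DisplaySpec())[2], 3)
    return out
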