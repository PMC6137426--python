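"""Bilinear-trajectory stimulus geometry for MOT memory experiments.

A stimulus consists of N gray disks, each moving along a *bilinear*
trajectory: a straight segment, a single direction deviation at the
mid-point, then a second straight segment of equal length. Deviation
magnitudes are drawn uniformly from a configurable range (default
30-180 deg), clockwise or counter-clockwise with equal probability.
Two sampling constraints mirror the behavioural protocol:

* none of the 2N motion directions in a stimulus may lie within
  ``min_direction_sep_deg`` (default 20 deg) of one another, and
* the whole two-segment path of every disk, inflated by the disk
  radius, must stay inside the display.

Both constraints are enforced by rejection sampling of the entire
direction set / start-point set, which keeps accepted samples
exchangeable.

Two deviation conventions are supported. Under ``direction_change``
the sampled deviation is the change in the direction of motion
(post = pre + deviation). Under ``interior_angle`` the sampled value
is the interior angle between the two path segments, so the change in
the direction of motion is 180 deg minus the sampled magnitude. The
second convention makes a nominal 30-180 deg deviation range imply a
mean inter-segment direction difference of 75 deg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._angles import wrap_deg, pairwise_min_separation, unit_vector

__all__ = [
    "DisplaySpec",
    "StimulusSpec",
    "BilinearTrajectory",
    "StimulusSet",
    "InfeasibleGeometryError",
    "sample_direction_set",
    "sample_direction_sets",
    "post_direction_for",
    "sample_stimulus_set",
    "sample_stimulus_sets",
    "position_at",
    "frame_positions",
    "pixel_subtense",
]


class InfeasibleGeometryError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the stimulus constraints."""


@dataclass(frozen=True)
class DisplaySpec:
    """Physical display geometry.

    Defaults describe a 22.5 x 17 deg CRT viewed from 1 m: 39.5 cm
    (800 px) wide and 29.5 cm (600 px) high at 100 Hz.
    """

    width_deg: float = 22.5
    height_deg: float = 17.0
    width_px: int = 800
    height_px: int = 600
    width_cm: float = 39.5
    height_cm: float = 29.5
    viewing_distance_cm: float = 100.0
    frame_rate_hz: float = 100.0

    def __post_init__(self):
        for name in (
            "width_deg", "height_deg", "width_px", "height_px",
            "width_cm", "height_cm", "viewing_distance_cm", "frame_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"DisplaySpec.{name} must be positive")
        if int(self.width_px) != self.width_px or int(self.height_px) != self.height_px:
            raise ValueError("pixel counts must be integers")


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one stimulus condition.

    ``regime`` selects whether speed is held constant (path length =
    speed * duration) or the total trajectory length is held constant
    (speed = length / duration).
    """

    n_disks: int = 3
    disk_diameter_deg: float = 1.0
    speed_deg_per_s: float = 5.0
    duration_ms: float = 800.0
    regime: str = "constant_speed"
    trajectory_length_deg: float = 4.0
    deviation_range_deg: tuple[float, float] = (30.0, 180.0)
    min_direction_sep_deg: float = 20.0
    deviation_convention: str = "direction_change"
    static_period_ms: float = 1000.0  # pre-motion static viewing; metadata only

    def __post_init__(self):
        if not 1 <= self.n_disks <= 4:
            raise ValueError("n_disks must be in 1..4")
        lo, hi = self.deviation_range_deg
        if not (0 <= lo <= hi <= 180) or hi <= 0 and lo != 0:
            raise ValueError("deviation range must lie within [0, 180]")
        if self.min_direction_sep_deg < 0:
            raise ValueError("min_direction_sep_deg must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.regime not in ("constant_speed", "constant_length"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.deviation_convention not in ("direction_change", "interior_angle"):
            raise ValueError(f"unknown deviation convention {self.deviation_convention!r}")

    @property
    def path_length_deg(self) -> float:
        """Total path length of each trajectory in degrees."""
        if self.regime == "constant_length":
            return self.trajectory_length_deg
        return self.speed_deg_per_s * self.duration_ms / 1000.0

    @property
    def effective_speed_deg_per_s(self) -> float:
        if self.regime == "constant_length":
            return self.trajectory_length_deg / (self.duration_ms / 1000.0)
        return self.speed_deg_per_s


@dataclass(frozen=True)
class BilinearTrajectory:
    """One disk's motion: two straight segments joined at the vertex."""

    start_xy: tuple[float, float]
    pre_direction_deg: float
    deviation_deg: float
    post_direction_deg: float
    speed_deg_per_s: float
    duration_ms: float

    @property
    def vertex_xy(self) -> tuple[float, float]:
        half = self.speed_deg_per_s * self.duration_ms / 2000.0
        u = unit_vector(self.pre_direction_deg)
        return (self.start_xy[0] + half * u[0], self.start_xy[1] + half * u[1])

    @property
    def end_xy(self) -> tuple[float, float]:
        half = self.speed_deg_per_s * self.duration_ms / 2000.0
        vx, vy = self.vertex_xy
        u = unit_vector(self.post_direction_deg)
        return (vx + half * u[0], vy + half * u[1])


@dataclass(frozen=True)
class StimulusSet:
    """All trajectories of one trial plus the seed that produced them."""

    trajectories: tuple[BilinearTrajectory, ...]
    seed: int | None = None

    @property
    def n_disks(self) -> int:
        return len(self.trajectories)

    @property
    def pre_directions(self) -> np.ndarray:
        return np.array([t.pre_direction_deg for t in self.trajectories])

    @property
    def post_directions(self) -> np.ndarray:
        return np.array([t.post_direction_deg for t in self.trajectories])

    @property
    def deviations(self) -> np.ndarray:
        return np.array([t.deviation_deg for t in self.trajectories])

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "trajectories": [asdict(t) for t in self.trajectories]}
        )

    @classmethod
    def from_json(cls, s: str) -> "StimulusSet":
        d = json.loads(s)
        trajs = tuple(
            BilinearTrajectory(
                start_xy=tuple(t["start_xy"]),
                pre_direction_deg=t["pre_direction_deg"],
                deviation_deg=t["deviation_deg"],
                post_direction_deg=t["post_direction_deg"],
                speed_deg_per_s=t["speed_deg_per_s"],
                duration_ms=t["duration_ms"],
            )
            for t in d["trajectories"]
        )
        return cls(trajectories=trajs, seed=d.get("seed"))


# ---------------------------------------------------------------------------
# direction sampling


def post_direction_for(pre, deviation, convention):
    """Post-segment motion direction implied by a signed deviation."""
    if convention == "direction_change":
        change = deviation
    else:  # interior_angle: direction change is the supplement of the angle
        change = np.sign(deviation) * (180.0 - np.abs(deviation))
    return np.mod(pre + change, 360.0)


def sample_direction_sets(
    spec: StimulusSpec,
    n_sets: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
):
    """Vectorised rejection sampler for direction sets.

    Returns
    -------
    (pre, deviations, post) : arrays of shape (n_sets, n_disks)
        Pre-segment directions (uniform on the circle), signed
        deviations (magnitude uniform on the deviation range, sign
        equiprobable) and the implied post-segment directions.
    """
    n = spec.n_disks
    lo, hi = spec.deviation_range_deg
    out_pre = np.empty((n_sets, n))
    out_dev = np.empty((n_sets, n))
    out_post = np.empty((n_sets, n))
    filled = 0
    attempts = 0
    budget = max_attempts * max(n_sets, 1)
    batch = max(256, 2 * n_sets)
    while filled < n_sets:
        if attempts >= budget:
            raise InfeasibleGeometryError(
                f"direction-set sampling failed after {attempts} attempts; "
                "constraint set appears infeasible"
            )
        m = min(batch, budget - attempts)
        pre = rng.uniform(0.0, 360.0, size=(m, n))
        mag = rng.uniform(lo, hi, size=(m, n))
        sign = rng.choice([-1.0, 1.0], size=(m, n))
        dev = sign * mag
        post = post_direction_for(pre, dev, spec.deviation_convention)
        attempts += m
        if spec.min_direction_sep_deg > 0:
            dirs = np.concatenate([pre, post], axis=1)
            if n == 1:
                ok = pairwise_min_separation(dirs) >= spec.min_direction_sep_deg
            else:
                ok = pairwise_min_separation(dirs) >= spec.min_direction_sep_deg
            idx = np.nonzero(ok)[0]
        else:
            idx = np.arange(m)
        take = idx[: n_sets - filled]
        k = len(take)
        out_pre[filled : filled + k] = pre[take]
        out_dev[filled : filled + k] = dev[take]
        out_post[filled : filled + k] = post[take]
        filled += k
    return out_pre, out_dev, out_post


def sample_direction_set(
    spec: StimulusSpec, rng: np.random.Generator, max_attempts: int = 10_000
):
    """Sample one direction set; see :func:`sample_direction_sets`."""
    pre, dev, post = sample_direction_sets(spec, 1, rng, max_attempts=max_attempts)
    return pre[0], dev[0], post[0]


# ---------------------------------------------------------------------------
# start-point sampling and full stimulus sets


def _path_excursions(pre, post, length):
    """Bounding-box excursions of a bilinear path relative to its start.

    Returns (min_xy, max_xy), each of shape (..., 2).
    """
    half = length / 2.0
    d1 = half * unit_vector(pre)
    d2 = d1 + half * unit_vector(post)
    pts = np.stack([np.zeros_like(d1), d1, d2], axis=-2)  # (..., 3, 2)
    return pts.min(axis=-2), pts.max(axis=-2)


def sample_stimulus_sets(
    spec: StimulusSpec,
    display: DisplaySpec,
    n_sets: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
):
    """Sample full stimulus sets (directions + start points) as arrays.

    Start points are drawn uniformly from each trajectory's feasible
    rectangle (display minus disk radius minus the path's bounding
    box), rejecting sets whose start points are closer than one disk
    diameter. Coordinates are centred on the display.

    Returns (pre, dev, post, start_xy) with start_xy of shape
    (n_sets, n_disks, 2).
    """
    n = spec.n_disks
    length = spec.path_length_deg
    radius = spec.disk_diameter_deg / 2.0
    half_w = display.width_deg / 2.0 - radius
    half_h = display.height_deg / 2.0 - radius
    diag = np.hypot(display.width_deg - 2 * radius, display.height_deg - 2 * radius)
    if length > diag:
        raise InfeasibleGeometryError(
            f"path length {length:.2f} deg exceeds the usable display diagonal "
            f"{diag:.2f} deg"
        )

    out_pre = np.empty((n_sets, n))
    out_dev = np.empty((n_sets, n))
    out_post = np.empty((n_sets, n))
    out_start = np.empty((n_sets, n, 2))
    filled = 0
    attempts = 0
    budget = max_attempts * max(n_sets, 1)
    while filled < n_sets:
        if attempts >= budget:
            raise InfeasibleGeometryError(
                f"stimulus sampling failed after {attempts} attempts; "
                "paths do not fit the display under the given constraints"
            )
        m = min(max(256, 2 * (n_sets - filled)), budget - attempts)
        pre, dev, post = sample_direction_sets(spec, m, rng, max_attempts=max_attempts)
        mn, mx = _path_excursions(pre, post, length)  # (m, n, 2)
        lo_x = -half_w - mn[..., 0]
        hi_x = half_w - mx[..., 0]
        lo_y = -half_h - mn[..., 1]
        hi_y = half_h - mx[..., 1]
        feasible = (hi_x > lo_x) & (hi_y > lo_y)  # per disk
        ok = feasible.all(axis=1)
        sx = lo_x + rng.random((m, n)) * np.maximum(hi_x - lo_x, 0.0)
        sy = lo_y + rng.random((m, n)) * np.maximum(hi_y - lo_y, 0.0)
        start = np.stack([sx, sy], axis=-1)
        if n > 1:
            d = np.linalg.norm(start[:, :, None, :] - start[:, None, :, :], axis=-1)
            iu = np.triu_indices(n, 1)
            ok &= (d[:, iu[0], iu[1]] > spec.disk_diameter_deg).all(axis=1)
        attempts += m
        idx = np.nonzero(ok)[0][: n_sets - filled]
        k = len(idx)
        out_pre[filled : filled + k] = pre[idx]
        out_dev[filled : filled + k] = dev[idx]
        out_post[filled : filled + k] = post[idx]
        out_start[filled : filled + k] = start[idx]
        filled += k
    return out_pre, out_dev, out_post, out_start


def sample_stimulus_set(
    spec: StimulusSpec,
    display: DisplaySpec,
    rng: np.random.Generator,
    seed: int | None = None,
    max_attempts: int = 10_000,
) -> StimulusSet:
    """Sample one :class:`StimulusSet` satisfying all constraints."""
    pre, dev, post, start = sample_stimulus_sets(
        spec, display, 1, rng, max_attempts=max_attempts
    )
    speed = spec.effective_speed_deg_per_s
    trajs = tuple(
        BilinearTrajectory(
            start_xy=(float(start[0, i, 0]), float(start[0, i, 1])),
            pre_direction_deg=float(pre[0, i]),
            deviation_deg=float(dev[0, i]),
            post_direction_deg=float(post[0, i]),
            speed_deg_per_s=speed,
            duration_ms=spec.duration_ms,
        )
        for i in range(spec.n_disks)
    )
    return StimulusSet(trajectories=trajs, seed=seed)


# ---------------------------------------------------------------------------
# kinematics and display arithmetic


def position_at(traj: BilinearTrajectory, t_ms: float) -> tuple[float, float]:
    """Disk-centre position at time ``t_ms`` from motion onset.

    Piecewise linear and continuous at the vertex; raises for times
    outside [0, duration].
    """
    if not 0 <= t_ms <= traj.duration_ms:
        raise ValueError(f"t_ms={t_ms} outside [0, {traj.duration_ms}]")
    v = traj.speed_deg_per_s / 1000.0  # deg per ms
    half_t = traj.duration_ms / 2.0
    if t_ms <= half_t:
        u = unit_vector(traj.pre_direction_deg)
        return (traj.start_xy[0] + v * t_ms * u[0], traj.start_xy[1] + v * t_ms * u[1])
    vx, vy = traj.vertex_xy
    u = unit_vector(traj.post_direction_deg)
    dt = t_ms - half_t
    return (vx + v * dt * u[0], vy + v * dt * u[1])


def frame_positions(stim: StimulusSet, display: DisplaySpec) -> pd.DataFrame:
    """Tidy frame-by-frame positions at the display frame rate.

    Columns: disk, frame, t_ms, x_deg, y_deg.
    """
    dt = 1000.0 / display.frame_rate_hz
    rows = []
    for i, traj in enumerate(stim.trajectories):
        n_frames = int(round(traj.duration_ms / dt))
        for f in range(n_frames + 1):
            t = min(f * dt, traj.duration_ms)
            x, y = position_at(traj, t)
            rows.append((i, f, t, x, y))
    return pd.DataFrame(rows, columns=["disk", "frame", "t_ms", "x_deg", "y_deg"])


def pixel_subtense(display: DisplaySpec) -> tuple[float, float, float]:
    """Angular size of one screen pixel in minutes of arc.

    Returns (horizontal, vertical, mean). Uses the exact arctangent of
    the per-pixel physical size over the viewing distance.
    """
    if display.viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    per_px_w = display.width_cm / display.width_px
    per_px_h = display.height_cm / display.height_px
    to_arcmin = 60.0 * 180.0 / np.pi
    h = np.arctan2(per_px_w, display.viewing_distance_cm) * to_arcmin
    v = np.arctan2(per_px_h, display.viewing_distance_cm) * to_arcmin
    return float(h), float(v), float((h + v) / 2.0)
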