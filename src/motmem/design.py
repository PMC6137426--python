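"""Trial schedules for the four experiments.

Every experiment crosses a set of stimulus conditions (duration,
post-cue delay, or set size) with the four reporting conditions:
pre/post-deviation x single/full report. Each stimulus condition is
run in 10 blocks of 40 trials (10 per reporting condition, randomly
interleaved), and the level-blocks are presented in randomised order.

Presets
-------
exp1a
    Constant speed 5 deg/s; durations 200, 400, 800, 1200 ms; 3 disks.
exp1b
    Constant trajectory length 4 deg; same durations (speed co-varies).
exp2
    Fixed 800 ms duration; post-deviation cue delays 0, 100, 200, 400,
    800, 1600 ms (blocked); 3 disks.
exp3
    Set sizes 1-4; speed 5 deg/s; 800 ms.

The report cue always appears at the end of motion (plus the block's
extra post-deviation delay in exp2). For a pre-deviation query the
reportable segment ended half a stimulus-duration before motion
offset, so the effective pre-deviation cue delay is duration / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DisplaySpec, StimulusSpec, StimulusSet, BilinearTrajectory, sample_stimulus_sets

__all__ = [
    "ReportCondition",
    "TrialSpec",
    "ConditionLevel",
    "ExperimentConfig",
    "CueDescription",
    "REPORT_CONDITIONS",
    "preset_config",
    "build_experiment",
    "cue_for",
    "schedule_to_frame",
]


@dataclass(frozen=True)
class ReportCondition:
    """One of the four reporting conditions."""

    segment: str  # "pre_deviation" | "post_deviation"
    scope: str  # "single_report" | "full_report"

    def __post_init__(self):
        if self.segment not in ("pre_deviation", "post_deviation"):
            raise ValueError(f"unknown segment {self.segment!r}")
        if self.scope not in ("single_report", "full_report"):
            raise ValueError(f"unknown scope {self.scope!r}")

    @property
    def label(self) -> str:
        seg = "pre" if self.segment == "pre_deviation" else "post"
        sc = "SR" if self.scope == "single_report" else "FR"
        return f"{seg}-{sc}"


REPORT_CONDITIONS = (
    ReportCondition("pre_deviation", "single_report"),
    ReportCondition("post_deviation", "single_report"),
    ReportCondition("pre_deviation", "full_report"),
    ReportCondition("post_deviation", "full_report"),
)


@dataclass(frozen=True)
class ConditionLevel:
    """One stimulus-condition level (a parameter bundle)."""

    label: str
    stimulus: StimulusSpec
    post_cue_delay_ms: float = 0.0


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    experiment_id: str
    stimulus_condition: str
    block_index: int
    trial_index: int
    stimulus: StimulusSet
    report_condition: ReportCondition
    cue_delay_ms: float
    queried_disks: tuple[int, ...]

    @property
    def set_size(self) -> int:
        return self.stimulus.n_disks


@dataclass(frozen=True)
class CueDescription:
    """Which disks are marked for report, where, and in which colour."""

    marked_disks: tuple[int, ...]
    marker_color: str  # "blue" (pre-deviation) | "red" (post-deviation)
    disk_positions: tuple[tuple[float, float], ...]  # all disks, cue-time positions


@dataclass(frozen=True)
class ExperimentConfig:
    preset: str
    levels: tuple[ConditionLevel, ...]
    blocks_per_condition: int = 10
    trials_per_condition_per_block: int = 10

    @property
    def n_trials(self) -> int:
        return (
            len(self.levels)
            * self.blocks_per_condition
            * len(REPORT_CONDITIONS)
            * self.trials_per_condition_per_block
        )


def preset_config(
    preset: str,
    deviation_convention: str = "direction_change",
    min_direction_sep_deg: float = 20.0,
) -> ExperimentConfig:
    """Build the :class:`ExperimentConfig` for a named experiment."""
    common = dict(
        deviation_convention=deviation_convention,
        min_direction_sep_deg=min_direction_sep_deg,
    )
    if preset == "exp1a":
        levels = tuple(
            ConditionLevel(
                label=f"dur{d}",
                stimulus=StimulusSpec(
                    n_disks=3, speed_deg_per_s=5.0, duration_ms=d,
                    regime="constant_speed", **common,
                ),
            )
            for d in (200, 400, 800, 1200)
        )
    elif preset == "exp1b":
        levels = tuple(
            ConditionLevel(
                label=f"dur{d}",
                stimulus=StimulusSpec(
                    n_disks=3, duration_ms=d, regime="constant_length",
                    trajectory_length_deg=4.0, **common,
                ),
            )
            for d in (200, 400, 800, 1200)
        )
    elif preset == "exp2":
        levels = tuple(
            ConditionLevel(
                label=f"delay{c}",
                stimulus=StimulusSpec(
                    n_disks=3, speed_deg_per_s=5.0, duration_ms=800,
                    regime="constant_speed", **common,
                ),
                post_cue_delay_ms=float(c),
            )
            for c in (0, 100, 200, 400, 800, 1600)
        )
    elif preset == "exp3":
        levels = tuple(
            ConditionLevel(
                label=f"set{n}",
                stimulus=StimulusSpec(
                    n_disks=n, speed_deg_per_s=5.0, duration_ms=800,
                    regime="constant_speed", **common,
                ),
            )
            for n in (1, 2, 3, 4)
        )
    else:
        raise ValueError(f"unknown experiment preset {preset!r}")
    return ExperimentConfig(preset=preset, levels=levels)


def _cue_delay(level: ConditionLevel, condition: ReportCondition) -> float:
    """Effective cue delay for the queried segment.

    The cue follows motion offset by the block's post-deviation delay
    (0 outside exp2). The pre-deviation segment additionally ended
    duration/2 before motion offset.
    """
    if condition.segment == "post_deviation":
        return level.post_cue_delay_ms
    return level.stimulus.duration_ms / 2.0 + level.post_cue_delay_ms


def build_experiment(
    config: ExperimentConfig,
    rng: np.random.Generator,
    display: DisplaySpec | None = None,
) -> list[TrialSpec]:
    """Build the randomised trial schedule for one observer/session.

    Stimulus sets are sampled per trial (vectorised per level); block
    order across levels and trial order within blocks are shuffled.
    Deterministic given the generator state.
    """
    display = display or DisplaySpec()
    n_rc = len(REPORT_CONDITIONS)
    per_block = n_rc * config.trials_per_condition_per_block

    # stimulus arrays per level, sampled in one batch each
    level_stimuli = {}
    for level in config.levels:
        n_needed = config.blocks_per_condition * per_block
        pre, dev, post, start = sample_stimulus_sets(
            level.stimulus, display, n_needed, rng
        )
        level_stimuli[level.label] = (pre, dev, post, start)

    # randomised order of (level, block) pairs
    level_blocks = [
        (level, b)
        for level in config.levels
        for b in range(config.blocks_per_condition)
    ]
    rng.shuffle(level_blocks)

    trials: list[TrialSpec] = []
    used = {level.label: 0 for level in config.levels}
    for block_index, (level, _b) in enumerate(level_blocks):
        conditions = np.repeat(
            np.arange(n_rc), config.trials_per_condition_per_block
        )
        rng.shuffle(conditions)
        spec = level.stimulus
        speed = spec.effective_speed_deg_per_s
        pre, dev, post, start = level_stimuli[level.label]
        for trial_in_block, ci in enumerate(conditions):
            rc = REPORT_CONDITIONS[ci]
            k = used[level.label]
            used[level.label] += 1
            trajs = tuple(
                BilinearTrajectory(
                    start_xy=(float(start[k, i, 0]), float(start[k, i, 1])),
                    pre_direction_deg=float(pre[k, i]),
                    deviation_deg=float(dev[k, i]),
                    post_direction_deg=float(post[k, i]),
                    speed_deg_per_s=speed,
                    duration_ms=spec.duration_ms,
                )
                for i in range(spec.n_disks)
            )
            stim = StimulusSet(trajectories=trajs)
            if rc.scope == "single_report":
                queried = (int(rng.integers(spec.n_disks)),)
            else:
                queried = tuple(range(spec.n_disks))
            trials.append(
                TrialSpec(
                    experiment_id=config.preset,
                    stimulus_condition=level.label,
                    block_index=block_index,
                    trial_index=trial_in_block,
                    stimulus=stim,
                    report_condition=rc,
                    cue_delay_ms=_cue_delay(level, rc),
                    queried_disks=queried,
                )
            )
    return trials


def cue_for(trial: TrialSpec) -> CueDescription:
    """Cue rendering metadata for a trial.

    Pre-deviation cues: every disk jumps back to its deviation point
    (the vertex) and the queried disks are marked blue. Post-deviation
    cues: disks stay at their final positions and the queried disks
    turn red.
    """
    if trial.report_condition.segment == "pre_deviation":
        positions = tuple(t.vertex_xy for t in trial.stimulus.trajectories)
        color = "blue"
    else:
        positions = tuple(t.end_xy for t in trial.stimulus.trajectories)
        color = "red"
    return CueDescription(
        marked_disks=trial.queried_disks,
        marker_color=color,
        disk_positions=positions,
    )


def schedule_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """Tidy one-row-per-trial view of a schedule (no stimulus payload)."""
    rows = [
        dict(
            experiment=t.experiment_id,
            stimulus_condition=t.stimulus_condition,
            block=t.block_index,
            trial=t.trial_index,
            segment=t.report_condition.segment,
            scope=t.report_condition.scope,
            set_size=t.set_size,
            duration_ms=t.stimulus.trajectories[0].duration_ms,
            cue_delay_ms=t.cue_delay_ms,
            n_queried=len(t.queried_disks),
        )
        for t in trials
    ]
    return pd.DataFrame(rows)
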