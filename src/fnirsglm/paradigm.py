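"""Randomized block-design schedule generation and stimulus indicators.

The default design has four conditions — neuromuscular electrical
stimulation (NMES) paired with landscape observation (LO, the control),
action observation (AO), action execution (AE), or action imitation (AI) —
cycled eight times.  Every block is 35 s: a 15 s task phase tiled by five
3 s video trials, followed by 20 s of rest.  Within each cycle the four
conditions are presented in a uniformly random order, and the five clips of
a block are drawn without replacement from a ten-clip library of the
matching video type (action clips for AO/AE/AI, landscape clips for LO).
A 30 s lead-in and lead-out of rest bracket the run, giving a 1180 s
(~20 min) recording.

The NMES pulse-train envelope (1 s ramp up, 15 s hold, 1 s ramp down,
18 s interval) is carried as schedule metadata only: every condition
includes the stimulation, so it cancels from between-condition contrasts
and is not modelled hemodynamically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "CONTROL_CONDITION",
    "DesignConfig",
    "Block",
    "Schedule",
    "generate_schedule",
    "schedule_to_events",
    "write_events",
    "read_events",
    "condition_boxcars",
]

CONDITIONS: tuple[str, ...] = ("NMES+LO", "NMES+AO", "NMES+AE", "NMES+AI")
CONTROL_CONDITION = "NMES+LO"

#: conditions whose task phase shows action clips; the control shows landscapes
_ACTION_CONDITIONS = frozenset({"NMES+AO", "NMES+AE", "NMES+AI"})

#: NMES envelope metadata (seconds); informational only, see module docstring
NMES_ENVELOPE = {"ramp_up_s": 1.0, "hold_s": 15.0, "ramp_down_s": 1.0, "interval_s": 18.0}


class ParadigmConfigError(ValueError):
    """Design parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class DesignConfig:
    """Block-design parameters; defaults reproduce the study paradigm."""

    conditions: tuple[str, ...] = CONDITIONS
    n_cycles: int = 8
    task_s: float = 15.0
    rest_s: float = 20.0
    lead_in_s: float = 30.0
    lead_out_s: float = 30.0
    trials_per_block: int = 5
    trial_s: float = 3.0
    action_library_size: int = 10
    landscape_library_size: int = 10

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ParadigmConfigError("need at least 2 conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ParadigmConfigError("conditions must be unique")
        for name in ("task_s", "rest_s", "trial_s"):
            if getattr(self, name) <= 0:
                raise ParadigmConfigError(f"{name} must be > 0")
        if self.n_cycles < 1:
            raise ParadigmConfigError("n_cycles must be >= 1")
        if min(self.action_library_size, self.landscape_library_size) < self.trials_per_block:
            raise ParadigmConfigError(
                "video library smaller than trials_per_block: cannot draw "
                f"{self.trials_per_block} distinct clips"
            )


@dataclass(frozen=True)
class Block:
    """One task+rest epoch of a single condition."""

    condition: str
    onset: float  # s from recording start (task phase begins here)
    task_duration: float
    rest_duration: float
    trials: tuple[tuple[int, float, float], ...]  # (clip_id, onset s, duration s)

    @property
    def duration(self) -> float:
        return self.task_duration + self.rest_duration

    @property
    def task_end(self) -> float:
        return self.onset + self.task_duration


@dataclass(frozen=True)
class Schedule:
    """The full randomized timeline of one recording run."""

    blocks: tuple[Block, ...]
    lead_in: float
    lead_out: float
    n_cycles: int
    seed: int
    config: DesignConfig = field(default_factory=DesignConfig)

    @property
    def total_duration(self) -> float:
        return self.lead_in + sum(b.duration for b in self.blocks) + self.lead_out

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.config.conditions

    def blocks_of(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]


def generate_schedule(config: DesignConfig | None = None, seed: int = 0) -> Schedule:
    """Draw a randomized schedule: per cycle a fresh condition permutation,
    per block a without-replacement draw of clips from the matching library.

    Deterministic for a given ``(config, seed)`` pair.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)
    blocks: list[Block] = []
    t = config.lead_in_s
    for _ in range(config.n_cycles):
        order = rng.permutation(len(config.conditions))
        for idx in order:
            cond = config.conditions[idx]
            lib = (
                config.action_library_size
                if cond in _ACTION_CONDITIONS
                else config.landscape_library_size
            )
            clips = rng.choice(lib, size=config.trials_per_block, replace=False)
            trials = tuple(
                (int(c), t + k * config.trial_s, config.trial_s)
                for k, c in enumerate(clips)
            )
            blocks.append(
                Block(
                    condition=cond,
                    onset=t,
                    task_duration=config.task_s,
                    rest_duration=config.rest_s,
                    trials=trials,
                )
            )
            t += config.task_s + config.rest_s
    return Schedule(
        blocks=tuple(blocks),
        lead_in=config.lead_in_s,
        lead_out=config.lead_out_s,
        n_cycles=config.n_cycles,
        seed=seed,
        config=config,
    )


def schedule_to_events(schedule: Schedule, per_trial: bool = False) -> pd.DataFrame:
    """Flatten a schedule into a BIDS-style events table.

    One row per block task phase (or per trial with ``per_trial=True``) with
    columns ``onset`` (s), ``duration`` (s), ``trial_type``.  Onsets are
    strictly increasing; overlap is rejected.
    """
    rows = []
    for b in schedule.blocks:
        if per_trial:
            for clip_id, onset, dur in b.trials:
                rows.append((onset, dur, b.condition))
        else:
            rows.append((b.onset, b.task_duration, b.condition))
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    if len(df) > 1:
        onsets = df["onset"].to_numpy()
        ends = onsets + df["duration"].to_numpy()
        if np.any(np.diff(onsets) <= 0) or np.any(ends[:-1] > onsets[1:] + 1e-9):
            raise ValueError("events overlap or are not strictly increasing")
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an events table as TSV with 3-decimal fixed-point seconds."""
    out = events.copy()
    for col in ("onset", "duration"):
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    Path(path).write_text(out.to_csv(sep="\t", index=False), encoding="utf-8")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t", dtype={"trial_type": str})
    df["onset"] = df["onset"].astype(float)
    df["duration"] = df["duration"].astype(float)
    return df


def condition_boxcars(
    schedule: Schedule, fs: float, n_samples: int | None = None
) -> pd.DataFrame:
    """Per-condition 0/1 stimulus indicator series sampled at ``fs`` Hz.

    Sample ``k`` (0-based) is inside an event iff ``onset <= k/fs < end``
    (half-open), which makes the per-condition sums exact:
    ``n_blocks x task_s x fs`` samples for the default grid.
    """
    if fs <= 0:
        raise ParadigmConfigError("fs must be > 0")
    if n_samples is None:
        n_samples = int(round(schedule.total_duration * fs))
    t = np.arange(n_samples) / fs
    data = {}
    for cond in schedule.conditions:
        box = np.zeros(n_samples)
        for b in schedule.blocks_of(cond):
            box[(t >= b.onset) & (t < b.task_end)] = 1.0
        data[cond] = box
    return pd.DataFrame(data)


def events_to_boxcars(
    events: pd.DataFrame,
    fs: float,
    n_samples: int,
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Boxcars from an events table (same half-open sample rule as above).

    ``conditions`` fixes the column order; by default the distinct
    ``trial_type`` values in order of first appearance.
    """
    if fs <= 0:
        raise ParadigmConfigError("fs must be > 0")
    if conditions is None:
        conditions = tuple(pd.unique(events["trial_type"]))
    t = np.arange(n_samples) / fs
    data = {}
    for cond in conditions:
        box = np.zeros(n_samples)
        sel = events[events["trial_type"] == cond]
        for onset, dur in zip(sel["onset"], sel["duration"]):
            box[(t >= onset) & (t < onset + dur)] = 1.0
        data[cond] = box
    return pd.DataFrame(data)
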