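"""Probe layout, anatomical registration metadata, and channel-to-ROI weights.

A *montage* is the set of source-detector (S-D) optode pairs laid over the
scalp.  Each channel carries MNI coordinates and an estimated cortical depth
(metadata only — no registration math is done here), plus a row of spatial
weights: the percentage of each region of interest (ROI, a Brodmann area)
that the channel is sensitive to.  Weights are consumed as printed
percentages; within an ROI the column is normalized so channel statistics
can be averaged into a single ROI statistic.

The packaged fixture ``colin27_mns20.tsv`` describes a 20-channel montage
over the left mirror-neuron system (BA6, BA7, BA40, BA44, BA45, BA46)
registered to the Colin-27 atlas.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Montage",
    "MontageFormatError",
    "MontageValidationError",
    "load_montage",
    "default_montage",
    "roi_weight_matrix",
    "aggregate_to_roi",
]

_CHANNEL_RE = re.compile(r"^S(\d+)-D(\d+)$")


class MontageFormatError(ValueError):
    """The montage file is missing required columns or cannot be parsed."""


class MontageValidationError(ValueError):
    """The montage file parses but violates a structural invariant."""


@dataclass(frozen=True)
class Channel:
    """One S-D measurement pair with its anatomical registration metadata."""

    source_index: int
    detector_index: int
    mni: np.ndarray  # (3,) MNI x/y/z in mm
    depth: float  # scalp-to-cortex depth in mm

    def __post_init__(self) -> None:
        if self.source_index < 1 or self.detector_index < 1:
            raise MontageValidationError("optode indices are 1-based positive integers")
        if self.depth <= 0:
            raise MontageValidationError(f"channel {self.name}: depth must be > 0 mm")
        object.__setattr__(self, "mni", np.asarray(self.mni, dtype=float))
        if self.mni.shape != (3,):
            raise MontageValidationError(f"channel {self.name}: mni must be a 3-vector")

    @property
    def name(self) -> str:
        return f"S{self.source_index}-D{self.detector_index}"


@dataclass(frozen=True)
class Montage:
    """Ordered channels plus the [channel x ROI] spatial-weight matrix (percent)."""

    channels: tuple[Channel, ...]
    roi_names: tuple[str, ...]
    weights: np.ndarray  # [n_channels, n_rois], percentages in [0, 100]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        n_ch, n_roi = len(self.channels), len(self.roi_names)
        if self.weights.shape != (n_ch, n_roi):
            raise MontageValidationError(
                f"weights shape {self.weights.shape} != ({n_ch}, {n_roi})"
            )
        names = self.channel_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MontageValidationError(f"duplicate channel names: {dupes}")
        if np.any(self.weights < 0) or np.any(self.weights > 100):
            raise MontageValidationError("spatial weights must lie in [0, 100] percent")

    @property
    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def __len__(self) -> int:
        return len(self.channels)


def _parse_channel_name(name: str) -> tuple[int, int]:
    m = _CHANNEL_RE.match(name.strip())
    if m is None:
        raise MontageFormatError(f"channel name {name!r} is not of the form 'S<i>-D<j>'")
    return int(m.group(1)), int(m.group(2))


def load_montage(path: str | Path) -> Montage:
    """Read a montage description from a delimited text file.

    The file must have a header row with columns ``channel``, ``mni_x``,
    ``mni_y``, ``mni_z``, ``depth_mm``, followed by one column per ROI label;
    tab- or comma-separated.  ROI weight cells may carry a trailing ``%``.

    Raises
    ------
    MontageFormatError
        Missing required columns, unparseable file, or malformed channel name.
    MontageValidationError
        Weight outside [0, 100], duplicate channel name, or bad geometry.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise MontageFormatError(f"cannot parse montage file {path}: {exc}") from exc

    required = ["channel", "mni_x", "mni_y", "mni_z", "depth_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MontageFormatError(f"montage file {path} is missing columns {missing}")
    roi_names = [c for c in df.columns if c not in required]
    if not roi_names:
        raise MontageFormatError(f"montage file {path} has no ROI weight columns")

    channels = []
    for _, row in df.iterrows():
        s, d = _parse_channel_name(str(row["channel"]))
        channels.append(
            Channel(
                source_index=s,
                detector_index=d,
                mni=np.array([row["mni_x"], row["mni_y"], row["mni_z"]], dtype=float),
                depth=float(row["depth_mm"]),
            )
        )

    weights = (
        df[roi_names]
        .apply(lambda col: col.astype(str).str.rstrip("%"))
        .astype(float)
        .to_numpy()
    )
    return Montage(channels=tuple(channels), roi_names=tuple(roi_names), weights=weights)


def default_montage() -> Montage:
    """The packaged 20-channel left-MNS montage (Colin-27 registration)."""
    with resources.as_file(
        resources.files("fnirsglm.data").joinpath("colin27_mns20.tsv")
    ) as p:
        return load_montage(p)


def roi_weight_matrix(montage: Montage) -> np.ndarray:
    """Column-normalized [channel x ROI] weight matrix (each ROI sums to 1).

    Zero entries are preserved; an ROI whose raw column sums to zero has no
    contributing channel and is a configuration error.
    """
    raw = montage.weights
    totals = raw.sum(axis=0)
    dead = [montage.roi_names[j] for j in np.flatnonzero(totals == 0)]
    if dead:
        raise MontageValidationError(f"ROI(s) with all-zero weight column: {dead}")
    return raw / totals


def aggregate_to_roi(
    values: dict[str, float] | pd.Series, montage: Montage
) -> pd.Series:
    """Weighted-average per-channel scalars into per-ROI scalars.

    Each ROI value is the spatial-weight-weighted mean of the channel values;
    channels with zero weight in an ROI do not contribute to it.  A missing
    value on a channel that has nonzero weight somewhere is an error — values
    are never silently dropped.
    """
    values = pd.Series(values, dtype=float)
    norm = roi_weight_matrix(montage)
    names = montage.channel_names
    needed = [n for n, w in zip(names, montage.weights) if np.any(w > 0)]
    missing = [n for n in needed if n not in values.index or not np.isfinite(values[n])]
    if missing:
        raise KeyError(f"missing channel values for weighted channels: {missing}")
    x = values.reindex(names).to_numpy()
    # channels absent everywhere in the weight matrix contribute nothing
    x = np.where(np.isfinite(x), x, 0.0)
    return pd.Series(x @ norm, index=list(montage.roi_names))
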