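"""Raw intensity -> optical density -> hemoglobin concentration changes.

Optical density uses the natural-log convention with the whole-recording
mean as reference, so each OD trace is (approximately) zero-mean and
invariant under global intensity rescaling.  The hemoglobin inversion
solves the two-wavelength modified Beer-Lambert system per sample.  No
band-pass filter is applied before modelling: slow drifts go into the
design-matrix polynomial regressors and serial correlation is handled by
autoregressive prewhitening in the first-level fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .optics import OpticsSpec

__all__ = [
    "RawRecording",
    "ODSeries",
    "HbSeries",
    "DataError",
    "intensity_to_od",
    "od_to_hb",
    "quality_metrics",
]


class DataError(ValueError):
    """The recording violates a data invariant (e.g. nonpositive intensity)."""


@dataclass
class RawRecording:
    """Two-wavelength raw intensity, [channel x wavelength x time]."""

    intensity: np.ndarray
    fs: float
    wavelengths: tuple[float, float]
    channel_names: list[str]
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise DataError("intensity must be [channel x 2 wavelengths x time]")
        if self.fs <= 0:
            raise DataError("fs must be > 0")
        if len(self.channel_names) != self.intensity.shape[0]:
            raise DataError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ODSeries:
    """Optical-density changes, [channel x wavelength x time], unitless."""

    od: np.ndarray
    fs: float
    wavelengths: tuple[float, float]
    channel_names: list[str]
    reference_intensity: np.ndarray  # [channel x wavelength]
    events: pd.DataFrame | None = None


@dataclass
class HbSeries:
    """Hemoglobin concentration changes in uM, [channel x time]."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_names: list[str]
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise DataError("hbo and hbr must share a shape")

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]


def intensity_to_od(raw: RawRecording, reference: np.ndarray | None = None) -> ODSeries:
    """OD(t) = -ln(I(t) / I_ref), I_ref the temporal mean per channel and
    wavelength by default (each OD trace is then approximately zero-mean).
    Pass ``reference`` [channel x wavelength] to use a known baseline
    instead — e.g. the emitted level of a forward simulation, which makes
    the OD exactly the modelled dOD.

    Raises :class:`DataError` naming the first offending channel/sample if
    any intensity is nonpositive.
    """
    intensity = raw.intensity
    bad = np.argwhere(intensity <= 0)
    if bad.size:
        ch, wl, t = bad[0]
        raise DataError(
            f"nonpositive intensity at channel {raw.channel_names[ch]}, "
            f"wavelength index {wl}, sample {t}"
        )
    ref = intensity.mean(axis=2) if reference is None else np.asarray(reference, float)
    od = -np.log(intensity / ref[:, :, None])
    return ODSeries(
        od=od,
        fs=raw.fs,
        wavelengths=raw.wavelengths,
        channel_names=list(raw.channel_names),
        reference_intensity=ref,
        events=raw.events,
    )


def od_to_hb(od: ODSeries, optics: OpticsSpec) -> HbSeries:
    """Invert the two-wavelength modified Beer-Lambert system per sample.

    Solves ``dOD(lambda) = sum_c eps(lambda, c) dC_c d DPF(lambda)`` for
    (dHbO, dHbR); output in uM.
    """
    if tuple(od.wavelengths) != tuple(optics.wavelengths):
        raise ValueError(
            f"wavelength mismatch: data {od.wavelengths} vs optics {optics.wavelengths}"
        )
    n_ch = od.od.shape[0]
    d = optics.distances(n_ch)
    dpf = np.asarray(optics.dpf)
    # effective pathlength-scaled OD: y[ch, wl, t] / (d * DPF)
    y = od.od / (d[:, None, None] * dpf[None, :, None])
    eps_inv = np.linalg.inv(optics.extinction)
    conc_mm = np.einsum("cl,klt->kct", eps_inv, y)  # [ch, (HbO, HbR), t]
    hbo, hbr = conc_mm[:, 0, :] * 1e3, conc_mm[:, 1, :] * 1e3
    return HbSeries(
        hbo=hbo, hbr=hbr, fs=od.fs, channel_names=list(od.channel_names), events=od.events
    )


def quality_metrics(
    raw: RawRecording,
    cardiac_band: tuple[float, float] = (0.7, 1.5),
    corr_threshold: float = 0.7,
    cv_threshold_pct: float = 15.0,
) -> pd.DataFrame:
    """Per-channel signal-quality report.

    Two complementary metrics: the coefficient of variation of the raw
    intensity (optode-contact stability), and the correlation of the
    cardiac-band (0.7-1.5 Hz by default) band-passed OD between the two
    wavelengths — a scalp-coupling index: a channel optically coupled to the
    scalp sees the same cardiac pulsation at both wavelengths.  A channel is
    flagged bad when the correlation falls below ``corr_threshold`` or the
    CV exceeds ``cv_threshold_pct`` percent.
    """
    if raw.duration < 30.0:
        raise DataError("need at least 30 s of data for quality metrics")
    od = intensity_to_od(raw).od
    lo, hi = cardiac_band
    nyq = raw.fs / 2.0
    hi = min(hi, 0.95 * nyq)
    if not 0 < lo < hi:
        raise ValueError("cardiac band must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(3, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    rows = []
    for k, name in enumerate(raw.channel_names):
        cv = float(
            np.max(raw.intensity[k].std(axis=1) / raw.intensity[k].mean(axis=1)) * 100.0
        )
        bp = signal.sosfiltfilt(sos, od[k], axis=1)
        s0, s1 = bp[0].std(), bp[1].std()
        corr = float(np.corrcoef(bp[0], bp[1])[0, 1]) if s0 > 0 and s1 > 0 else 0.0
        rows.append(
            {
                "channel": name,
                "cv": cv,
                "cardiac_corr": corr,
                "good": bool(corr >= corr_threshold and cv <= cv_threshold_pct),
            }
        )
    return pd.DataFrame(rows)
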