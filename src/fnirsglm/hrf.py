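"""Canonical hemodynamic response function (HRF).

The double-gamma form: a gamma-density main lobe peaking ~6 s after
stimulus onset minus a scaled gamma-density undershoot peaking ~16 s.
The kernel is zero at t = 0 and rescaled to unit peak amplitude, so a
regression coefficient on an HRF-convolved boxcar keeps the amplitude
units of the data (uM here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HrfParams", "canonical_hrf"]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma shape parameters (seconds / unitless ratio)."""

    peak_time_s: float = 6.0
    undershoot_time_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    peak_disp_s: float = 1.2  # gamma scale of the main lobe
    undershoot_disp_s: float = 16.0 / 15.0  # gamma scale of the undershoot
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_time_s", "undershoot_time_s", "peak_disp_s",
                     "undershoot_disp_s", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be > 0")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")
        if self.duration_s < 30.0:
            raise ValueError("kernel must cover at least 30 s")


def canonical_hrf(fs: float, params: HrfParams | None = None) -> np.ndarray:
    """Sample the double-gamma HRF kernel at ``fs`` Hz, unit peak amplitude.

    The gamma shapes are chosen so the mode of the main lobe falls at
    ``peak_time_s`` and the undershoot trough at ``undershoot_time_s``:
    a gamma density with shape a and scale s peaks at (a - 1) * s.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    p = params or HrfParams()
    t = np.arange(0.0, p.duration_s, 1.0 / fs)
    a_peak = p.peak_time_s / p.peak_disp_s + 1.0
    a_under = p.undershoot_time_s / p.undershoot_disp_s + 1.0
    h = stats.gamma.pdf(t, a_peak, scale=p.peak_disp_s) - p.undershoot_ratio * stats.gamma.pdf(
        t, a_under, scale=p.undershoot_disp_s
    )
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return h / peak
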