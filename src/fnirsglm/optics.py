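"""Modified Beer-Lambert law (mBLL) forward model and its optical constants.

For a continuous-wave instrument the change in optical density at
wavelength lambda is linear in the chromophore concentration changes:

    dOD(lambda, t) = [eps(lambda, HbO) * dC_HbO(t) + eps(lambda, HbR) * dC_HbR(t)]
                     * d * DPF(lambda)

with eps the molar extinction coefficient in 1/(mM*cm), d the
source-detector separation in cm, DPF the unitless differential
pathlength factor, and concentrations in mM.  With two wavelengths this
is an invertible 2x2 system per sample; the inverse lives in
:mod:`fnirsglm.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["OpticsSpec", "extinction_table", "extinction_matrix", "forward_mbll"]


class OpticsConfigError(ValueError):
    """Inconsistent or degenerate optical configuration."""


def extinction_table() -> pd.DataFrame:
    """Packaged hemoglobin extinction coefficients, 1/(mM*cm) by wavelength."""
    with resources.as_file(
        resources.files("fnirsglm.data").joinpath("extinction_hb.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2x2 matrix eps[wavelength, chromophore] (columns HbO, HbR) at the
    requested wavelengths, linearly interpolated from the packaged table."""
    tab = extinction_table()
    lo, hi = tab["wavelength_nm"].min(), tab["wavelength_nm"].max()
    eps = np.empty((2, 2))
    for i, wl in enumerate(wavelengths):
        if not lo <= wl <= hi:
            raise OpticsConfigError(
                f"wavelength {wl} nm outside the packaged table range [{lo}, {hi}]"
            )
        eps[i, 0] = np.interp(wl, tab["wavelength_nm"], tab["hbo"])
        eps[i, 1] = np.interp(wl, tab["wavelength_nm"], tab["hbr"])
    return eps


@dataclass(frozen=True)
class OpticsSpec:
    """Wavelengths, extinction matrix, pathlength factors and geometry.

    ``distance_cm`` is the per-channel S-D separation; ``baseline_intensity``
    the raw detector level [channel x wavelength] about which fluctuations
    are simulated.
    """

    wavelengths: tuple[float, float] = (769.0, 850.0)
    extinction: np.ndarray | None = None  # eps[wavelength, (HbO, HbR)], 1/(mM*cm)
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: np.ndarray | float = 3.0
    baseline_intensity: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        eps = self.extinction
        if eps is None:
            eps = extinction_matrix(self.wavelengths)
        eps = np.asarray(eps, dtype=float)
        if eps.shape != (2, 2):
            raise OpticsConfigError("extinction must be a 2x2 matrix")
        if not np.all(np.isfinite(eps)) or abs(np.linalg.det(eps)) < 1e-12:
            raise OpticsConfigError("extinction matrix is singular or non-finite")
        object.__setattr__(self, "extinction", eps)
        if any(v <= 0 for v in self.dpf):
            raise OpticsConfigError("DPF must be > 0")
        if np.any(np.asarray(self.distance_cm) <= 0):
            raise OpticsConfigError("source-detector distance must be > 0")

    def distances(self, n_channels: int) -> np.ndarray:
        d = np.asarray(self.distance_cm, dtype=float)
        return np.full(n_channels, float(d)) if d.ndim == 0 else d

    def baselines(self, n_channels: int) -> np.ndarray:
        b = np.asarray(self.baseline_intensity, dtype=float)
        if b.ndim == 0:
            return np.full((n_channels, 2), float(b))
        return b


def forward_mbll(
    hbo_um: np.ndarray, hbr_um: np.ndarray, optics: OpticsSpec
) -> np.ndarray:
    """Map concentration changes (uM, [channel x time]) to dOD [channel x
    wavelength x time] via the mBLL.  Concentrations are converted to mM so
    the extinction units match."""
    hbo_um = np.atleast_2d(np.asarray(hbo_um, dtype=float))
    hbr_um = np.atleast_2d(np.asarray(hbr_um, dtype=float))
    if hbo_um.shape != hbr_um.shape:
        raise ValueError("HbO and HbR arrays must share a shape")
    n_ch = hbo_um.shape[0]
    d = optics.distances(n_ch)
    eps = optics.extinction
    conc_mm = np.stack([hbo_um, hbr_um], axis=1) * 1e-3  # [ch, chromophore, t]
    od = np.einsum("lc,kct->klt", eps, conc_mm)  # [ch, wl, t]
    od *= d[:, None, None] * np.asarray(optics.dpf)[None, :, None]
    return od
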