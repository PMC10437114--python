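"""Minimal SNIRF (Shared Near Infrared Format) reader and writer.

SNIRF is an HDF5 layout; this module covers the subset needed for
continuous-wave amplitude recordings: ``/nirs/data1`` with a
``dataTimeSeries`` [time x measurement] matrix, one ``measurementList<k>``
entry per (channel, wavelength) column, and a ``probe`` group with
wavelengths and optode positions.  Channel ordering round-trips through
the measurement-list source/detector/wavelength indices.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .montage import Montage
from .preprocess import RawRecording

__all__ = ["write_snirf", "read_snirf"]

_FORMAT_VERSION = "1.0"


def _str_dataset(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(
    raw: RawRecording, path: str | Path, montage: Montage | None = None
) -> None:
    """Write a continuous-wave amplitude recording as SNIRF v1.0."""
    n_ch, _, n_t = raw.intensity.shape
    time = np.arange(n_t) / raw.fs
    # columns ordered channel-major, wavelength-minor
    data = raw.intensity.transpose(2, 0, 1).reshape(n_t, n_ch * 2)
    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", _FORMAT_VERSION)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_dataset(meta, "SubjectID", "synthetic")
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "mm")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=time)
        src_idx, det_idx = _optode_indices(raw, montage)
        for k in range(n_ch * 2):
            ch, wl = divmod(k, 2)
            ml = d1.create_group(f"measurementList{k + 1}")
            ml.create_dataset("sourceIndex", data=int(src_idx[ch]))
            ml.create_dataset("detectorIndex", data=int(det_idx[ch]))
            ml.create_dataset("wavelengthIndex", data=wl + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths, float))
        n_src, n_det = int(src_idx.max()), int(det_idx.max())
        pos = np.zeros((max(n_src, 1), 3))
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=np.zeros((max(n_det, 1), 3)))
        probe.create_dataset(
            "sourceLabels",
            data=np.array([f"S{i + 1}".encode() for i in range(n_src)]),
        )
        probe.create_dataset(
            "detectorLabels",
            data=np.array([f"D{i + 1}".encode() for i in range(n_det)]),
        )


def _optode_indices(
    raw: RawRecording, montage: Montage | None
) -> tuple[np.ndarray, np.ndarray]:
    if montage is not None and montage.channel_names == list(raw.channel_names):
        src = np.array([c.source_index for c in montage.channels])
        det = np.array([c.detector_index for c in montage.channels])
        return src, det
    # fall back to parsing "S<i>-D<j>" names, else sequential indices
    src, det = [], []
    for k, name in enumerate(raw.channel_names):
        try:
            s, d = name.removeprefix("S").split("-D")
            src.append(int(s))
            det.append(int(d))
        except ValueError:
            src.append(k + 1)
            det.append(k + 1)
    return np.array(src), np.array(det)


def read_snirf(path: str | Path) -> RawRecording:
    """Read a continuous-wave amplitude SNIRF file written by this package
    (or any file using the same two-wavelength CW layout)."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        if time.size < 2:
            raise ValueError("need at least two time points")
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"], float))
        ml_names = sorted(
            (n for n in d1 if n.startswith("measurementList")),
            key=lambda n: int(n.removeprefix("measurementList")),
        )
        cols = []
        for n in ml_names:
            g = d1[n]
            cols.append(
                (int(g["sourceIndex"][()]), int(g["detectorIndex"][()]),
                 int(g["wavelengthIndex"][()]))
            )
    pairs = list(dict.fromkeys((s, d) for s, d, _ in cols))
    n_ch, n_t = len(pairs), data.shape[0]
    intensity = np.empty((n_ch, 2, n_t))
    for col, (s, d, w) in enumerate(cols):
        intensity[pairs.index((s, d)), w - 1] = data[:, col]
    names = [f"S{s}-D{d}" for s, d in pairs]
    return RawRecording(
        intensity=intensity, fs=fs, wavelengths=wavelengths, channel_names=names
    )
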