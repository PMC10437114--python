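"""Synthetic multi-subject fNIRS recordings with known ground truth.

Each subject's per-channel oxyhemoglobin series is a sum of
HRF-convolved condition boxcars scaled by subject-specific response
amplitudes, plus structured noise: a stationary autoregressive process,
sinusoidal physiological oscillations (cardiac ~1.1 Hz, respiration
~0.25 Hz, Mayer waves ~0.1 Hz) with random phases, a linear drift, and
optional motion spikes.  Deoxyhemoglobin is tied to the HbO signal by a
fixed negative ratio (default 1/3) plus independent noise, matching the
typical empirical HbO:HbR anticorrelation; downstream statistics model
HbO only.  Subject amplitudes are drawn once per subject and channel as
Normal(beta_true, tau^2), giving the between-subject variance the group
mixed model estimates.

The forward optics step maps concentration changes to two-wavelength raw
intensity through the modified Beer-Lambert law, the exact inverse of
the preprocessing chain, so noise-free recordings round-trip to the
injected hemoglobin series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hrf import HrfParams, canonical_hrf
from .montage import Montage, default_montage
from .optics import OpticsSpec, forward_mbll
from .paradigm import (
    DesignConfig,
    Schedule,
    condition_boxcars,
    generate_schedule,
    schedule_to_events,
    write_events,
)
from .preprocess import HbSeries, RawRecording

__all__ = [
    "NoiseSpec",
    "SubjectTruth",
    "simulate_subject",
    "hb_to_raw",
    "simulate_group",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for one channel's concentration series (uM).

    Defaults give the serial correlation and physiological structure that
    motivates autoregressive prewhitening: AR(1) phi = 0.8 innovations of
    0.5 uM, cardiac/respiratory/Mayer oscillations of 0.2-0.3 uM, and a
    slow 0.1 uM/min drift.
    """

    ar_coeffs: tuple[float, ...] = (0.8,)
    white_sd: float = 0.5
    oscillations: tuple[tuple[float, float, bool], ...] = (
        (1.1, 0.3, True),   # cardiac
        (0.25, 0.2, True),  # respiration
        (0.1, 0.3, True),   # Mayer waves
    )
    drift_slope: float = 0.1  # uM per minute
    spike_rate: float = 0.0  # motion artifacts per minute
    spike_amp: float = 5.0  # uM

    def __post_init__(self) -> None:
        if self.white_sd < 0 or any(a < 0 for _, a, _ in self.oscillations):
            raise ValueError("noise amplitudes must be >= 0")
        if self.ar_coeffs:
            poly = np.r_[1.0, -np.asarray(self.ar_coeffs)]
            if np.any(np.abs(np.roots(poly)) >= 1.0 - 1e-9):
                raise ValueError("AR polynomial is not stationary")

    def is_silent(self) -> bool:
        return (
            self.white_sd == 0
            and all(a == 0 for _, a, _ in self.oscillations)
            and self.drift_slope == 0
            and self.spike_rate == 0
        )


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth response amplitudes and variability for a cohort.

    ``beta_true`` is [channel x condition] in uM (HbO peak amplitude per
    condition); ``subject_offset_sd`` (tau) is the between-subject SD of
    the realized amplitudes; ``hbr_ratio`` ties HbR to -ratio * HbO.
    """

    beta_true: np.ndarray
    conditions: tuple[str, ...]
    hbr_ratio: float = 1.0 / 3.0
    subject_offset_sd: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_true", np.atleast_2d(np.asarray(self.beta_true, float)))
        if self.beta_true.shape[1] != len(self.conditions):
            raise ValueError("beta_true columns must match conditions")
        if self.hbr_ratio < 0 or self.subject_offset_sd < 0:
            raise ValueError("hbr_ratio and subject_offset_sd must be >= 0")


def _noise_trace(n: int, fs: float, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    if spec.white_sd > 0:
        eps = rng.normal(0.0, spec.white_sd, size=n + 200)
        if spec.ar_coeffs:
            from scipy.signal import lfilter

            eps = lfilter([1.0], np.r_[1.0, -np.asarray(spec.ar_coeffs)], eps)
        out += eps[200:]  # discard burn-in
    t = np.arange(n) / fs
    for freq, amp, random_phase in spec.oscillations:
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi) if random_phase else 0.0
            out += amp * np.sin(2 * np.pi * freq * t + phase)
    if spec.drift_slope:
        out += spec.drift_slope * t / 60.0
    if spec.spike_rate > 0:
        n_spikes = rng.poisson(spec.spike_rate * n / fs / 60.0)
        for _ in range(n_spikes):
            pos = rng.integers(0, n)
            width = max(1, int(0.5 * fs))
            amp = rng.choice([-1.0, 1.0]) * spec.spike_amp * rng.uniform(0.5, 1.5)
            seg = np.arange(n - pos)[: 3 * width]
            out[pos : pos + seg.size] += amp * np.exp(-seg / width)
    return out


def simulate_subject(
    schedule: Schedule,
    montage: Montage,
    truth: SubjectTruth,
    fs: float = 10.0,
    seed: int = 0,
    hrf_params: HrfParams | None = None,
) -> tuple[HbSeries, np.ndarray]:
    """Simulate one subject's concentration series and return it with the
    realized per-channel, per-condition amplitudes (for recovery scoring).

    Per channel: ``dHbO = sum_c beta_subject[c] * (boxcar_c conv HRF) + noise``
    with ``beta_subject ~ Normal(beta_true, tau^2)`` drawn once per
    channel-condition; ``dHbR = -hbr_ratio * signal + hbr_ratio * noise'``.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.total_duration * fs))
    box = condition_boxcars(schedule, fs, n)
    if list(box.columns) != list(truth.conditions):
        raise ValueError(
            f"schedule conditions {list(box.columns)} != truth conditions "
            f"{list(truth.conditions)}"
        )
    kernel = canonical_hrf(fs, hrf_params)
    regressors = np.stack(
        [np.convolve(box[c].to_numpy(), kernel)[:n] for c in truth.conditions]
    )  # [condition x time]
    n_ch = montage.n_channels
    beta_subject = np.broadcast_to(
        truth.beta_true, (n_ch, len(truth.conditions))
    ).astype(float).copy()
    if truth.subject_offset_sd > 0:
        beta_subject += rng.normal(
            0.0, truth.subject_offset_sd, size=beta_subject.shape
        )
    signal_part = beta_subject @ regressors  # [channel x time]
    hbo = signal_part.copy()
    hbr = -truth.hbr_ratio * signal_part
    if not truth.noise.is_silent():
        for k in range(n_ch):
            hbo[k] += _noise_trace(n, fs, truth.noise, rng)
            hbr[k] += truth.hbr_ratio * _noise_trace(n, fs, truth.noise, rng)
    hb = HbSeries(
        hbo=hbo,
        hbr=hbr,
        fs=fs,
        channel_names=montage.channel_names,
        events=schedule_to_events(schedule),
    )
    return hb, beta_subject


def hb_to_raw(
    hb: HbSeries,
    optics: OpticsSpec,
    seed: int | None = None,
    shot_noise_sd: float = 0.0,
) -> RawRecording:
    """Forward-model concentrations to two-wavelength raw intensity.

    ``I(lambda, t) = I0(lambda) * exp(-dOD(lambda, t))`` with dOD from the
    modified Beer-Lambert law; optional multiplicative shot noise.  The
    noise-free composition with ``preprocess.od_to_hb`` is the identity up
    to the OD reference (which only shifts each trace by a constant).
    """
    od = forward_mbll(hb.hbo, hb.hbr, optics)
    n_ch = od.shape[0]
    i0 = optics.baselines(n_ch)
    intensity = i0[:, :, None] * np.exp(-od)
    if shot_noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * np.exp(rng.normal(0.0, shot_noise_sd, size=intensity.shape))
    return RawRecording(
        intensity=intensity,
        fs=hb.fs,
        wavelengths=tuple(optics.wavelengths),
        channel_names=list(hb.channel_names),
        events=hb.events,
    )


def simulate_group(
    n_subjects: int,
    truth: SubjectTruth,
    out_dir: str | Path,
    design: DesignConfig | None = None,
    montage: Montage | None = None,
    optics: OpticsSpec | None = None,
    fs: float = 10.0,
    seed: int = 0,
    write_raw: bool = True,
) -> pd.DataFrame:
    """Write a synthetic cohort: one fresh randomized schedule and recording
    per subject (SNIRF + events TSV) plus a ground-truth manifest.

    Returns the manifest as a long DataFrame (subject, channel, condition,
    beta_true, beta_realized, seed); the same content is written to
    ``manifest.tsv`` with generator settings in ``manifest_meta.json``.
    """
    from .snirfio import write_snirf

    if n_subjects < 2:
        raise ValueError("need n_subjects >= 2")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    montage = montage or default_montage()
    optics = optics or OpticsSpec()
    design = design or DesignConfig()
    root = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        sched_seed, subj_seed, optics_seed = (int(v) for v in root.integers(0, 2**31 - 1, 3))
        schedule = generate_schedule(design, seed=sched_seed)
        try:
            hb, beta_subject = simulate_subject(schedule, montage, truth, fs=fs, seed=subj_seed)
            if write_raw:
                raw = hb_to_raw(hb, optics, seed=optics_seed)
                write_snirf(raw, out_dir / f"sub-{s + 1:02d}.snirf", montage)
            write_events(hb.events, out_dir / f"sub-{s + 1:02d}_events.tsv")
        except Exception as exc:  # surface the failing subject
            raise RuntimeError(f"simulation failed for subject {s + 1}") from exc
        for k, ch in enumerate(montage.channel_names):
            for j, cond in enumerate(truth.conditions):
                rows.append(
                    {
                        "subject": s + 1,
                        "channel": ch,
                        "condition": cond,
                        "beta_true": float(np.broadcast_to(truth.beta_true, beta_subject.shape)[k, j]),
                        "beta_realized": float(beta_subject[k, j]),
                        "seed": subj_seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    meta = {
        "n_subjects": n_subjects,
        "fs": fs,
        "seed": seed,
        "conditions": list(truth.conditions),
        "hbr_ratio": truth.hbr_ratio,
        "subject_offset_sd": truth.subject_offset_sd,
        "noise": asdict(truth.noise),
        "wavelengths": list(optics.wavelengths),
    }
    (out_dir / "manifest_meta.json").write_text(json.dumps(meta, indent=2))
    return manifest
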