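"""End-to-end orchestration: simulate / QC / preprocess / fit / group / report.

Every stage is deterministic given the run configuration and its seeds;
rendered tables are formatted views of the stats tables the stages
produce, with no recomputation at render time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .first_level import build_design, fit_channels, first_level_table
from .group_level import (
    default_contrasts,
    fit_group,
    roi_group_stats,
    significant_counts,
)
from .hrf import HrfParams
from .montage import Montage, default_montage, load_montage
from .optics import OpticsSpec
from .paradigm import CONDITIONS, CONTROL_CONDITION, DesignConfig, read_events
from .preprocess import intensity_to_od, od_to_hb, quality_metrics
from .simulate import NoiseSpec, SubjectTruth, simulate_group
from .snirfio import read_snirf

__all__ = ["RunConfig", "run_pipeline", "render_activation_table"]

log = logging.getLogger("fnirsglm")


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML via :meth:`from_yaml`."""

    input_dir: str = "dataset"
    output_dir: str = "results"
    montage_file: str | None = None  # None -> packaged 20-channel montage
    fs: float = 10.0
    wavelengths: tuple[float, float] = (769.0, 850.0)
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: float = 3.0
    drift_order: int = 3
    max_ar_order: int | None = None  # None -> 4 * fs
    robust: bool = True
    alpha: float = 0.05
    conditions: tuple[str, ...] = CONDITIONS
    control: str = CONTROL_CONDITION
    seed: int = 0
    # simulation settings (used by the simulate stage)
    n_subjects: int = 6
    effect_um: dict = field(default_factory=dict)  # {channel: {condition: uM}}
    subject_offset_sd: float = 1.0
    hbr_ratio: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("wavelengths", "dpf", "conditions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def montage(self) -> Montage:
        return load_montage(self.montage_file) if self.montage_file else default_montage()

    def optics(self) -> OpticsSpec:
        return OpticsSpec(
            wavelengths=self.wavelengths, dpf=self.dpf, distance_cm=self.distance_cm
        )


def _truth_from_config(cfg: RunConfig, montage: Montage) -> SubjectTruth:
    beta = np.zeros((montage.n_channels, len(cfg.conditions)))
    names = montage.channel_names
    for channel, cond_map in (cfg.effect_um or {}).items():
        for cond, amp in cond_map.items():
            beta[names.index(channel), cfg.conditions.index(cond)] = float(amp)
    return SubjectTruth(
        beta_true=beta,
        conditions=cfg.conditions,
        hbr_ratio=cfg.hbr_ratio,
        subject_offset_sd=cfg.subject_offset_sd,
        noise=NoiseSpec(),
    )


def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    montage = cfg.montage()
    truth = _truth_from_config(cfg, montage)
    log.info("simulate: %d subjects -> %s", cfg.n_subjects, cfg.input_dir)
    return simulate_group(
        cfg.n_subjects,
        truth,
        cfg.input_dir,
        design=DesignConfig(conditions=cfg.conditions),
        montage=montage,
        optics=cfg.optics(),
        fs=cfg.fs,
        seed=cfg.seed,
    )


def _subject_files(input_dir: str | Path) -> list[tuple[str, Path, Path]]:
    input_dir = Path(input_dir)
    out = []
    for snirf_path in sorted(input_dir.glob("sub-*.snirf")):
        stem = snirf_path.stem
        events_path = input_dir / f"{stem}_events.tsv"
        if not events_path.exists():
            raise FileNotFoundError(f"no events table for {snirf_path.name}")
        out.append((stem, snirf_path, events_path))
    if not out:
        raise FileNotFoundError(f"no sub-*.snirf recordings under {input_dir}")
    return out


def stage_qc(cfg: RunConfig) -> pd.DataFrame:
    frames = []
    for subject, snirf_path, _ in _subject_files(cfg.input_dir):
        report = quality_metrics(read_snirf(snirf_path))
        report.insert(0, "subject", subject)
        frames.append(report)
    qc = pd.concat(frames, ignore_index=True)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc.to_csv(out / "quality_report.csv", index=False)
    return qc


def stage_first_level(cfg: RunConfig) -> pd.DataFrame:
    optics = cfg.optics()
    frames = []
    for subject, snirf_path, events_path in _subject_files(cfg.input_dir):
        t0 = time.perf_counter()
        try:
            raw = read_snirf(snirf_path)
            raw.events = read_events(events_path)
            hb = od_to_hb(intensity_to_od(raw), optics)
            design = build_design(
                raw.events,
                raw.fs,
                drift_order=cfg.drift_order,
                n_samples=hb.n_samples,
                conditions=cfg.conditions,
            )
            fits = fit_channels(
                hb, design, max_ar_order=cfg.max_ar_order, robust=cfg.robust
            )
        except Exception as exc:
            raise RuntimeError(f"first-level stage failed for {subject}") from exc
        n_bad = sum(not f.converged for f in fits.values())
        if n_bad:
            log.warning("%s: %d channel fit(s) did not converge", subject, n_bad)
        frames.append(first_level_table(fits, subject=subject))
        log.info("first level %s: %.1f s", subject, time.perf_counter() - t0)
    table = pd.concat(frames, ignore_index=True)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "first_level.csv", index=False)
    return table


def stage_group(cfg: RunConfig, first_level: pd.DataFrame) -> dict:
    montage = cfg.montage()
    betas = first_level[first_level["regressor"].isin(cfg.conditions)].rename(
        columns={"regressor": "condition"}
    )[["subject", "channel", "condition", "beta"]]
    contrasts = default_contrasts(cfg.conditions, cfg.control)
    channel_stats = fit_group(betas, contrasts)
    roi_stats = roi_group_stats(betas, montage, contrasts)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    channel_stats.to_csv(out / "channel_stats.csv", index=False)
    roi_stats.to_csv(out / "roi_stats.csv", index=False)
    summary = {
        "alpha": cfg.alpha,
        "n_subjects": int(betas["subject"].nunique()),
        "significant_channels": significant_counts(channel_stats, cfg.alpha),
        "significant_rois": significant_counts(roi_stats, cfg.alpha),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"channel_stats": channel_stats, "roi_stats": roi_stats, "summary": summary}


def render_activation_table(
    stats: pd.DataFrame,
    path: str | Path,
    alpha: float | None = None,
    label_col: str | None = None,
) -> pd.DataFrame:
    """Write a formatted activation table (3-decimal fixed point).

    Rows are sorted by contrast then label; with ``alpha`` set, only rows
    significant after FDR are kept (an all-null run yields a header-only
    file).  Every cell comes straight from the stats table.
    """
    if label_col is None:
        label_col = "roi" if "roi" in stats.columns else "channel"
    cols = ["contrast", label_col, "beta", "se", "t", "p", "p_fdr"]
    table = stats.loc[:, cols].sort_values(["contrast", label_col])
    if alpha is not None:
        table = table[table["p_fdr"] < alpha]
    formatted = table.copy()
    for col in ("beta", "se", "t", "p", "p_fdr"):
        formatted[col] = formatted[col].map(lambda v: f"{v:.3f}")
    formatted = formatted.rename(columns={"beta": "beta_um", "se": "se_um"})
    Path(path).write_text(formatted.to_csv(sep="\t", index=False), encoding="utf-8")
    return table


def stage_report(cfg: RunConfig, results: dict) -> None:
    out = Path(cfg.output_dir)
    render_activation_table(
        results["channel_stats"], out / "channel_table.tsv", alpha=cfg.alpha
    )
    render_activation_table(results["roi_stats"], out / "roi_table.tsv", alpha=cfg.alpha)
    render_activation_table(results["channel_stats"], out / "channel_table_full.tsv")
    render_activation_table(results["roi_stats"], out / "roi_table_full.tsv")
    try:
        from .viz import plot_channel_grid, plot_roi_bars

        plot_roi_bars(results["roi_stats"], out / "roi_tvalues.png", alpha=cfg.alpha)
        plot_channel_grid(
            results["channel_stats"], cfg.montage(), out / "channel_tmap.png",
            alpha=cfg.alpha,
        )
    except Exception as exc:  # plotting is best-effort reporting
        log.warning("figure rendering skipped: %s", exc)


def run_pipeline(cfg: RunConfig, simulate: bool = False) -> dict:
    """Run all stages in order and return the result bundle."""
    t0 = time.perf_counter()
    if simulate:
        stage_simulate(cfg)
    stage_qc(cfg)
    first_level = stage_first_level(cfg)
    results = stage_group(cfg, first_level)
    stage_report(cfg, results)
    results["first_level"] = first_level
    log.info("pipeline complete in %.1f s", time.perf_counter() - t0)
    return results
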