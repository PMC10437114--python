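"""Group-level mixed-effects contrasts, FDR correction, ROI statistics.

Per channel (or ROI), the subjects' first-level condition coefficients
are modelled as ``beta ~ condition`` with a participant random intercept
— a linear mixed-effects model — and the contrasts of interest are each
task condition minus the control condition (landscape observation).
Inference on the fixed-effect differences uses the normal approximation,
appropriate at the cohort sizes this design targets.  Within each
contrast, p-values are Benjamini-Hochberg adjusted across the channels
(or across the ROIs for the ROI analysis) — each contrast is its own
multiple-testing family, matching how activation tables are reported.

ROI statistics aggregate each subject's first-level channel coefficients
into ROI coefficients with the montage spatial weights *before* the
group model, preserving the between-subject variance structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .montage import Montage, aggregate_to_roi
from .paradigm import CONDITIONS, CONTROL_CONDITION

__all__ = [
    "fit_group",
    "fdr_adjust",
    "significant_set",
    "roi_group_stats",
    "default_contrasts",
]


def default_contrasts(
    conditions: tuple[str, ...] = CONDITIONS, control: str = CONTROL_CONDITION
) -> list[tuple[str, str]]:
    """Each non-control condition versus the control."""
    return [(c, control) for c in conditions if c != control]


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def _paired_contrast(
    wide: pd.DataFrame, cond: str, control: str
) -> tuple[float, float, float, float]:
    """Paired-difference fallback when the mixed model is degenerate."""
    d = (wide[cond] - wide[control]).to_numpy()
    n = d.size
    est = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return est, 0.0, 0.0 if est == 0 else np.inf, 1.0 if est == 0 else 0.0
    se = sd / np.sqrt(n)
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return est, se, t, p


def _mixed_model_rows(
    df: pd.DataFrame, unit_col: str, contrasts: list[tuple[str, str]]
) -> pd.DataFrame:
    """One mixed-effects fit per unit; one output row per contrast x unit."""
    required = {"subject", unit_col, "condition", "beta"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    if df["subject"].nunique() < 2:
        raise ValueError("group analysis needs at least 2 subjects")
    rows = []
    for unit, sub in df.groupby(unit_col, sort=False):
        wide = sub.pivot_table(index="subject", columns="condition", values="beta")
        if wide.isna().any().any():
            missing = wide.columns[wide.isna().any()].tolist()
            raise ValueError(
                f"{unit_col} {unit}: every subject must contribute all "
                f"conditions (incomplete: {missing})"
            )
        n_subjects = len(wide)
        controls = {ctl for _, ctl in contrasts}
        results: dict[tuple[str, str], tuple[float, float, float, float]] = {}
        for control in controls:
            conds = [c for c, ctl in contrasts if ctl == control]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    res = None
                    # lbfgs can hit a singular profiled information matrix
                    # when a variance component sits on the boundary; powell
                    # is derivative-free and usually survives
                    for method in ("lbfgs", "powell"):
                        try:
                            model = smf.mixedlm(
                                f"beta ~ C(condition, Treatment('{control}'))",
                                data=sub,
                                groups=sub["subject"],
                            )
                            res = model.fit(reml=True, method=method)
                            break
                        except (np.linalg.LinAlgError, ValueError):
                            continue
                    if res is None:
                        raise np.linalg.LinAlgError("mixed model failed to fit")
                for cond in conds:
                    key = f"C(condition, Treatment('{control}'))[T.{cond}]"
                    est = float(res.params[key])
                    se = float(res.bse[key])
                    if not np.isfinite(est) or not np.isfinite(se) or se == 0.0:
                        raise np.linalg.LinAlgError("degenerate fixed-effect SE")
                    t = est / se
                    p = float(2.0 * stats.norm.sf(abs(t)))
                    results[(cond, control)] = (est, se, t, p)
            except (np.linalg.LinAlgError, ValueError, KeyError):
                warnings.warn(
                    f"mixed model degenerate for {unit_col} {unit}; "
                    "falling back to paired differences",
                    RuntimeWarning,
                    stacklevel=2,
                )
                for cond in conds:
                    results[(cond, control)] = _paired_contrast(wide, cond, control)
        for cond, control in contrasts:
            est, se, t, p = results[(cond, control)]
            rows.append(
                {
                    "contrast": f"{cond} - {control}",
                    unit_col: unit,
                    "beta": est,
                    "se": se,
                    "t": t,
                    "p": min(max(p, 1e-300), 1.0),
                    "n_subjects": n_subjects,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for _, idx in out.groupby("contrast", sort=False).groups.items():
        out.loc[idx, "p_fdr"] = fdr_adjust(out.loc[idx, "p"].to_numpy())
    return out


def fit_group(
    first_level_betas: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Channel-level group statistics.

    Parameters
    ----------
    first_level_betas
        Long table with columns ``subject, channel, condition, beta``
        (condition coefficients from the first-level fits, in uM).
    contrasts
        ``(condition, control)`` pairs; default is every non-control
        condition against the control condition.

    Returns a table with one row per contrast x channel: ``beta`` (fixed-
    effect difference, uM), ``se``, ``t``, ``p``, ``p_fdr`` (BH within
    contrast across channels), ``n_subjects``.
    """
    contrasts = contrasts or default_contrasts(
        tuple(pd.unique(first_level_betas["condition"]))
    )
    return _mixed_model_rows(first_level_betas, "channel", contrasts)


def roi_group_stats(
    first_level_betas: pd.DataFrame,
    montage: Montage,
    contrasts: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """ROI-level group statistics.

    Per subject and condition, channel coefficients are averaged into ROI
    coefficients with the normalized montage spatial weights; the same
    mixed-effects contrast machinery then runs per ROI, with BH adjustment
    across the ROIs within each contrast.
    """
    contrasts = contrasts or default_contrasts(
        tuple(pd.unique(first_level_betas["condition"]))
    )
    rows = []
    for (subject, condition), sub in first_level_betas.groupby(
        ["subject", "condition"], sort=False
    ):
        values = sub.set_index("channel")["beta"]
        roi_vals = aggregate_to_roi(values, montage)
        for roi, val in roi_vals.items():
            rows.append(
                {"subject": subject, "roi": roi, "condition": condition, "beta": val}
            )
    roi_betas = pd.DataFrame(rows)
    return _mixed_model_rows(roi_betas, "roi", contrasts)


def significant_set(stats_df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with ``p_fdr < alpha``; pair with :func:`significant_counts`."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return stats_df[stats_df["p_fdr"] < alpha].copy()


def significant_counts(stats_df: pd.DataFrame, alpha: float = 0.05) -> dict[str, int]:
    """Number of significant channels/ROIs per contrast at ``alpha``."""
    sig = significant_set(stats_df, alpha)
    counts = {c: 0 for c in pd.unique(stats_df["contrast"])}
    counts.update(sig.groupby("contrast").size().to_dict())
    return counts
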