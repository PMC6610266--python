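"""Cohort comparison statistics for lobar imaging scores.

Mirrors the comparison structure used when validating lobar
hyperpolarized-gas ventilation against CT emphysema and V/Q-SPECT:
per-subject five-lobe Pearson correlations, pooled lobar ordinary
least squares regressions across the whole cohort (lobes pooled,
within-subject clustering deliberately ignored — plain OLS/Pearson is
what the field reports for these scatter plots, and the limitation is
documented rather than silently "fixed" with mixed models), and
whole-lung regressions against lung-function covariates (FEV1 %pred,
FEV1/FVC).  Two-sided p-values throughout; significance marked ``*``
at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lobar_scores import LOBE_NAMES, WHOLE_LUNG

__all__ = ["RegressionResult", "pearson_with_ci", "linear_regression", "run_cohort_comparison"]

#: (x column, y column) pairs pooled across lobes; x is the first-named axis.
POOLED_PAIRINGS = [
    ("ct_emphysema_pct", "hpx_rel_vent_pct"),
    ("ct_emphysema_pct", "hpx_abs_vent_pct"),
    ("ct_emphysema_pct", "spect_perf_pct"),
    ("ct_emphysema_pct", "spect_vent_pct"),
    ("hpx_rel_vent_pct", "spect_perf_pct"),
    ("hpx_rel_vent_pct", "spect_vent_pct"),
    ("spect_vent_pct", "spect_perf_pct"),
]

#: Per-subject 5-lobe correlations: emphysema against each relative score.
PER_SUBJECT_PAIRINGS = [
    ("ct_emphysema_pct", "hpx_rel_vent_pct"),
    ("ct_emphysema_pct", "spect_vent_pct"),
    ("ct_emphysema_pct", "spect_perf_pct"),
]


@dataclass
class RegressionResult:
    """OLS fit plus the Pearson correlation of the same pair."""

    slope: float
    slope_se: float
    intercept: float
    pearson_r: float
    p_value_r: float
    p_value_slope: float
    ci95_r: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")


def _validate_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} points, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def pearson_with_ci(x, y, confidence: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Product-moment correlation with t-test p-value and Fisher-z CI.

    Returns ``(r, p, (lo, hi))``.  Raises on zero variance (r is
    undefined).
    """
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), float(res.pvalue), (float(ci.low), float(ci.high))


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with slope SE and p-values.

    x is always the first-named variable of the comparison (the
    figure-axes convention: emphysema or the first modality on x).
    """
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance")
    ls = stats.linregress(x, y)
    if np.ptp(y) == 0:
        # horizontal line: r and its CI are undefined, slope is exact
        r, p_r, ci = 0.0, 1.0, (0.0, 0.0)
    else:
        r, p_r, ci = pearson_with_ci(x, y)
    return RegressionResult(
        slope=float(ls.slope),
        slope_se=float(ls.stderr),
        intercept=float(ls.intercept),
        pearson_r=r,
        p_value_r=p_r,
        p_value_slope=float(ls.pvalue),
        ci95_r=ci,
        n=len(x),
    )


def _star(p: float) -> str:
    return "*" if p < 0.05 else ""


def _result_row(res: RegressionResult | None, **keys) -> dict:
    row = dict(keys)
    if res is None:
        row.update(
            slope=np.nan, slope_se=np.nan, intercept=np.nan, pearson_r=np.nan,
            p_value_r=np.nan, p_value_slope=np.nan, ci95_low=np.nan, ci95_high=np.nan,
            n=0, note="not_computable",
        )
    else:
        row.update(
            slope=res.slope, slope_se=res.slope_se, intercept=res.intercept,
            pearson_r=res.pearson_r, p_value_r=res.p_value_r, p_value_slope=res.p_value_slope,
            ci95_low=res.ci95_r[0], ci95_high=res.ci95_r[1], n=res.n,
            note=_star(res.p_value_r),
        )
    return row


def _paired(df: pd.DataFrame, xcol: str, ycol: str) -> tuple[np.ndarray, np.ndarray]:
    sub = df[[xcol, ycol]].dropna()
    return sub[xcol].to_numpy(), sub[ycol].to_numpy()


def run_cohort_comparison(
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Full comparison report for a cohort score table.

    ``scores`` is the concatenation of per-subject lobar score tables
    (MultiIndex subject_id x lobe, whole-lung rows labelled ``WL``).
    Subjects missing a modality are excluded per-analysis; a pairing
    with fewer than 3 complete lobe pairs is reported as
    ``not_computable`` rather than dropped.

    Returns a dict with ``per_subject``, ``pooled`` and ``whole_lung``
    DataFrames plus a plain-text ``summary``.
    """
    if not isinstance(scores.index, pd.MultiIndex) or scores.index.names != ["subject_id", "lobe"]:
        raise ValueError("scores must be indexed by (subject_id, lobe)")
    subjects = scores.index.get_level_values("subject_id").unique()
    lobar = scores[scores.index.get_level_values("lobe") != WHOLE_LUNG]

    per_rows = []
    for sid in subjects:
        sub = lobar.loc[sid].reindex(list(LOBE_NAMES))
        for xcol, ycol in PER_SUBJECT_PAIRINGS:
            x, y = _paired(sub, xcol, ycol)
            res = None
            if len(x) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
                r, p, ci = pearson_with_ci(x, y)
                res = RegressionResult(np.nan, np.nan, np.nan, r, p, np.nan, ci, len(x))
            per_rows.append(_result_row(res, subject_id=sid, x=xcol, y=ycol))
    per_subject = pd.DataFrame(per_rows)

    pooled_rows = []
    for xcol, ycol in POOLED_PAIRINGS:
        x, y = _paired(lobar, xcol, ycol)
        res = linear_regression(x, y) if len(x) >= 3 and np.ptp(x) > 0 else None
        pooled_rows.append(_result_row(res, x=xcol, y=ycol))
    pooled = pd.DataFrame(pooled_rows)

    wl_rows = []
    if covariates is not None:
        wl = scores.xs(WHOLE_LUNG, level="lobe").join(covariates, how="inner")
        for score_col in ("hpx_abs_vent_pct", "ct_emphysema_pct"):
            for cov_col in ("fev1_pct_pred", "fev1_fvc_pct"):
                if cov_col not in wl.columns:
                    continue
                x, y = _paired(wl, score_col, cov_col)
                res = linear_regression(x, y) if len(x) >= 3 and np.ptp(x) > 0 else None
                wl_rows.append(_result_row(res, x=score_col, y=cov_col))
    whole_lung = pd.DataFrame(wl_rows)

    return {
        "per_subject": per_subject,
        "pooled": pooled,
        "whole_lung": whole_lung,
        "summary": _render_summary(per_subject, pooled, whole_lung),
    }


def _render_summary(per_subject: pd.DataFrame, pooled: pd.DataFrame, whole_lung: pd.DataFrame) -> str:
    lines = ["Pooled lobar regressions (all subjects, lobes pooled)", "=" * 54]
    for _, r in pooled.iterrows():
        if r["note"] == "not_computable":
            lines.append(f"{r['x']} vs {r['y']}: not computable (insufficient complete pairs)")
        else:
            lines.append(
                f"{r['x']} vs {r['y']}: slope = {r['slope']:.3f} +/- {r['slope_se']:.3f} "
                f"(p = {r['p_value_slope']:.3g}); r = {r['pearson_r']:.3f} "
                f"[{r['ci95_low']:.3f}, {r['ci95_high']:.3f}] (p = {r['p_value_r']:.3g}){r['note']} "
                f"n = {int(r['n'])}"
            )
    lines += ["", "Per-subject 5-lobe Pearson correlations", "=" * 40]
    for _, r in per_subject.iterrows():
        if r["note"] == "not_computable":
            lines.append(f"{r['subject_id']}: {r['x']} vs {r['y']}: not computable")
        else:
            lines.append(
                f"{r['subject_id']}: {r['x']} vs {r['y']}: r = {r['pearson_r']:.3f} "
                f"(p = {r['p_value_r']:.3g}){r['note']}"
            )
    if len(whole_lung):
        lines += ["", "Whole-lung scores vs lung function", "=" * 34]
        for _, r in whole_lung.iterrows():
            if r["note"] == "not_computable":
                lines.append(f"{r['x']} vs {r['y']}: not computable")
            else:
                lines.append(
                    f"{r['x']} vs {r['y']}: r = {r['pearson_r']:.3f} (p = {r['p_value_r']:.3g}){r['note']}, "
                    f"slope = {r['slope']:.3f}"
                )
    return "\n".join(lines)
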