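"""Descriptive and comparative statistics for dd-cfDNA cohorts.

Group contrasts use the two-sided Mann-Whitney U test (exact enumeration for
tiny groups, tie-corrected normal approximation otherwise) with
Benjamini-Hochberg correction across a declarative battery of subgroup
comparisons. Time trajectories of the cfDNA measures are smoothed by local
*quadratic* weighted least squares with tricube weights (LOWESS of degree 2).
Variability descriptives summarize inter- and intrapatient dispersion of
total cfDNA and the within-patient fold-change statistics
(median-to-maximum and minimum-to-maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort

__all__ = [
    "GroupComparison",
    "TrajectoryFit",
    "compare_groups",
    "bh_adjust",
    "lowess_fit",
    "variability_stats",
    "run_comparison_battery",
    "DEFAULT_BATTERY",
]

#: pooled group size at or below which the exact U distribution is used
_EXACT_N = 8


@dataclass
class GroupComparison:
    group_a_median: float
    group_b_median: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    u_statistic: float
    p_value: float
    p_adjusted: float | None = None
    n_a: int = 0
    n_b: int = 0
    method: str = ""


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two groups.

    Exact enumeration when both groups have at most 8 observations,
    otherwise the tie-corrected normal approximation with continuity
    correction. ``p_adjusted`` is left unset (see :func:`bh_adjust`).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if (a.size <= _EXACT_N and b.size <= _EXACT_N) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        group_a_median=float(np.median(a)),
        group_b_median=float(np.median(b)),
        iqr_a=tuple(np.percentile(a, [25, 75])),
        iqr_b=tuple(np.percentile(b, [25, 75])),
        u_statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class TrajectoryFit:
    """Fitted local-quadratic trajectory at the evaluation times."""

    eval_times: np.ndarray
    fitted_values: np.ndarray
    span: float
    degree: int = 2


def lowess_fit(times, values, span: float = 0.5, eval_times=None, degree: int = 2) -> TrajectoryFit:
    """Locally weighted polynomial regression (default quadratic, tricube).

    At each evaluation time the ``span`` fraction of nearest observations
    (by time distance) is fitted by weighted least squares of the given
    degree with tricube weights; the smoothed value is the local fit at that
    time. ``span`` must be in (0, 1]; at least max(5, degree+1) observations
    are required and each window must contain more than ``degree`` distinct
    times.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be aligned 1-d arrays")
    n = t.size
    if n < max(5, degree + 1):
        raise ValueError(f"need at least {max(5, degree + 1)} observations")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if eval_times is None:
        eval_times = np.unique(t)
    ev = np.sort(np.asarray(eval_times, dtype=float))
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    fitted = np.empty(ev.size)
    for i, t0 in enumerate(ev):
        d = np.abs(t - t0)
        order = np.argsort(d, kind="stable")[:k]
        dmax = d[order[-1]]
        if dmax == 0.0:
            window_y = y[d == 0.0]
            if np.ptp(window_y) == 0.0:
                fitted[i] = window_y[0]
                continue
            raise ValueError(f"degenerate design at t={t0}: all window times equal")
        w = (1.0 - np.clip(d[order] / dmax, 0.0, 1.0) ** 3) ** 3
        # keep the boundary point with a tiny weight so the design stays full
        w = np.maximum(w, 1e-9)
        tw = t[order] - t0
        if np.unique(tw).size <= degree:
            raise ValueError(f"degenerate design at t={t0}: too few distinct times")
        design = np.vander(tw, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[order] * sw, rcond=None)
        fitted[i] = coef[0]
    return TrajectoryFit(eval_times=ev, fitted_values=fitted, span=span, degree=degree)


@dataclass
class VariabilityStats:
    """Dispersion descriptives of one biomarker across a cohort."""

    interpatient_cv: float
    intrapatient_cv_mean: float
    max_over_median_percentiles: dict[str, float]
    max_over_median_max: float
    max_over_min_max: float
    n_patients: int
    n_multi_sample_patients: int


def variability_stats(cohort: Cohort, variable: str = "total_cfdna_cpml") -> VariabilityStats:
    """Inter-/intrapatient CVs and within-patient fold-change statistics.

    * interpatient CV: CV of per-patient mean levels across patients;
    * intrapatient CV: mean of per-patient CVs (patients with >= 2 samples);
    * fold changes per patient: max/median (with cohort 50th/75th percentiles
      and maximum) and max/min (maximum only).
    """
    df = cohort.frame
    grouped = df.groupby("patient_id", sort=False)[variable]
    means = grouped.mean().to_numpy()
    if means.size == 0:
        raise ValueError("empty cohort")
    inter_cv = float(means.std(ddof=1) / means.mean()) if means.size > 1 else 0.0
    cvs, fc_med, fc_min = [], [], []
    for _, vals in grouped:
        v = vals.to_numpy(float)
        if v.size >= 2:
            cvs.append(v.std(ddof=1) / v.mean())
            fc_med.append(v.max() / np.median(v))
            fc_min.append(v.max() / v.min())
    if not cvs:
        raise ValueError("no patient has >= 2 samples")
    fc_med = np.asarray(fc_med)
    return VariabilityStats(
        interpatient_cv=inter_cv,
        intrapatient_cv_mean=float(np.mean(cvs)),
        max_over_median_percentiles={
            "p50": float(np.percentile(fc_med, 50)),
            "p75": float(np.percentile(fc_med, 75)),
        },
        max_over_median_max=float(fc_med.max()),
        max_over_min_max=float(np.max(fc_min)),
        n_patients=int(means.size),
        n_multi_sample_patients=len(cvs),
    )


def _stratifier_masks(df: pd.DataFrame, stratifier: str) -> tuple[np.ndarray, np.ndarray, str, str]:
    if stratifier == "indication":
        return (
            (df["indication"] == "for_cause").to_numpy(),
            (df["indication"] == "surveillance").to_numpy(),
            "for_cause",
            "surveillance",
        )
    if stratifier == "dsa":
        return (
            (df["dsa"] == True).to_numpy(),  # noqa: E712 — NaN-safe comparison
            (df["dsa"] == False).to_numpy(),  # noqa: E712
            "dsa_positive",
            "dsa_negative",
        )
    if stratifier == "lvef":
        lvef = df["lvef_pct"].to_numpy(float)
        return (lvef < 40) & ~np.isnan(lvef), lvef >= 40, "lvef_lt40", "lvef_ge40"
    if stratifier == "cav":
        return (
            (df["cav"] == True).to_numpy(),  # noqa: E712
            (df["cav"] == False).to_numpy(),  # noqa: E712
            "cav_positive",
            "cav_negative",
        )
    raise ValueError(f"unknown stratifier {stratifier!r}")


#: (stratifier, biomarker) pairs of the subgroup comparison battery
DEFAULT_BATTERY: tuple[tuple[str, str], ...] = tuple(
    (s, v)
    for s in ("indication", "dsa", "lvef", "cav")
    for v in ("dd_cfdna_pct", "dqs_cpml")
)


def run_comparison_battery(
    cohort: Cohort, battery: Sequence[tuple[str, str]] = DEFAULT_BATTERY
) -> pd.DataFrame:
    """Mann-Whitney subgroup comparisons with BH correction across the battery.

    Returns one row per (stratifier, variable) with group medians, IQRs, raw
    and adjusted p-values. Pairs with an empty stratum are skipped.
    """
    rows = []
    df = cohort.frame
    for stratifier, variable in battery:
        mask_a, mask_b, name_a, name_b = _stratifier_masks(df, stratifier)
        if not mask_a.any() or not mask_b.any():
            continue
        cmp = compare_groups(df.loc[mask_a, variable], df.loc[mask_b, variable])
        rows.append(
            {
                "stratifier": stratifier,
                "group_a": name_a,
                "group_b": name_b,
                "variable": variable,
                "median_a": cmp.group_a_median,
                "median_b": cmp.group_b_median,
                "iqr_a_low": cmp.iqr_a[0],
                "iqr_a_high": cmp.iqr_a[1],
                "iqr_b_low": cmp.iqr_b[0],
                "iqr_b_high": cmp.iqr_b[1],
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "u_statistic": cmp.u_statistic,
                "p_value": cmp.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_value"].tolist())
    return out
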