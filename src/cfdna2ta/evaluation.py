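"""Diagnostic performance evaluation with patient-clustered bootstrap.

Repeated draws from the same patient are not independent, so confidence
intervals are built by a one-sample-per-patient bootstrap: in each of
``n_iterations`` (default 10,000) iterations exactly one sample is selected
uniformly at random from every patient, and sensitivity, specificity, AUC
and the subsample rejection prevalence are computed on that subsample.
Point estimates are means over defined draws; intervals are the 2.5th/97.5th
percentiles.

Predictive values are *not* raw column ratios: PPV and NPV are obtained by
Bayes' rule at the cohort rejection prevalence, taken here as the mean AR
fraction of the bootstrap subsamples (one draw per patient, so it sits
between the sample-level and patient-level prevalences).

The AUC of the two-threshold rule is computed conventionally by ranking the
surrogate score (see :mod:`cfdna2ta.classifier`); :func:`roc_auc` uses the
rank (Mann-Whitney) formulation with ties counted 1/2.

The net reclassification index (NRI) of a new rule over an old one is

    NRI = [P(up | AR) - P(down | AR)] + [P(down | non-AR) - P(up | non-AR)]

where "up" means reclassified negative-to-positive; it is bootstrapped on
the same one-sample-per-patient scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata

from .cohort import Cohort

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "BootstrapResult",
    "NriResult",
    "confusion",
    "metrics_from_confusion",
    "bootstrap_metrics",
    "roc_auc",
    "two_threshold_auc",
    "whole_cohort_nri",
    "nri",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    """Operating characteristics; an undefined metric is NaN with its reason
    recorded in ``notes`` (never a silent zero)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    prevalence_used: float
    auc: float | None = None
    notes: tuple[str, ...] = ()


def confusion(labels, calls) -> ConfusionCounts:
    """Standard 2x2 tally of boolean labels vs boolean calls."""
    labels = np.asarray(labels, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    if labels.shape != calls.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {calls.shape}")
    return ConfusionCounts(
        tp=int(np.sum(labels & calls)),
        fp=int(np.sum(~labels & calls)),
        tn=int(np.sum(~labels & ~calls)),
        fn=int(np.sum(labels & ~calls)),
    )


def _bayes_ppv(sens: float, spec: float, prev: float) -> float:
    num = sens * prev
    den = num + (1.0 - spec) * (1.0 - prev)
    return num / den if den > 0 else math.nan


def _bayes_npv(sens: float, spec: float, prev: float) -> float:
    num = spec * (1.0 - prev)
    den = num + (1.0 - sens) * prev
    return num / den if den > 0 else math.nan


def metrics_from_confusion(
    counts: ConfusionCounts,
    prevalence: float | None = None,
    auc: float | None = None,
) -> MetricSet:
    """MetricSet from a confusion table, with Bayes-rule PPV/NPV.

    ``prevalence`` defaults to the table's own positive fraction; supply the
    cohort prevalence to reproduce prevalence-standardized predictive values.
    """
    notes: list[str] = []
    sens = spec = math.nan
    if counts.tp + counts.fn > 0:
        sens = counts.tp / (counts.tp + counts.fn)
    else:
        notes.append("sensitivity undefined: no positive-class samples")
    if counts.tn + counts.fp > 0:
        spec = counts.tn / (counts.tn + counts.fp)
    else:
        notes.append("specificity undefined: no negative-class samples")
    if prevalence is None:
        prevalence = (counts.tp + counts.fn) / counts.total if counts.total else math.nan
    if not (0.0 < prevalence < 1.0):
        notes.append(f"predictive values undefined at prevalence {prevalence!r}")
        ppv = npv = math.nan
    else:
        ppv = _bayes_ppv(sens, spec, prevalence)
        npv = _bayes_npv(sens, spec, prevalence)
    if not math.isnan(spec) and spec < 1.0:
        lr_pos = sens / (1.0 - spec)
    else:
        lr_pos = math.inf if sens > 0 else math.nan
        notes.append("LR+ undefined or infinite: specificity = 1")
    if not math.isnan(spec) and spec > 0.0:
        lr_neg = (1.0 - sens) / spec
    else:
        lr_neg = math.nan
        notes.append("LR- undefined: specificity = 0")
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        prevalence_used=prevalence,
        auc=auc,
        notes=tuple(notes),
    )


def patient_choice_matrix(
    cohort: Cohort, n_iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_iterations, n_patients) positional sample indices: one uniformly
    chosen sample per patient per iteration (independent across iterations)."""
    groups = cohort.patient_groups()
    choices = np.empty((n_iterations, len(groups)), dtype=np.intp)
    for j, idx in enumerate(groups):
        choices[:, j] = idx[rng.integers(0, idx.size, size=n_iterations)]
    return choices


@dataclass
class BootstrapResult:
    """Per-iteration metric draws with point estimates and percentile CIs."""

    n_iterations: int
    seed: int
    draws: dict[str, np.ndarray]
    point_estimate: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    prevalence_used: float = math.nan
    n_undefined: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, d in self.draws.items():
            if d.shape != (self.n_iterations,):
                raise ValueError(f"draws[{name!r}] must have length n_iterations")
            defined = d[~np.isnan(d)]
            self.n_undefined[name] = self.n_iterations - defined.size
            if defined.size:
                self.point_estimate[name] = float(defined.mean())
                self.ci_low[name] = float(np.percentile(defined, 2.5))
                self.ci_high[name] = float(np.percentile(defined, 97.5))
            else:
                self.point_estimate[name] = math.nan
                self.ci_low[name] = math.nan
                self.ci_high[name] = math.nan

    def summary(self) -> dict:
        """JSON-serializable report."""
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "prevalence_used": self.prevalence_used,
            "metrics": {
                name: {
                    "estimate": self.point_estimate[name],
                    "ci95": [self.ci_low[name], self.ci_high[name]],
                    "n_undefined_iterations": self.n_undefined[name],
                }
                for name in sorted(self.draws)
            },
        }


def _auc_draws(scores: np.ndarray, labels: np.ndarray, choices: np.ndarray) -> np.ndarray:
    """AUC per bootstrap iteration via the rank formulation, vectorized over
    iterations; NaN where a subsample has a single class."""
    sub_scores = scores[choices]
    sub_labels = labels[choices]
    ranks = rankdata(sub_scores, axis=1)
    n_pos = sub_labels.sum(axis=1)
    n_neg = sub_labels.shape[1] - n_pos
    rank_sum_pos = np.where(sub_labels, ranks, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        auc = (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    auc[(n_pos == 0) | (n_neg == 0)] = np.nan
    return auc


def bootstrap_metrics(
    cohort: Cohort,
    rule: Callable[[np.ndarray, np.ndarray], np.ndarray],
    n_iterations: int = 10_000,
    seed: int = 0,
    score_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> BootstrapResult:
    """One-sample-per-patient bootstrap of a classification rule.

    ``rule(frac, dqs)`` returns boolean calls; ``score_fn(frac, dqs)``, if
    given, returns a continuous score from which a per-iteration AUC is
    computed. Iterations whose subsample contains no AR sample contribute to
    specificity only (their sensitivity draw is NaN, excluded from the mean
    and counted in ``n_undefined``).
    """
    if cohort.n_patients < 2:
        raise ValueError("bootstrap requires at least 2 patients")
    frac, dqs, _ = cohort.biomarkers()
    labels = cohort.labels()
    calls = np.asarray(rule(frac, dqs), dtype=bool)
    rng = np.random.default_rng(seed)
    choices = patient_choice_matrix(cohort, n_iterations, rng)

    sub_labels = labels[choices]
    sub_calls = calls[choices]
    n_patients = choices.shape[1]
    tp = np.sum(sub_labels & sub_calls, axis=1, dtype=float)
    n_pos = sub_labels.sum(axis=1, dtype=float)
    fp = np.sum(~sub_labels & sub_calls, axis=1, dtype=float)
    n_neg = n_patients - n_pos
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(n_pos > 0, tp / n_pos, np.nan)
        spec = np.where(n_neg > 0, 1.0 - fp / n_neg, np.nan)
    prevalence = n_pos / n_patients
    prevalence_used = float(prevalence.mean())

    ppv = np.array([_bayes_ppv(s, p, prevalence_used) for s, p in zip(sens, spec)])
    npv = np.array([_bayes_npv(s, p, prevalence_used) for s, p in zip(sens, spec)])
    draws = {
        "sensitivity": sens,
        "specificity": spec,
        "prevalence": prevalence,
        "ppv": ppv,
        "npv": npv,
    }
    if score_fn is not None:
        scores = np.asarray(score_fn(frac, dqs), dtype=float)
        draws["auc"] = _auc_draws(scores, labels, choices)
    return BootstrapResult(
        n_iterations=n_iterations,
        seed=seed,
        draws=draws,
        prevalence_used=prevalence_used,
    )


def roc_auc(scores, labels) -> float:
    """AUC = P(random positive outscores random negative), ties counted 1/2.

    Rank (Mann-Whitney) formulation; agrees exactly with all-pairs counting.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[labels].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def two_threshold_auc(cohort: Cohort, thresholds, spec=None) -> float:
    """Full-cohort AUC of the 2TA via the surrogate score.

    Ranks the (monotone) log surrogate score, so arbitrarily large threshold
    ratios cannot overflow.
    """
    from .classifier import SurrogateSpec, surrogate_log_score

    spec = spec or SurrogateSpec()
    frac, dqs, _ = cohort.biomarkers()
    scores = surrogate_log_score(frac, dqs, thresholds, spec)
    return roc_auc(scores, cohort.labels())


def whole_cohort_nri(labels, calls_new, calls_old) -> float:
    """Non-bootstrap NRI of rule_new over rule_old on aligned call vectors."""
    labels = np.asarray(labels, dtype=bool)
    calls_new = np.asarray(calls_new, dtype=bool)
    calls_old = np.asarray(calls_old, dtype=bool)
    up = calls_new & ~calls_old
    down = ~calls_new & calls_old
    n_ev = labels.sum()
    n_ne = labels.size - n_ev
    if n_ev == 0 or n_ne == 0:
        raise ValueError("NRI requires both classes present")
    event_term = (up[labels].sum() - down[labels].sum()) / n_ev
    nonevent_term = (down[~labels].sum() - up[~labels].sum()) / n_ne
    return float(event_term + nonevent_term)


@dataclass
class NriResult:
    mean: float
    sd: float
    p_value: float
    n_iterations: int
    seed: int
    draws: np.ndarray
    n_undefined: int = 0

    def summary(self) -> dict:
        return {
            "nri_mean": self.mean,
            "nri_sd": self.sd,
            "p_value": self.p_value,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "n_undefined_iterations": self.n_undefined,
        }


def nri(
    cohort: Cohort,
    rule_new: Callable,
    rule_old: Callable,
    n_iterations: int = 10_000,
    seed: int = 0,
    p_value_method: str = "bootstrap",
) -> NriResult:
    """Bootstrapped net reclassification index of ``rule_new`` over ``rule_old``.

    One sample per patient per iteration (same scheme as
    :func:`bootstrap_metrics`). The two-sided p-value for NRI = 0 is the
    bootstrap tail probability ``2 * min(P(draw <= 0), P(draw >= 0))``
    (capped at 1); ``p_value_method="normal"`` uses a normal approximation
    mean/sd instead.
    """
    if cohort.n_patients < 2:
        raise ValueError("bootstrap requires at least 2 patients")
    frac, dqs, _ = cohort.biomarkers()
    labels = cohort.labels()
    calls_new = np.asarray(rule_new(frac, dqs), dtype=bool)
    calls_old = np.asarray(rule_old(frac, dqs), dtype=bool)
    up = calls_new & ~calls_old
    down = ~calls_new & calls_old
    rng = np.random.default_rng(seed)
    choices = patient_choice_matrix(cohort, n_iterations, rng)

    sub_labels = labels[choices]
    sub_up = up[choices]
    sub_down = down[choices]
    n_ev = sub_labels.sum(axis=1, dtype=float)
    n_ne = choices.shape[1] - n_ev
    up_ev = np.sum(sub_up & sub_labels, axis=1, dtype=float)
    down_ev = np.sum(sub_down & sub_labels, axis=1, dtype=float)
    up_ne = np.sum(sub_up & ~sub_labels, axis=1, dtype=float)
    down_ne = np.sum(sub_down & ~sub_labels, axis=1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        draws = np.where(n_ev > 0, (up_ev - down_ev) / np.where(n_ev > 0, n_ev, 1), np.nan)
        draws = draws + np.where(n_ne > 0, (down_ne - up_ne) / np.where(n_ne > 0, n_ne, 1), np.nan)
    defined = draws[~np.isnan(draws)]
    if defined.size == 0:
        raise ValueError("no bootstrap iteration had both classes present")
    mean = float(defined.mean())
    sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    if p_value_method == "normal":
        from scipy.stats import norm

        p = 1.0 if sd == 0 and mean == 0 else float(2.0 * norm.sf(abs(mean) / sd)) if sd > 0 else 0.0
    else:
        p = float(min(1.0, 2.0 * min(np.mean(defined <= 0.0), np.mean(defined >= 0.0))))
    return NriResult(
        mean=mean,
        sd=sd,
        p_value=p,
        n_iterations=n_iterations,
        seed=seed,
        draws=draws,
        n_undefined=int(np.isnan(draws).sum()),
    )
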