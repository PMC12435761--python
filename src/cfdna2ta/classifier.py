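"""Decision rules on the dd-cfDNA biomarker pair.

The two-threshold algorithm (2TA) calls a sample positive when *either*
dd-cfDNA% exceeds its cutoff C1 *or* DQS exceeds its cutoff C2 (strict
inequality: a value exactly at a cutoff is negative). The single-threshold
comparator uses dd-cfDNA% alone.

For ROC construction the OR-rule is replaced by the smooth surrogate score

    s = (dd-cfDNA% / C1)^n + (DQS / C2)^n,   n > 20,

whose level set s = 1 approximates the 2TA decision boundary: for samples
whose threshold ratios are not both in a thin band around 1, (s > 1) agrees
exactly with the 2TA call, so ranking by s yields a conventional ROC curve
for the two-threshold rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ThresholdPair",
    "SurrogateSpec",
    "classify_2ta",
    "classify_single",
    "surrogate_score",
    "surrogate_log_score",
    "two_threshold_rule",
    "single_threshold_rule",
]


@dataclass(frozen=True)
class ThresholdPair:
    """2TA cutoffs: ``c_frac`` on dd-cfDNA% (percent), ``c_dqs`` on DQS (cp/mL).

    Both must be strictly positive and not NaN. ``c_dqs = inf`` is admitted as
    the degenerate pair under which the 2TA collapses to the single-threshold
    fraction rule.
    """

    c_frac: float
    c_dqs: float

    def __post_init__(self) -> None:
        for name in ("c_frac", "c_dqs"):
            v = getattr(self, name)
            if np.isnan(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class SurrogateSpec:
    """Exponent of the surrogate score; must exceed 20 for the level-set
    approximation of the OR-rule to hold away from the boundary."""

    exponent_n: int = 30

    def __post_init__(self) -> None:
        if self.exponent_n <= 20:
            raise ValueError(f"exponent_n must be > 20, got {self.exponent_n}")


def _check_inputs(*arrays: np.ndarray) -> None:
    for a in arrays:
        if np.any(np.isnan(a)) or np.any(np.isinf(a)) or np.any(a < 0):
            raise ValueError("biomarker inputs must be finite and nonnegative")


def classify_2ta(frac, dqs, thresholds: ThresholdPair):
    """2TA call: positive iff frac > C1 or dqs > C2 (strict). Vectorized."""
    frac = np.asarray(frac, dtype=float)
    dqs = np.asarray(dqs, dtype=float)
    _check_inputs(frac, dqs)
    out = (frac > thresholds.c_frac) | (dqs > thresholds.c_dqs)
    return bool(out) if out.ndim == 0 else out


def classify_single(frac, cutoff: float):
    """Fraction-only call: positive iff frac > cutoff (strict). Vectorized."""
    frac = np.asarray(frac, dtype=float)
    _check_inputs(frac)
    out = frac > cutoff
    return bool(out) if out.ndim == 0 else out


def two_threshold_rule(thresholds: ThresholdPair) -> Callable:
    """Bind thresholds into a ``rule(frac, dqs) -> bool array`` callable."""
    return lambda frac, dqs: classify_2ta(frac, dqs, thresholds)


def single_threshold_rule(cutoff: float) -> Callable:
    """Fraction-only rule with the 2TA callable signature (dqs ignored)."""
    return lambda frac, dqs: classify_single(frac, cutoff)


def surrogate_log_score(frac, dqs, thresholds: ThresholdPair, spec: SurrogateSpec = SurrogateSpec()):
    """log of the surrogate score; -inf where both biomarkers are zero.

    Computed via the max-term factorization
    ``max^n * (1 + (min/max)^n)`` in the log domain, so ratios of hundreds at
    n = 30 are exact where the naive power would overflow. The log score is a
    strictly monotone transform of the score and is the preferred quantity
    for ranking (ROC) purposes.
    """
    frac = np.atleast_1d(np.asarray(frac, dtype=float))
    dqs = np.atleast_1d(np.asarray(dqs, dtype=float))
    _check_inputs(frac, dqs)
    n = spec.exponent_n
    r1 = frac / thresholds.c_frac
    r2 = dqs / thresholds.c_dqs
    hi = np.maximum(r1, r2)
    lo = np.minimum(r1, r2)
    out = np.full(np.broadcast(r1, r2).shape, -np.inf)
    nz = hi > 0
    with np.errstate(divide="ignore"):
        ratio = np.where(nz, lo / np.where(nz, hi, 1.0), 0.0)
        out[nz] = n * np.log(hi[nz]) + np.log1p(ratio[nz] ** n)
    return out


def surrogate_score(frac, dqs, thresholds: ThresholdPair, spec: SurrogateSpec = SurrogateSpec()):
    """Surrogate score (frac/C1)^n + (dqs/C2)^n, overflow-safe.

    Scores may be astronomically large for samples far above threshold; such
    values saturate to ``inf`` only beyond ~1e308 (threshold ratios above
    ~e^(709/n)), far outside the biomarker range. Score > 1 corresponds to a
    positive 2TA call away from the threshold boundary.
    """
    scalar = np.ndim(frac) == 0 and np.ndim(dqs) == 0
    log_s = surrogate_log_score(frac, dqs, thresholds, spec)
    with np.errstate(over="ignore"):
        out = np.exp(log_s)
    return float(out[0]) if scalar else out
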