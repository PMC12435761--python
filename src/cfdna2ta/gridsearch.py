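"""Exhaustive two-dimensional threshold optimization for the 2TA.

The threshold grid spans DQS cutoffs 8–35 cp/mL in 1 cp/mL steps and
dd-cfDNA% cutoffs 0.10–0.50% in 0.01% steps (28 x 41 = 1,148 pairs by
default). For every pair the rule's sensitivity and specificity are
bootstrapped one-sample-per-patient; the objective is their sum (Youden-style)
and threshold selection proceeds by identifying local maxima of the objective
surface and applying a (pluggable) clinical-adequacy policy.

Two deliberate variance-reduction / tractability choices:

* one *shared* set of bootstrap subsamples is drawn once from the seed and
  reused at every grid point, so the metric surface is smooth in the
  thresholds (changing the grid point changes nothing about the resampling);
* the per-pair, per-iteration tallies are computed as one matrix product
  between the iteration-by-sample choice-count matrix and the
  sample-by-pair boolean call matrix, instead of 1,148 independent bootstrap
  loops.

The per-pair AUC column reports the full-cohort surrogate-score AUC (the
objective never uses it); a bootstrap AUC is computed downstream for the
selected pair only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .classifier import SurrogateSpec, ThresholdPair, surrogate_log_score
from .cohort import Cohort, AR_ACR_GRADES, AR_PAMR_GRADES
from .evaluation import patient_choice_matrix, roc_auc

__all__ = [
    "GridSpec",
    "GridResult",
    "build_grid",
    "evaluate_grid",
    "find_local_maxima",
    "select_thresholds",
]


@dataclass(frozen=True)
class GridSpec:
    """Threshold grid: values enumerated by integer index (min + k*step), both
    endpoints inclusive, so the pair count is exact with no float drift."""

    dqs_min: float = 8.0
    dqs_max: float = 35.0
    dqs_step: float = 1.0
    frac_min: float = 0.10
    frac_max: float = 0.50
    frac_step: float = 0.01

    def __post_init__(self) -> None:
        if self.dqs_step <= 0 or self.frac_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.dqs_min > self.dqs_max or self.frac_min > self.frac_max:
            raise ValueError("grid min must not exceed max")

    @property
    def n_dqs(self) -> int:
        return int(round((self.dqs_max - self.dqs_min) / self.dqs_step)) + 1

    @property
    def n_frac(self) -> int:
        return int(round((self.frac_max - self.frac_min) / self.frac_step)) + 1

    @property
    def n_pairs(self) -> int:
        return self.n_dqs * self.n_frac

    def dqs_values(self) -> np.ndarray:
        return self.dqs_min + self.dqs_step * np.arange(self.n_dqs)

    def frac_values(self) -> np.ndarray:
        return self.frac_min + self.frac_step * np.arange(self.n_frac)


def build_grid(spec: GridSpec) -> list[ThresholdPair]:
    """All threshold pairs, frac-major order (matches the result table)."""
    pairs = [
        ThresholdPair(c_frac=float(f), c_dqs=float(d))
        for f in spec.frac_values()
        for d in spec.dqs_values()
    ]
    if not pairs:
        raise ValueError("empty grid")
    return pairs


@dataclass
class GridResult:
    """Bootstrap metric surface over the grid plus maxima and selection.

    ``table`` has one row per pair (frac-major order) with columns c_frac,
    c_dqs, sensitivity/specificity summaries and CIs, auc, objective.
    """

    spec: GridSpec
    table: pd.DataFrame
    objective: str = "sensitivity+specificity"
    local_maxima: list[ThresholdPair] = field(default_factory=list)
    selected: ThresholdPair | None = None
    n_iterations: int = 0
    seed: int = 0

    def objective_surface(self) -> np.ndarray:
        """(n_frac, n_dqs) objective matrix in grid order."""
        return self.table["objective"].to_numpy().reshape(self.spec.n_frac, self.spec.n_dqs)

    def pair_at(self, i_frac: int, j_dqs: int) -> ThresholdPair:
        return ThresholdPair(
            float(self.spec.frac_values()[i_frac]), float(self.spec.dqs_values()[j_dqs])
        )

    def summary(self) -> dict:
        return {
            "objective": self.objective,
            "n_pairs": int(len(self.table)),
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "local_maxima": [[p.c_frac, p.c_dqs] for p in self.local_maxima],
            "selected": None if self.selected is None
            else [self.selected.c_frac, self.selected.c_dqs],
        }


def evaluate_grid(
    cohort: Cohort,
    spec: GridSpec = GridSpec(),
    n_iterations: int = 10_000,
    seed: int = 0,
    surrogate: SurrogateSpec = SurrogateSpec(),
    compute_auc: bool = True,
) -> GridResult:
    """Bootstrap sensitivity/specificity of the 2TA at every grid pair.

    All pairs share one choice of bootstrap subsamples (drawn from ``seed``),
    making the surface smooth in the thresholds.
    """
    frac, dqs, _ = cohort.biomarkers()
    labels = cohort.labels()
    if not labels.any() or labels.all():
        raise ValueError("grid evaluation requires both AR and non-AR samples")
    rng = np.random.default_rng(seed)
    choices = patient_choice_matrix(cohort, n_iterations, rng)
    n_patients = choices.shape[1]

    # iteration-by-sample choice-count matrix (row sums = n_patients)
    count_m = np.zeros((n_iterations, len(labels)), dtype=np.float32)
    np.add.at(count_m, (np.arange(n_iterations)[:, None], choices), 1.0)

    fvals = spec.frac_values()
    dvals = spec.dqs_values()
    # sample x pair call matrix, frac-major pair order
    calls = (
        (frac[:, None, None] > fvals[None, :, None])
        | (dqs[:, None, None] > dvals[None, None, :])
    ).reshape(len(labels), -1).astype(np.float32)

    lab_f = labels.astype(np.float32)[:, None]
    tp = count_m @ (calls * lab_f)  # (n_iter, n_pairs)
    pos_calls = count_m @ calls
    n_pos = count_m @ lab_f  # (n_iter, 1)
    fp = pos_calls - tp
    n_neg = n_patients - n_pos
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(n_pos > 0, tp / n_pos, np.nan)
        spec_draws = np.where(n_neg > 0, 1.0 - fp / n_neg, np.nan)

    sens_mean = np.nanmean(sens, axis=0)
    spec_mean = np.nanmean(spec_draws, axis=0)
    sens_lo, sens_hi = np.nanpercentile(sens, [2.5, 97.5], axis=0)
    spec_lo, spec_hi = np.nanpercentile(spec_draws, [2.5, 97.5], axis=0)

    pairs_f = np.repeat(fvals, dvals.size)
    pairs_d = np.tile(dvals, fvals.size)
    auc = np.full(pairs_f.size, np.nan)
    if compute_auc:
        for k, (c1, c2) in enumerate(zip(pairs_f, pairs_d)):
            scores = surrogate_log_score(frac, dqs, ThresholdPair(float(c1), float(c2)), surrogate)
            auc[k] = roc_auc(scores, labels)

    table = pd.DataFrame(
        {
            "c_frac": pairs_f,
            "c_dqs": pairs_d,
            "sensitivity": sens_mean,
            "sensitivity_ci_low": sens_lo,
            "sensitivity_ci_high": sens_hi,
            "specificity": spec_mean,
            "specificity_ci_low": spec_lo,
            "specificity_ci_high": spec_hi,
            "auc": auc,
            "objective": sens_mean + spec_mean,
        }
    )
    return GridResult(
        spec=spec, table=table, n_iterations=n_iterations, seed=seed
    )


def find_local_maxima(
    grid_result: GridResult, objective: str = "objective"
) -> list[ThresholdPair]:
    """Grid points whose objective is >= all existing 8-neighbors.

    Adjacent equal-valued maxima (plateaus) are merged into one
    representative — the cell with the largest c_frac, then largest c_dqs —
    and the result is sorted by objective descending. Mutates
    ``grid_result.local_maxima``.
    """
    surf = grid_result.table[objective].to_numpy().reshape(
        grid_result.spec.n_frac, grid_result.spec.n_dqs
    )
    neighborhood_max = ndimage.maximum_filter(surf, size=3, mode="constant", cval=-np.inf)
    mask = surf >= neighborhood_max  # equality: >= all neighbors incl. plateaus
    lab, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    reps: list[tuple[float, ThresholdPair]] = []
    for comp in range(1, n_comp + 1):
        ii, jj = np.nonzero(lab == comp)
        k = np.lexsort((jj, ii))[-1]  # largest c_frac index, then c_dqs
        reps.append((float(surf[ii[k], jj[k]]), grid_result.pair_at(int(ii[k]), int(jj[k]))))
    reps.sort(key=lambda t: (-t[0], -t[1].c_frac, -t[1].c_dqs))
    grid_result.local_maxima = [p for _, p in reps]
    return grid_result.local_maxima


def _arm_sensitivities(cohort: Cohort, pair: ThresholdPair) -> tuple[float, float]:
    """Full-cohort ACR-arm and AMR-arm sensitivity of the 2TA at ``pair``.

    A sample belongs to the ACR arm if its ACR grade is 2R/3R and to the AMR
    arm if its pAMR grade is 1H+/1I+/2/3 (mixed rejection counts in both).
    Returns NaN for an arm with no samples.
    """
    frac, dqs, _ = cohort.biomarkers()
    calls = (frac > pair.c_frac) | (dqs > pair.c_dqs)
    acr = cohort.frame["acr_grade"].isin(AR_ACR_GRADES).to_numpy()
    amr = cohort.frame["pamr_grade"].isin(AR_PAMR_GRADES).to_numpy()
    acr_sens = float(calls[acr].mean()) if acr.any() else np.nan
    amr_sens = float(calls[amr].mean()) if amr.any() else np.nan
    return acr_sens, amr_sens


def select_thresholds(
    grid_result: GridResult,
    cohort: Cohort,
    policy: Callable[[GridResult, Cohort, Sequence[ThresholdPair]], ThresholdPair] | None = None,
    arm_sensitivity_floor: float = 0.5,
) -> ThresholdPair:
    """Pick the operating thresholds among the local maxima.

    Default policy: keep maxima whose full-cohort ACR-arm and AMR-arm
    sensitivities both exceed ``arm_sensitivity_floor`` (an arm with no
    samples is vacuously adequate), then take the highest objective; ties
    break toward larger c_frac, then larger c_dqs (fewer positive calls). If
    no maximum clears the floor, fall back to the highest objective with a
    warning. Mutates ``grid_result.selected``.
    """
    maxima = grid_result.local_maxima
    if not maxima:
        raise ValueError("no local maxima: run find_local_maxima first")
    if policy is not None:
        selected = policy(grid_result, cohort, maxima)
    else:
        obj = {
            (p.c_frac, p.c_dqs): float(
                grid_result.table.loc[
                    (grid_result.table["c_frac"] == p.c_frac)
                    & (grid_result.table["c_dqs"] == p.c_dqs),
                    "objective",
                ].iloc[0]
            )
            for p in maxima
        }
        adequate = []
        for p in maxima:
            acr_s, amr_s = _arm_sensitivities(cohort, p)
            ok_acr = np.isnan(acr_s) or acr_s > arm_sensitivity_floor
            ok_amr = np.isnan(amr_s) or amr_s > arm_sensitivity_floor
            if ok_acr and ok_amr:
                adequate.append(p)
        if not adequate:
            warnings.warn(
                "no local maximum clears the arm-sensitivity floor "
                f"{arm_sensitivity_floor}; falling back to highest objective",
                stacklevel=2,
            )
            adequate = list(maxima)
        adequate.sort(key=lambda p: (obj[(p.c_frac, p.c_dqs)], p.c_frac, p.c_dqs), reverse=True)
        selected = adequate[0]
    grid_result.selected = selected
    return selected
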