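# cfdna2ta

Evaluation pipeline for a **two-threshold algorithm (2TA)** that detects acute
rejection (AR) after heart transplantation from donor-derived cell-free DNA:
a biopsy-matched blood draw is called positive when **either** the donor
fraction **or** the donor quantity exceeds its cutoff,

```
positive  ⇔  dd-cfDNA% > C₁   or   DQS > C₂        (default C₁ = 0.26 %, C₂ = 18 cp/mL)
```

where dd-cfDNA% is donor-derived cell-free DNA as a percentage of total
plasma cfDNA and DQS (donor-quantity score) is its absolute concentration in
genomic copies/mL. The two are linked through total cfDNA by
`dd-cfDNA% = 100 · DQS / total cfDNA`: a spike in recipient-derived cfDNA
(infection, surgery, dialysis) dilutes the fraction and can mask rejection,
while the absolute quantity is unaffected — which is exactly the failure mode
the OR-rule repairs relative to the conventional fraction-only cutoff
(0.15 %).

The package is aimed at biostatisticians evaluating non-invasive rejection
surveillance rules on patient-clustered cohort data. It provides:

- **`cohort`** — the cohort data model: biopsy grade semantics (ACR 0/1R/2R/3R,
  pAMR 0/1H+/1I+/2/3), AR labeling (AR = ACR ≥ 2R or pAMR ≥ 1), eligibility
  filtering (draws < 28 days post-transplant excluded), CSV/TSV round-trips.
- **`simulate`** — a synthetic patient-clustered cohort generator emulating
  the study conditions (187 patients, 1–14 draws each, ~5.1 % sample-level AR
  prevalence, lognormal biomarkers), plus a large-sample Monte-Carlo oracle
  for the true operating characteristics of any rule under the generative
  model.
- **`classifier`** — the 2TA, the fraction-only comparator, and the smooth
  surrogate score `(dd-cfDNA%/C₁)ⁿ + (DQS/C₂)ⁿ` (n > 20) whose unit level
  set reproduces the OR-rule decision boundary, enabling conventional ROC
  analysis of a two-threshold rule.
- **`evaluation`** — confusion metrics with Bayes-rule PPV/NPV at a supplied
  prevalence, the **one-sample-per-patient bootstrap** (10,000 iterations;
  exactly one uniformly chosen draw per patient per iteration) for clustered
  confidence intervals, rank-based ROC AUC, and the net reclassification
  index (NRI).
- **`gridsearch`** — exhaustive threshold optimization over the 28 × 41 =
  1,148-pair cutoff grid (DQS 8–35 cp/mL by 1; dd-cfDNA% 0.10–0.50 % by
  0.01) with one shared set of bootstrap subsamples across all pairs, local
  maxima of sensitivity + specificity, and a pluggable selection policy that
  requires adequate detection of both the cellular and antibody-mediated
  rejection arms.
- **`stats`** — Mann–Whitney group contrasts with Benjamini–Hochberg
  correction, locally *quadratic* LOWESS (tricube weights) time
  trajectories, and inter-/intrapatient variability descriptives.
- **`pipeline` / `cli`** — end-to-end orchestration with deterministic
  seeding (`cfdna2ta simulate|optimize|evaluate|run|describe|report`).

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_cohort_statistics.py
python analysis/03_optimize_thresholds.py --iterations 1000
python analysis/04_evaluate_2ta.py --iterations 5000
python analysis/05_compare_rules.py --iterations 5000
```

Output of the seed-1 run (abridged):

```
wrote 756 samples / 187 patients to results/cohort.csv
dd-cfDNA%: AR median 0.927 (IQR 0.0899-2.19) vs non-AR 0.0466 (0.0175-0.129), p = 8.41e-14
DQS:       AR median 63.9  (IQR 5.85-152)    vs non-AR 3.08   (1.14-7.23),    p = 1.9e-13
evaluating 1148 threshold pairs at 1000 iterations each (shared subsamples) ...
16 local maxima of sensitivity+specificity
selected pair: (0.50%, 35 cp/mL)
2ta: sensitivity 64.6% (37.5-88.9), specificity 85.0% (80.7-89.3), AUC 0.837,
     PPV 17.0%, NPV 98.1% at prevalence 4.49%
fixture reclassification: FP 126 -> 79 (37.3% reduction), TN 641 -> 688,
     TP/FN unchanged at 30/11; whole-cohort NRI 6.13%
```

Reading this: the generator reproduces the intended AR/non-AR biomarker
contrasts (medians ~0.9 % vs ~0.05 % and ~64 vs ~3 cp/mL); the bootstrap
intervals are wide on sensitivity because only ~30 patients ever reject; the
grid search lands on the high-specificity corner of the cutoff grid for this
particular synthetic cohort (threshold choice is cohort-dependent — see
`docs/methods.md`); and on the deterministic worked-example fixture the 2TA
removes 37.3 % of the fraction-only rule's false positives without touching
a single true positive.

The same machinery is importable directly:

```python
from cfdna2ta import SyntheticConfig, ThresholdPair, generate_cohort, \
    bootstrap_metrics, two_threshold_rule

cohort = generate_cohort(SyntheticConfig(), seed=1)
res = bootstrap_metrics(cohort, two_threshold_rule(ThresholdPair(0.26, 18.0)),
                        n_iterations=10_000, seed=2)
print(res.point_estimate["sensitivity"], res.ci_low["sensitivity"])
```

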