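"""Bootstrap the 2TA and the fraction-only comparator on the cohort.

Evaluates the two-threshold rule at (0.26%, 18 cp/mL) and the 0.15%
fraction-only rule by the one-sample-per-patient bootstrap: sensitivity,
specificity, surrogate-score AUC, and Bayes-rule PPV/NPV at the mean
subsample prevalence. Writes results/bootstrap_2ta.json and
results/bootstrap_comparator.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cfdna2ta import (
    SurrogateSpec,
    ThresholdPair,
    bootstrap_metrics,
    read_cohort,
    single_threshold_rule,
    two_threshold_rule,
)
from cfdna2ta.classifier import surrogate_log_score

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    parser.add_argument("--c-frac", type=float, default=0.26)
    parser.add_argument("--c-dqs", type=float, default=18.0)
    parser.add_argument("--comparator-cutoff", type=float, default=0.15)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--iterations", type=int, default=10_000)
    args = parser.parse_args()

    cohort = read_cohort(args.cohort)
    pair = ThresholdPair(args.c_frac, args.c_dqs)
    runs = {
        "2ta": (
            two_threshold_rule(pair),
            lambda f, d: surrogate_log_score(f, d, pair, SurrogateSpec()),
            RESULTS / "bootstrap_2ta.json",
        ),
        "comparator": (
            single_threshold_rule(args.comparator_cutoff),
            lambda f, d: np.asarray(f, dtype=float),
            RESULTS / "bootstrap_comparator.json",
        ),
    }
    for name, (rule, score, path) in runs.items():
        res = bootstrap_metrics(cohort, rule, args.iterations, seed=args.seed, score_fn=score)
        path.write_text(json.dumps(res.summary(), indent=2, sort_keys=True) + "\n")
        m = res.point_estimate
        print(
            f"{name}: sensitivity {100 * m['sensitivity']:.1f}% "
            f"({100 * res.ci_low['sensitivity']:.1f}-{100 * res.ci_high['sensitivity']:.1f}), "
            f"specificity {100 * m['specificity']:.1f}% "
            f"({100 * res.ci_low['specificity']:.1f}-{100 * res.ci_high['specificity']:.1f}), "
            f"AUC {m['auc']:.3f}, PPV {100 * m['ppv']:.1f}%, NPV {100 * m['npv']:.1f}% "
            f"at prevalence {100 * res.prevalence_used:.2f}%"
        )


if __name__ == "__main__":
    main()
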