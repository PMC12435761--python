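"""Descriptive statistics of the cohort: group contrasts and time trends.

Reads results/cohort.csv (run 01_simulate_cohort.py first, or point --cohort
at a real table in the documented schema). Writes the subgroup comparison
battery (Mann-Whitney + Benjamini-Hochberg) to results/comparisons.csv and
LOWESS trajectories of the three cfDNA measures among stable patients to
results/trajectory_<variable>.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cfdna2ta import compare_groups, lowess_fit, read_cohort, run_comparison_battery

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    parser.add_argument("--span", type=float, default=0.5)
    args = parser.parse_args()

    cohort = read_cohort(args.cohort)
    labels = cohort.labels()
    frac, dqs, _ = cohort.biomarkers()

    for name, values in (("dd-cfDNA%", frac), ("DQS", dqs)):
        cmp = compare_groups(values[labels], values[~labels])
        print(
            f"{name}: AR median {cmp.group_a_median:.3g} "
            f"(IQR {cmp.iqr_a[0]:.3g}-{cmp.iqr_a[1]:.3g}) vs non-AR "
            f"{cmp.group_b_median:.3g} ({cmp.iqr_b[0]:.3g}-{cmp.iqr_b[1]:.3g}), "
            f"p = {cmp.p_value:.3g}"
        )

    battery = run_comparison_battery(cohort)
    battery.to_csv(RESULTS / "comparisons.csv", index=False)
    print(f"\nsubgroup battery ({len(battery)} comparisons) -> results/comparisons.csv")
    sig = battery[battery["p_adjusted"] < 0.05]
    print(f"significant after BH at 0.05: {len(sig)} of {len(battery)}")

    # trajectories among stable patients (never AR, no CAV on record)
    df = cohort.frame
    ar_by_patient = pd.Series(labels, index=df.index).groupby(df["patient_id"]).transform("max")
    stable = (~ar_by_patient.astype(bool)) & (df["cav"] != True)  # noqa: E712
    sub = df.loc[stable]
    t = sub["days_post_tx"].to_numpy(float)
    ev = np.linspace(t.min(), t.max(), 80)
    for var in ("dd_cfdna_pct", "dqs_cpml", "total_cfdna_cpml"):
        fit = lowess_fit(t, sub[var].to_numpy(float), span=args.span, eval_times=ev)
        pd.DataFrame({"days_post_tx": fit.eval_times, "fitted": fit.fitted_values}).to_csv(
            RESULTS / f"trajectory_{var}.csv", index=False
        )
    print(f"LOWESS trajectories (span {args.span}) over {stable.sum()} stable-patient samples "
          "-> results/trajectory_*.csv")


if __name__ == "__main__":
    main()
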