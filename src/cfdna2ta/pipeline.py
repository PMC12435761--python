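"""End-to-end orchestration: simulate/load -> optimize -> evaluate -> compare -> report.

Each stage is a pure function of (inputs, config, seed); a run writes
machine-readable artifacts (JSON/CSV) plus a manifest with the config hash
and seeds so a run is reproducible bit-for-bit at fixed seeds (the manifest
timestamp is the only non-deterministic output).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import SurrogateSpec, ThresholdPair, single_threshold_rule, two_threshold_rule, surrogate_log_score
from .cohort import Cohort, read_cohort
from .evaluation import bootstrap_metrics, confusion, nri
from .gridsearch import GridSpec, evaluate_grid, find_local_maxima, select_thresholds
from .simulate import SyntheticConfig, generate_cohort
from .stats import lowess_fit, run_comparison_battery, variability_stats

logger = logging.getLogger("cfdna2ta")

DEFAULT_COMPARATOR_CUTOFF = 0.15
DEFAULT_THRESHOLDS = ThresholdPair(0.26, 18.0)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one input source)."""

    cohort_path: str | None = None
    synthetic: SyntheticConfig | None = None
    grid_spec: GridSpec = field(default_factory=GridSpec)
    run_grid_search: bool = True
    two_ta_thresholds: ThresholdPair | None = None
    comparator_cutoff: float = DEFAULT_COMPARATOR_CUTOFF
    n_iterations: int = 10_000
    grid_iterations: int | None = None  # defaults to n_iterations
    surrogate_exponent: int = 30
    lowess_span: float = 0.5
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of cohort_path / synthetic must be set")
        if self.two_ta_thresholds is not None:
            self.run_grid_search = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "grid_spec" in raw and raw["grid_spec"] is not None:
            raw["grid_spec"] = GridSpec(**raw["grid_spec"])
        if "two_ta_thresholds" in raw and raw["two_ta_thresholds"] is not None:
            raw["two_ta_thresholds"] = ThresholdPair(*raw["two_ta_thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return asdict(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _cohort_summary(cohort: Cohort) -> dict:
    labels = cohort.labels()
    frac, dqs, total = cohort.biomarkers()
    ar, non = labels, ~labels

    def med(x):
        return float(np.median(x)) if x.size else None

    return {
        "n_samples": cohort.n_samples,
        "n_patients": cohort.n_patients,
        "n_ar_samples": int(labels.sum()),
        "sample_prevalence": float(labels.mean()) if len(labels) else None,
        "n_excluded": len(cohort.exclusion_log),
        "median_dd_cfdna_pct": {"AR": med(frac[ar]), "non_AR": med(frac[non])},
        "median_dqs_cpml": {"AR": med(dqs[ar]), "non_AR": med(dqs[non])},
        "median_total_cfdna_cpml": {"AR": med(total[ar]), "non_AR": med(total[non])},
    }


def _stage(name: str, out_dir: Path):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
                logger.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                raise StageError(f"stage {name} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, dt)

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    surrogate = SurrogateSpec(config.surrogate_exponent)
    report: dict = {}

    with _stage("input", out_dir):
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
        else:
            cohort = generate_cohort(config.synthetic, seed=config.seed)
        summary = _cohort_summary(cohort)
        _dump_json(summary, out_dir / "cohort_summary.json")
        report["cohort"] = summary

    if config.run_grid_search:
        with _stage("optimize", out_dir):
            grid_iters = config.grid_iterations or config.n_iterations
            gr = evaluate_grid(
                cohort, config.grid_spec, n_iterations=grid_iters,
                seed=config.seed + 1, surrogate=surrogate,
            )
            find_local_maxima(gr)
            selected = select_thresholds(gr, cohort)
            gr.table.to_csv(out_dir / "grid.csv", index=False)
            _dump_json(gr.summary(), out_dir / "grid_selection.json")
            report["grid"] = gr.summary()
    else:
        selected = config.two_ta_thresholds or DEFAULT_THRESHOLDS
        report["grid"] = {"skipped": True, "selected": [selected.c_frac, selected.c_dqs]}

    rule_2ta = two_threshold_rule(selected)
    rule_cmp = single_threshold_rule(config.comparator_cutoff)
    score_2ta = lambda f, d: surrogate_log_score(f, d, selected, surrogate)  # noqa: E731
    score_cmp = lambda f, d: np.asarray(f, dtype=float)  # noqa: E731

    with _stage("evaluate", out_dir):
        boot_2ta = bootstrap_metrics(
            cohort, rule_2ta, config.n_iterations, seed=config.seed + 2, score_fn=score_2ta
        )
        boot_cmp = bootstrap_metrics(
            cohort, rule_cmp, config.n_iterations, seed=config.seed + 2, score_fn=score_cmp
        )
        _dump_json(boot_2ta.summary(), out_dir / "bootstrap_2ta.json")
        _dump_json(boot_cmp.summary(), out_dir / "bootstrap_comparator.json")
        report["bootstrap_2ta"] = boot_2ta.summary()
        report["bootstrap_comparator"] = boot_cmp.summary()

        frac, dqs, _ = cohort.biomarkers()
        labels = cohort.labels()
        conf_2ta = confusion(labels, rule_2ta(frac, dqs))
        conf_cmp = confusion(labels, rule_cmp(frac, dqs))
        fp_reduction = (
            (conf_cmp.fp - conf_2ta.fp) / conf_cmp.fp * 100.0 if conf_cmp.fp else None
        )
        conf_report = {
            "two_threshold": asdict(conf_2ta),
            "comparator": asdict(conf_cmp),
            "fp_reduction_pct": fp_reduction,
        }
        _dump_json(conf_report, out_dir / "confusion.json")
        report["confusion"] = conf_report

    with _stage("compare", out_dir):
        nri_res = nri(
            cohort, rule_2ta, rule_cmp, n_iterations=config.n_iterations,
            seed=config.seed + 3,
        )
        _dump_json(nri_res.summary(), out_dir / "nri.json")
        report["nri"] = nri_res.summary()

        battery = run_comparison_battery(cohort)
        battery.to_csv(out_dir / "comparisons.csv", index=False)

        try:
            var_stats = variability_stats(cohort, "total_cfdna_cpml")
            _dump_json(asdict(var_stats), out_dir / "variability.json")
            report["variability"] = asdict(var_stats)
        except ValueError:
            report["variability"] = None

    with _stage("report", out_dir):
        # trajectories of stable patients (never AR, no CAV)
        df = cohort.frame
        ar_by_patient = pd.Series(labels, index=df.index).groupby(df["patient_id"]).transform("max")
        stable = (~ar_by_patient.astype(bool)) & (df["cav"] != True)  # noqa: E712
        for var in ("dd_cfdna_pct", "dqs_cpml", "total_cfdna_cpml"):
            sub = df.loc[stable]
            # a trajectory needs a genuine spread of draw times
            if len(sub) >= 10 and sub["days_post_tx"].nunique() >= 10:
                t = sub["days_post_tx"].to_numpy(float)
                ev = np.linspace(t.min(), t.max(), 60)
                fit = lowess_fit(t, sub[var].to_numpy(float), span=config.lowess_span, eval_times=ev)
                pd.DataFrame(
                    {"days_post_tx": fit.eval_times, "fitted": fit.fitted_values}
                ).to_csv(out_dir / f"trajectory_{var}.csv", index=False)

        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        _dump_json(manifest, out_dir / "manifest.json")
        _dump_json(report, out_dir / "report.json")

    return report


def setup_logging(out_dir: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
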