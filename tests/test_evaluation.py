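"""Confusion metrics, clustered bootstrap, ROC AUC, and reclassification."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from cfdna2ta import (
    ConfusionCounts,
    SurrogateSpec,
    ThresholdPair,
    bootstrap_metrics,
    confusion,
    confusion_fixture_cohort,
    metrics_from_confusion,
    nri,
    roc_auc,
    single_threshold_rule,
    two_threshold_auc,
    two_threshold_rule,
    whole_cohort_nri,
)
from cfdna2ta.evaluation import patient_choice_matrix

PAIR = ThresholdPair(0.26, 18.0)
RULE_2TA = two_threshold_rule(PAIR)
RULE_CMP = single_threshold_rule(0.15)


class TestConfusion:
    def test_basic_tally(self):
        counts = confusion([1, 0], [1, 0])
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)
        assert confusion([0] * 5, [1] * 5).fp == 5

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])

    def test_total_partitions_samples(self, synthetic_cohort):
        frac, dqs, _ = synthetic_cohort.biomarkers()
        counts = confusion(synthetic_cohort.labels(), RULE_2TA(frac, dqs))
        assert counts.total == synthetic_cohort.n_samples


class TestMetricsFromConfusion:
    def test_printed_operating_point_predictive_values(self):
        """Bayes' rule at sensitivity 86.48%, specificity 83.57% and
        prevalence 8.74% gives PPV ~33.5%, NPV ~98.5%, LR- ~0.16."""
        # counts scaled to reproduce the stated sensitivity/specificity
        counts = ConfusionCounts(tp=8648, fn=1352, tn=8357, fp=1643)
        m = metrics_from_confusion(counts, prevalence=0.0874)
        assert m.sensitivity == pytest.approx(0.8648)
        assert m.specificity == pytest.approx(0.8357)
        assert m.ppv == pytest.approx(0.3358, abs=0.001)
        assert m.npv == pytest.approx(0.985, abs=0.001)
        assert m.lr_neg == pytest.approx(0.16, abs=0.01)
        assert m.lr_pos == pytest.approx(0.8648 / (1 - 0.8357), rel=1e-12)

    def test_sample_level_sensitivity_from_printed_counts(self):
        m = metrics_from_confusion(ConfusionCounts(tp=30, fn=11, fp=79, tn=688))
        assert m.sensitivity == pytest.approx(30 / 41)
        assert m.prevalence_used == pytest.approx(41 / 808)

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionCounts(tp=10, fn=0, fp=0, tn=90), prevalence=0.3)
        assert m.ppv == 1.0 and m.npv == 1.0

    def test_undefined_metrics_are_nan_with_reason(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
        assert math.isnan(m.sensitivity)
        assert any("sensitivity undefined" in note for note in m.notes)

    def test_bayes_closed_forms(self, rng):
        for _ in range(20):
            sens, spec, prev = rng.uniform(0.05, 0.95, 3)
            counts = ConfusionCounts(
                tp=int(sens * 10_000), fn=10_000 - int(sens * 10_000),
                tn=int(spec * 10_000), fp=10_000 - int(spec * 10_000),
            )
            m = metrics_from_confusion(counts, prevalence=prev)
            s, p = m.sensitivity, m.specificity
            assert m.ppv == pytest.approx(s * prev / (s * prev + (1 - p) * (1 - prev)))
            assert m.npv == pytest.approx(p * (1 - prev) / (p * (1 - prev) + (1 - s) * prev))


class TestBootstrap:
    def test_deterministic_given_seed(self, synthetic_cohort):
        a = bootstrap_metrics(synthetic_cohort, RULE_2TA, 200, seed=5)
        b = bootstrap_metrics(synthetic_cohort, RULE_2TA, 200, seed=5)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_single_sample_patients_have_zero_ci_width(self, default_config):
        from cfdna2ta import generate_cohort
        from cfdna2ta.simulate import config_with

        cfg = config_with(default_config, samples_per_patient_mean=1.0,
                          samples_per_patient_range=(1, 1), n_patients=60)
        cohort = generate_cohort(cfg, seed=21)
        res = bootstrap_metrics(cohort, RULE_2TA, 300, seed=5)
        assert res.ci_low["specificity"] == res.ci_high["specificity"]

    def test_ci_brackets_point_estimate(self, synthetic_cohort):
        res = bootstrap_metrics(synthetic_cohort, RULE_2TA, 500, seed=5)
        for k in res.draws:
            if not math.isnan(res.point_estimate[k]):
                assert res.ci_low[k] <= res.point_estimate[k] <= res.ci_high[k]

    def test_zero_event_iterations_excluded_not_zeroed(self, tiny_cohort):
        res = bootstrap_metrics(tiny_cohort, RULE_2TA, 400, seed=9)
        assert res.n_undefined["sensitivity"] > 0
        sens = res.draws["sensitivity"]
        assert np.isnan(sens).sum() == res.n_undefined["sensitivity"]
        assert res.point_estimate["sensitivity"] > 0  # mean over defined draws only

    def test_subsample_uniform_one_per_patient(self, tiny_cohort, rng):
        """Chi-square check: each of a patient's samples is chosen equally
        often across 10,000 iterations, one sample per patient always."""
        choices = patient_choice_matrix(tiny_cohort, 10_000, rng)
        assert choices.shape == (10_000, 3)
        groups = tiny_cohort.patient_groups()
        for j, idx in enumerate(groups):
            col = choices[:, j]
            assert np.isin(col, idx).all()
            if idx.size > 1:
                counts = [(col == i).sum() for i in idx]
                assert chisquare(counts).pvalue > 1e-4

    def test_point_estimates_match_generative_oracle(self, default_config):
        """Bootstrap means over 10 replicate cohorts agree with the
        Monte-Carlo generative-truth oracle within 3 standard errors."""
        from cfdna2ta import generate_cohort, summarize_generative_truth

        op = summarize_generative_truth(default_config, RULE_2TA, n_draws=500_000, seed=424242)
        sens, spec = [], []
        for seed in range(10):
            cohort = generate_cohort(default_config, seed=seed)
            res = bootstrap_metrics(cohort, RULE_2TA, 1000, seed=seed + 100)
            sens.append(res.point_estimate["sensitivity"])
            spec.append(res.point_estimate["specificity"])
        for draws, truth in ((sens, op.sensitivity), (spec, op.specificity)):
            draws = np.asarray(draws)
            se = draws.std(ddof=1) / math.sqrt(draws.size)
            assert abs(draws.mean() - truth) <= 3 * se


class TestRocAuc:
    def test_perfect_separation_and_all_ties(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.arange(20, dtype=float), n)  # many ties
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            brute = (
                (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            ) / (pos.size * neg.size)
            assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=500)
        labels = rng.random(500) < 0.2
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.lognormal(size=300)
        labels = rng.random(300) < 0.25
        base = roc_auc(scores, labels)
        assert roc_auc(np.log(scores), labels) == pytest.approx(base, abs=1e-12)
        assert roc_auc(scores**3, labels) == pytest.approx(base, abs=1e-12)


class TestSurrogateAuc:
    def test_dominating_positives_give_unit_auc(self, tiny_cohort):
        df = tiny_cohort.frame.copy()
        labels = tiny_cohort.labels()
        df.loc[labels, ["dd_cfdna_pct", "dqs_cpml"]] = [5.0, 500.0]
        df.loc[labels, "total_cfdna_cpml"] = 100.0 * 500.0 / 5.0
        from cfdna2ta import Cohort

        assert two_threshold_auc(Cohort(df), PAIR) == 1.0

    def test_rank_stability_in_exponent(self, synthetic_cohort):
        a25 = two_threshold_auc(synthetic_cohort, PAIR, SurrogateSpec(25))
        a40 = two_threshold_auc(synthetic_cohort, PAIR, SurrogateSpec(40))
        assert abs(a25 - a40) < 0.02

    def test_shuffled_labels_give_no_signal(self, synthetic_cohort, rng):
        from cfdna2ta.classifier import surrogate_log_score

        frac, dqs, _ = synthetic_cohort.biomarkers()
        scores = surrogate_log_score(frac, dqs, PAIR)
        labels = synthetic_cohort.labels()
        rng.shuffle(labels)
        assert 0.4 <= roc_auc(scores, labels) <= 0.6


class TestNri:
    def test_self_zero(self, synthetic_cohort):
        res = nri(synthetic_cohort, RULE_2TA, RULE_2TA, n_iterations=300, seed=4)
        defined = res.draws[~np.isnan(res.draws)]
        assert np.all(defined == 0.0)
        assert res.mean == 0.0
        assert res.p_value == 1.0

    def test_whole_cohort_value_on_printed_counts(self):
        """Replacing the 0.15% rule with the 2TA on the fixture moves no
        events and improves 47 of 767 non-events: NRI = 47/767."""
        cohort = confusion_fixture_cohort()
        frac, dqs, _ = cohort.biomarkers()
        labels = cohort.labels()
        got = whole_cohort_nri(labels, RULE_2TA(frac, dqs), RULE_CMP(frac, dqs))
        assert got == pytest.approx(47 / 767, abs=1e-12)

    def test_antisymmetry(self, synthetic_cohort):
        frac, dqs, _ = synthetic_cohort.biomarkers()
        labels = synthetic_cohort.labels()
        forward = whole_cohort_nri(labels, RULE_2TA(frac, dqs), RULE_CMP(frac, dqs))
        backward = whole_cohort_nri(labels, RULE_CMP(frac, dqs), RULE_2TA(frac, dqs))
        assert forward == pytest.approx(-backward, abs=1e-12)

    def test_bootstrap_deterministic(self, synthetic_cohort):
        a = nri(synthetic_cohort, RULE_2TA, RULE_CMP, n_iterations=200, seed=6)
        b = nri(synthetic_cohort, RULE_2TA, RULE_CMP, n_iterations=200, seed=6)
        assert a.mean == b.mean and a.p_value == b.p_value
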