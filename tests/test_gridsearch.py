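"""Threshold grid: enumeration, bootstrap surface, maxima, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cfdna2ta import (
    Cohort,
    GridSpec,
    ThresholdPair,
    build_grid,
    evaluate_grid,
    find_local_maxima,
    select_thresholds,
)
from cfdna2ta.evaluation import patient_choice_matrix
from cfdna2ta.gridsearch import GridResult


class TestEnumeration:
    def test_default_grid_has_1148_pairs(self):
        spec = GridSpec()
        assert spec.n_pairs == 28 * 41 == 1148
        assert len(build_grid(spec)) == 1148

    def test_membership_and_endpoints(self):
        pairs = {(p.c_frac, p.c_dqs) for p in build_grid(GridSpec())}
        assert (0.26, 18.0) in pairs
        assert (0.10, 8.0) in pairs and (0.50, 35.0) in pairs

    def test_single_point_grid(self):
        spec = GridSpec(dqs_min=8, dqs_max=8, frac_min=0.10, frac_max=0.10)
        assert [((p.c_frac, p.c_dqs)) for p in build_grid(spec)] == [(0.10, 8.0)]

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(dqs_min=1, dqs_max=10, dqs_step=3, frac_min=0.1, frac_max=0.1), 4),
            (dict(dqs_min=5, dqs_max=5, frac_min=0.2, frac_max=0.6, frac_step=0.05), 9),
        ],
    )
    def test_count_formula_exact_under_integer_enumeration(self, kwargs, expected):
        assert GridSpec(**kwargs).n_pairs == expected

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(dqs_step=0)
        with pytest.raises(ValueError):
            GridSpec(dqs_min=10, dqs_max=5)


@pytest.fixture(scope="module")
def small_grid_result(synthetic_cohort):
    spec = GridSpec(dqs_min=8, dqs_max=35, dqs_step=3, frac_min=0.10, frac_max=0.50, frac_step=0.05)
    return evaluate_grid(synthetic_cohort, spec, n_iterations=300, seed=3, compute_auc=True)


class TestSurface:
    def test_sensitivity_monotone_in_each_threshold(self, small_grid_result):
        spec = small_grid_result.spec
        sens = small_grid_result.table["sensitivity"].to_numpy().reshape(spec.n_frac, spec.n_dqs)
        assert (np.diff(sens, axis=0) <= 1e-12).all()  # increasing c_frac
        assert (np.diff(sens, axis=1) <= 1e-12).all()  # increasing c_dqs

    def test_specificity_monotone_in_each_threshold(self, small_grid_result):
        spec = small_grid_result.spec
        sp = small_grid_result.table["specificity"].to_numpy().reshape(spec.n_frac, spec.n_dqs)
        assert (np.diff(sp, axis=0) >= -1e-12).all()
        assert (np.diff(sp, axis=1) >= -1e-12).all()

    def test_shared_subsamples_bit_identical_across_pairs(self, synthetic_cohort):
        """The bootstrap subsample set depends only on the seed, not the
        grid point: the surface is evaluated on one shared resampling."""
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(3)
        a = patient_choice_matrix(synthetic_cohort, 100, rng_a)
        b = patient_choice_matrix(synthetic_cohort, 100, rng_b)
        np.testing.assert_array_equal(a, b)
        # and evaluate_grid at the same seed reproduces identical surfaces
        spec = GridSpec(dqs_min=8, dqs_max=11, frac_min=0.1, frac_max=0.12)
        t1 = evaluate_grid(synthetic_cohort, spec, 100, seed=3, compute_auc=False).table
        t2 = evaluate_grid(synthetic_cohort, spec, 100, seed=3, compute_auc=False).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_separated_point_masses_give_perfect_interior(self):
        """With class point masses on both axes straddling the grid, every
        interior pair separates perfectly."""
        rows = []
        for k in range(40):
            ar = k < 8
            frac = 5.0 if ar else 0.01
            dqs = 500.0 if ar else 0.5
            rows.append(
                {
                    "patient_id": f"P{k}",
                    "sample_id": f"S{k}",
                    "days_post_tx": 100,
                    "dd_cfdna_pct": frac,
                    "dqs_cpml": dqs,
                    "total_cfdna_cpml": 100.0 * dqs / frac,
                    "acr_grade": "2R" if ar else "0",
                    "pamr_grade": "0",
                }
            )
        cohort = Cohort(pd.DataFrame(rows))
        res = evaluate_grid(cohort, GridSpec(), n_iterations=50, seed=1, compute_auc=False)
        assert (res.table["sensitivity"] == 1.0).all()
        assert (res.table["specificity"] == 1.0).all()


def _surface_result(surface: np.ndarray) -> GridResult:
    """Wrap an explicit objective surface in a GridResult for maxima tests."""
    n_frac, n_dqs = surface.shape
    spec = GridSpec(
        dqs_min=1, dqs_max=n_dqs, dqs_step=1,
        frac_min=0.1, frac_max=0.1 + 0.01 * (n_frac - 1), frac_step=0.01,
    )
    fvals, dvals = spec.frac_values(), spec.dqs_values()
    table = pd.DataFrame(
        {
            "c_frac": np.repeat(fvals, n_dqs),
            "c_dqs": np.tile(dvals, n_frac),
            "objective": surface.ravel(),
        }
    )
    return GridResult(spec=spec, table=table)


class TestLocalMaxima:
    def test_constant_surface_merges_to_single_representative(self):
        res = _surface_result(np.ones((5, 6)))
        maxima = find_local_maxima(res)
        assert len(maxima) == 1

    def test_single_strict_peak_found(self):
        surf = np.zeros((41, 28))
        surf[16, 10] = 1.0  # c_frac = 0.26, c_dqs = 11
        res = _surface_result(surf)
        maxima = find_local_maxima(res)
        assert (maxima[0].c_frac, maxima[0].c_dqs) == (pytest.approx(0.26), 11.0)

    def test_randomized_surfaces_verified_by_brute_force(self, rng):
        for _ in range(10):
            surf = rng.random((rng.integers(3, 12), rng.integers(3, 12)))
            res = _surface_result(surf)
            maxima = find_local_maxima(res)
            assert maxima
            for p in maxima:
                i = int(round((p.c_frac - res.spec.frac_min) / res.spec.frac_step))
                j = int(round((p.c_dqs - res.spec.dqs_min) / res.spec.dqs_step))
                window = surf[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
                assert surf[i, j] >= window.max() - 1e-12

    def test_sorted_by_objective_descending(self, small_grid_result):
        maxima = find_local_maxima(small_grid_result)
        table = small_grid_result.table
        objs = [
            float(
                table.loc[(table.c_frac == p.c_frac) & (table.c_dqs == p.c_dqs), "objective"].iloc[0]
            )
            for p in maxima
        ]
        assert objs == sorted(objs, reverse=True)


class TestSelection:
    def test_single_maximum_returned_unchanged(self, synthetic_cohort):
        surf = np.zeros((5, 5))
        surf[2, 2] = 1.0
        res = _surface_result(surf)
        find_local_maxima(res)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_thresholds(res, synthetic_cohort)
        assert sel == res.local_maxima[0]

    def test_floor_prefers_adequate_arm_detection(self):
        """Among two equal-objective maxima, the one with zero cellular-arm
        sensitivity is rejected by the default adequacy floor."""
        rows = []
        # ACR samples: frac 0.3, dqs 2 -> detected only when c_frac < 0.3
        for k in range(4):
            rows.append(dict(patient_id=f"A{k}", sample_id=f"A{k}", days_post_tx=100,
                             dd_cfdna_pct=0.3, dqs_cpml=2.0, total_cfdna_cpml=100 * 2.0 / 0.3,
                             acr_grade="2R", pamr_grade="0"))
        # AMR samples: high on both axes, detected at every grid point
        for k in range(4):
            rows.append(dict(patient_id=f"M{k}", sample_id=f"M{k}", days_post_tx=100,
                             dd_cfdna_pct=2.0, dqs_cpml=200.0, total_cfdna_cpml=100 * 200.0 / 2.0,
                             acr_grade="0", pamr_grade="2"))
        for k in range(30):
            rows.append(dict(patient_id=f"N{k}", sample_id=f"N{k}", days_post_tx=100,
                             dd_cfdna_pct=0.02, dqs_cpml=1.0, total_cfdna_cpml=100 * 1.0 / 0.02,
                             acr_grade="0", pamr_grade="0"))
        cohort = Cohort(pd.DataFrame(rows))
        spec = GridSpec(dqs_min=10, dqs_max=10, frac_min=0.25, frac_max=0.35, frac_step=0.10)
        res = evaluate_grid(cohort, spec, n_iterations=100, seed=2, compute_auc=False)
        # force both pairs to be equal-objective maxima so only the floor decides
        res.table["objective"] = 1.5
        res.local_maxima = [res.pair_at(0, 0), res.pair_at(1, 0)]
        sel = select_thresholds(res, cohort)
        # ties otherwise break toward larger c_frac, so the floor is decisive
        assert sel.c_frac == pytest.approx(0.25)

    def test_fallback_warns_when_no_maximum_clears_floor(self, synthetic_cohort):
        res = evaluate_grid(
            synthetic_cohort,
            GridSpec(dqs_min=20, dqs_max=22, frac_min=0.4, frac_max=0.42),
            n_iterations=100,
            seed=2,
            compute_auc=False,
        )
        find_local_maxima(res)
        with pytest.warns(UserWarning, match="arm-sensitivity floor"):
            select_thresholds(res, synthetic_cohort)

    def test_requires_maxima(self, small_grid_result, synthetic_cohort):
        empty = GridResult(spec=small_grid_result.spec, table=small_grid_result.table)
        with pytest.raises(ValueError, match="local maxima"):
            select_thresholds(empty, synthetic_cohort)
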