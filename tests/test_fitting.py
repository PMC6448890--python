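"""Segmentation, TIP/vdW fitting, error metrics and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipiso.fitting import (
    P1_DEGENERACY_NOTE,
    RegionSpec,
    auto_breakpoints,
    compare_fitted_models,
    compare_models,
    evaluate_tip_piecewise,
    fit_tip_piecewise,
    fit_tip_region,
    fit_vdw,
    integral_error,
    pointwise_error,
    segment_isotherm,
)
from tipiso.models import Isotherm, TIPParams, VdWParams, eval_ideal, eval_tip, eval_vdw, thermal_scale
from tipiso.synthetic import DPPC_25C_BANDS, RegionBand, SyntheticSpec, generate_isotherm


def tip_isotherm(params, lo=70.0, hi=100.0, n=50, t=298.15, sigma=0.0, seed=0):
    a = np.linspace(lo, hi, n)
    pi = eval_tip(a, t, params)
    if sigma > 0:
        pi = pi + np.random.default_rng(seed).normal(0.0, sigma, n)
    return Isotherm(a, pi, t)


class TestSegmentation:
    def test_explicit_breakpoints_partition_all_points(self):
        a = np.linspace(40.0, 100.0, 61)
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        regions = segment_isotherm(iso, [55.0, 80.0])
        assert [s.phase_label for s, _ in regions] == [
            "liquid_expanded", "coexistence", "liquid_condensed"
        ]
        # descending a_L order, disjoint, covering every point exactly once
        total = sum(len(sub) for _, sub in regions)
        assert total == len(iso)
        all_areas = np.concatenate([sub.area_per_lipid for _, sub in regions[::-1]])
        np.testing.assert_array_equal(all_areas, a)

    def test_breakpoint_outside_range_rejected(self):
        a = np.linspace(40.0, 100.0, 31)
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        with pytest.raises(ValueError):
            segment_isotherm(iso, [120.0])

    def test_region_with_too_few_points_rejected(self):
        a = np.linspace(40.0, 100.0, 31)
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        with pytest.raises(ValueError):
            segment_isotherm(iso, [41.0, 80.0])

    def test_auto_mode_recovers_plateau_edges(self):
        # steep / flat / moderate piecewise construction with known breaks
        step = 0.5
        a1 = np.arange(40.0, 52.0, step)
        a2 = np.arange(52.0, 75.0, step)
        a3 = np.arange(75.0, 100.0 + step / 2, step)
        pi = np.concatenate([50.0 - a1, 5.0 - 0.002 * a2, 12.0 - 0.1 * a3])
        iso = Isotherm(np.concatenate([a1, a2, a3]), pi, 298.15)
        b1, b2 = auto_breakpoints(iso)
        assert abs(b1 - 52.0) <= step + 1e-9
        assert abs(b2 - 75.0) <= step + 1e-9

    def test_auto_mode_without_plateau_errors(self):
        a = np.linspace(40.0, 100.0, 40)
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        with pytest.raises(ValueError):
            auto_breakpoints(iso)


class TestTIPRegionFit:
    @pytest.mark.parametrize(
        "params",
        [
            TIPParams(6, -0.04, 0.94),
            TIPParams(3, -0.28, 1.62),
            TIPParams(2, 0.5, 0.3),
        ],
        ids=["liquid_expanded", "liquid_condensed", "generic"],
    )
    def test_noiseless_recovery_is_exact(self, params):
        iso = tip_isotherm(params)
        fit = fit_tip_region(iso)
        assert fit.params.p == params.p
        assert fit.params.k1 == pytest.approx(params.k1, rel=1e-8)
        assert fit.params.k2prime == pytest.approx(params.k2prime, rel=1e-8)

    def test_p1_data_selects_p1_and_recovers_sum(self):
        params = TIPParams(1, -0.43, 0.56)
        iso = tip_isotherm(params, lo=52.0, hi=75.0)
        fit = fit_tip_region(iso)
        # at p=1 only the sum k1+k2' is identifiable; ties over p break to 1
        assert fit.params.p == 1
        assert fit.params.k1 == pytest.approx(params.k1 + params.k2prime, rel=1e-10)
        assert fit.params.k2prime == 0.0
        assert fit.note == P1_DEGENERACY_NOTE

    def test_matches_closed_form_normal_equations(self):
        params = TIPParams(4, -0.1, 0.8)
        iso = tip_isotherm(params, n=30, sigma=0.3, seed=7)
        fit = fit_tip_region(iso, fix_p=4)
        a, y = iso.area_per_lipid, iso.surface_pressure
        kappa = thermal_scale(iso.temperature)
        X = np.column_stack([kappa / a, (kappa / 42.0) * (42.0 / a) ** 4])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params.k1 == pytest.approx(beta[0], rel=1e-10)
        assert fit.params.k2prime == pytest.approx(beta[1], rel=1e-10)

    def test_noisy_recovery_within_three_stderr(self):
        params = TIPParams(6, -0.04, 0.94)
        covered = 0
        for seed in range(40):
            iso = tip_isotherm(params, n=50, sigma=0.1, seed=seed)
            fit = fit_tip_region(iso, fix_p=6)
            covered += (
                abs(fit.params.k1 - params.k1) <= 3 * fit.k1_stderr
                and abs(fit.params.k2prime - params.k2prime) <= 3 * fit.k2prime_stderr
            )
        assert covered >= 38

    def test_estimates_unbiased_over_seeds(self):
        params = TIPParams(3, -0.28, 1.62)
        n_seeds = 100
        errs, ses = [], []
        for seed in range(n_seeds):
            iso = tip_isotherm(params, lo=40.0, hi=52.0, n=40, sigma=0.1, seed=seed)
            fit = fit_tip_region(iso, fix_p=3)
            errs.append(fit.params.k1 - params.k1)
            ses.append(fit.k1_stderr)
        assert abs(np.mean(errs)) < 3 * np.mean(ses) / np.sqrt(n_seeds)

    def test_too_few_points_rejected(self):
        iso = Isotherm([50.0, 60.0], [2.0, 1.5], 298.15)
        with pytest.raises(ValueError):
            fit_tip_region(iso)


class TestPiecewiseFit:
    def test_three_region_roundtrip(self):
        bands = tuple(RegionBand(ph, lo, hi, 40, pr) for ph, lo, hi, pr in DPPC_25C_BANDS)
        spec = SyntheticSpec(bands, 298.15)
        gen = generate_isotherm(spec)
        fits = fit_tip_piecewise(gen.isotherm, spec.region_specs())
        truth = spec.params_by_phase()
        for fit in fits:
            tr = truth[fit.spec.phase_label]
            assert fit.params.p == tr.p
            if tr.p == 1:
                assert fit.params.k1 == pytest.approx(tr.k1 + tr.k2prime, rel=1e-8)
            else:
                assert fit.params.k1 == pytest.approx(tr.k1, rel=1e-8)
                assert fit.params.k2prime == pytest.approx(tr.k2prime, rel=1e-8)

    def test_single_region_equals_direct_fit(self):
        params = TIPParams(5, 0.2, 0.7)
        iso = tip_isotherm(params, sigma=0.2, seed=1)
        spec = RegionSpec("liquid_expanded", 70.0, 101.0)
        [piecewise] = fit_tip_piecewise(iso, [spec])
        direct = fit_tip_region(iso)
        assert piecewise.params == direct.params
        assert piecewise.rss == direct.rss

    def test_overlapping_specs_rejected(self):
        iso = tip_isotherm(TIPParams(2, 0.3, 0.3))
        specs = [
            RegionSpec("liquid_expanded", 70.0, 90.0),
            RegionSpec("coexistence", 85.0, 101.0),
        ]
        with pytest.raises(ValueError):
            fit_tip_piecewise(iso, specs)


class TestVdWFit:
    def test_noiseless_recovery(self):
        truth = VdWParams(5000.0, 35.0)
        a = np.linspace(45.0, 100.0, 60)
        iso = Isotherm(a, eval_vdw(a, 298.15, truth), 298.15)
        res = fit_vdw(iso)
        assert res.converged
        assert res.params.a_coh == pytest.approx(truth.a_coh, rel=1e-6)
        assert res.params.b_co == pytest.approx(truth.b_co, rel=1e-6)

    def test_ideal_data_collapses_to_zero_corrections(self):
        a = np.linspace(45.0, 100.0, 60)
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        res = fit_vdw(iso)
        assert res.params.a_coh == pytest.approx(0.0, abs=1e-4)
        assert res.params.b_co == pytest.approx(0.0, abs=1e-6)

    def test_beats_ideal_on_vdw_data(self):
        truth = VdWParams(8000.0, 30.0)
        a = np.linspace(40.0, 110.0, 50)
        iso = Isotherm(a, eval_vdw(a, 298.15, truth), 298.15)
        res = fit_vdw(iso)
        rss_ideal = float(np.sum((iso.surface_pressure - eval_ideal(a, 298.15)) ** 2))
        assert res.rss <= rss_ideal

    def test_init_coarea_above_data_rejected(self):
        a = np.linspace(45.0, 100.0, 20)
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        with pytest.raises(ValueError):
            fit_vdw(iso, init=VdWParams(0.0, 50.0))


class TestErrorMetrics:
    def test_zero_for_perfect_model(self):
        iso = tip_isotherm(TIPParams(2, 0.4, 0.4))
        assert np.all(pointwise_error(iso, iso.surface_pressure) == 0.0)
        assert integral_error(iso, iso.surface_pressure) == 0.0

    def test_constant_offset_passes_through(self):
        # uneven grid: the range-normalized trapezoid of a constant is exact
        a = np.array([40.0, 41.0, 45.0, 60.0, 99.0])
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        delta = 0.37
        err = pointwise_error(iso, iso.surface_pressure + delta)
        np.testing.assert_allclose(err, delta, rtol=1e-14)
        assert integral_error(iso, iso.surface_pressure + delta) == pytest.approx(delta, rel=1e-12)

    def test_quadrature_refinement_is_stable(self):
        params = TIPParams(3, 0.2, 0.9)
        model = TIPParams(3, 0.25, 0.85)
        vals = []
        for n in (60, 120):
            a = np.linspace(50.0, 100.0, n)
            iso = Isotherm(a, eval_tip(a, 298.15, params), 298.15)
            vals.append(integral_error(iso, eval_tip(a, 298.15, model)))
        assert abs(vals[1] - vals[0]) / vals[0] < 0.01

    @settings(derandomize=True, max_examples=100)
    @given(
        offsets=st.lists(st.floats(-3.0, 3.0), min_size=3, max_size=12),
    )
    def test_bounded_by_mean_offset_and_max_error(self, offsets):
        n = len(offsets)
        a = np.linspace(40.0, 100.0, n)
        iso = Isotherm(a, eval_ideal(a, 298.15), 298.15)
        model = iso.surface_pressure + np.array(offsets)
        e_int = integral_error(iso, model)
        width = a[-1] - a[0]
        mean_signed = abs(np.trapezoid(np.array(offsets), a) / width)
        assert e_int >= mean_signed - 1e-12
        assert e_int <= np.max(np.abs(offsets)) + 1e-12

    def test_length_mismatch_rejected(self):
        iso = tip_isotherm(TIPParams(2, 0.4, 0.4), n=10)
        with pytest.raises(ValueError):
            pointwise_error(iso, np.zeros(9))


class TestModelComparison:
    def test_tip_ranks_first_on_tip_data(self, dppc45):
        comparison, _, _ = compare_fitted_models(dppc45.isotherm)
        assert comparison.ranking[0] == "tip"
        e = comparison.integral_errors
        assert e["tip"] < e["ideal"] and e["tip"] < e["vdw"]

    def test_ideal_error_exceeds_tip_error_pointwise_below_100(self, dppc25):
        iso = dppc25.isotherm
        tip_pi = dppc25.clean_pressure
        e_ideal = pointwise_error(iso, eval_ideal(iso.area_per_lipid, iso.temperature))
        e_tip = pointwise_error(iso, tip_pi)
        mask = iso.area_per_lipid < 100.0
        assert np.all(e_ideal[mask] > e_tip[mask])

    def test_degenerate_on_ideal_data(self):
        a = np.linspace(60.0, 110.0, 50)
        iso = Isotherm(a, eval_ideal(a, 318.15), 318.15)
        comparison, _, _ = compare_fitted_models(iso)
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in comparison.integral_errors.values())

    def test_mismatched_grid_rejected(self):
        iso = tip_isotherm(TIPParams(2, 0.4, 0.4), n=10)
        with pytest.raises(ValueError):
            compare_models(iso, {"ideal": np.zeros(9)})

    def test_piecewise_evaluation_requires_coverage(self, dppc25):
        fits = fit_tip_piecewise(dppc25.isotherm, dppc25.spec.region_specs())
        with pytest.raises(ValueError):
            evaluate_tip_piecewise(np.array([10.0, 80.0]), 298.15, fits)
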