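"""Entrapment simulator: size model, calibration, washout, flow, sections."""
import dataclasses
import math

import numpy as np
import pytest

from icretention import (
    EntrapmentModel,
    SimulatorParams,
    SizeModel,
    analyze_run,
    calibrate_p_max,
    default_params,
    expected_first_minute_fraction,
    expected_retention,
    fraction_exited_by,
    sample_population,
    simulate_flow,
    simulate_run,
    simulate_sections,
    summarize_sizes,
    whole_heart_estimate,
)


class TestSizeModel:
    def test_bmmnc_median_and_large_cell_tail(self, bmmnc_params):
        pop = sample_population(bmmnc_params, 1_000_000, seed=42)
        median, _ = summarize_sizes(pop.size_histogram)
        assert median == pytest.approx(7.0, abs=0.1)
        assert pop.size_histogram.fraction_at_least(10.0) < 0.01

    def test_msc_mean_median_ratio(self, msc_params):
        d = msc_params.size
        assert d.median_um == 11.5
        assert d.mean_um == pytest.approx(12.2)
        sample = d.sample(np.random.default_rng(7), 1_000_000)
        assert np.median(sample) == pytest.approx(11.5, rel=0.01)
        assert sample.mean() == pytest.approx(12.2, rel=0.01)

    def test_degenerate_sigma_collapses_to_median_bin(self):
        params = SimulatorParams(size=SizeModel(7.4, 0.0))
        pop = sample_population(params, 1000, seed=0)
        assert pop.size_histogram.to_dict() == {7: 1000}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SizeModel(-1.0, 0.1)
        with pytest.raises(ValueError):
            SizeModel(7.0, -0.1)


class TestEntrapmentModel:
    def test_monotone_non_decreasing(self):
        m = EntrapmentModel(p_max=0.9)
        d = np.linspace(2, 20, 200)
        p = m.prob(d)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0) & (p <= m.p_max))

    def test_lookup_table_overrides_logistic(self):
        m = EntrapmentModel(bin_probs=((5, 0.1), (6, 0.5), (7, 0.9)))
        assert m.prob(5.7) == 0.1
        assert m.prob(7.3) == 0.9
        # clamped outside the tabulated range
        assert m.prob(2.0) == 0.1
        assert m.prob(30.0) == 0.9

    def test_p_max_bounds(self):
        with pytest.raises(ValueError):
            EntrapmentModel(p_max=1.5)


class TestExpectedRetentionOracle:
    def test_constant_probability_returns_constant(self):
        params = SimulatorParams(
            entrapment=EntrapmentModel(bin_probs=((0, 0.37),)))
        assert expected_retention(params) == pytest.approx(0.37)

    @pytest.mark.parametrize("cell_type,target", [("BMMNC", 0.201), ("MSC", 0.775)])
    def test_calibration_hits_target(self, cell_type, target):
        params = default_params(cell_type)
        assert expected_retention(params) == pytest.approx(target, abs=1e-9)
        assert 0.0 < params.entrapment.p_max <= 1.0

    @pytest.mark.parametrize("cell_type", ["BMMNC", "MSC"])
    def test_quadrature_matches_brute_force_sampling(self, cell_type):
        # independent oracle: plain Monte-Carlo average of p(d)
        params = default_params(cell_type)
        rng = np.random.default_rng(202)
        d = params.size.sample(rng, 2_000_000)
        p = params.entrapment.prob(d)
        mc = float(p.mean())
        se = float(p.std() / math.sqrt(d.size))
        assert abs(mc - expected_retention(params)) <= 3 * se

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_p_max(default_params("BMMNC", calibrate=False), 0.999)


def _noiseless(params):
    return dataclasses.replace(params, counter_cv=0.0, flow_noise_cv=0.0)


class TestSimulateRun:
    def test_exact_conservation(self, small_bmmnc_run):
        run, truth = small_bmmnc_run
        assert truth.retained_count + truth.exited_count == truth.dose
        assert truth.retained_per_bin.total() == truth.retained_count
        assert truth.exited_per_bin.total() == truth.exited_count
        assert run.pre_injection_population.size_histogram.total() == truth.dose
        assert int(truth.exit_minute_counts.sum()) == truth.exited_count

    def test_all_or_nothing_entrapment(self, bmmnc_params):
        p0 = dataclasses.replace(
            _noiseless(bmmnc_params),
            entrapment=EntrapmentModel(bin_probs=((0, 0.0),)))
        run, truth = simulate_run(p0, 20_000, seed=3)
        res = analyze_run(run, window_minutes=run.n_minutes)
        assert truth.retained_count == 0
        assert res.retention_pct == pytest.approx(0.0, abs=1e-9)

        p1 = dataclasses.replace(
            _noiseless(bmmnc_params),
            entrapment=EntrapmentModel(bin_probs=((0, 1.0),)))
        run, truth = simulate_run(p1, 20_000, seed=3)
        res = analyze_run(run)
        assert truth.exited_count == 0
        assert res.total_effluent == 0.0
        assert res.retention_pct == 100.0

    def test_noiseless_pipeline_recovers_ground_truth(self, bmmnc_params):
        run, truth = simulate_run(_noiseless(bmmnc_params), 300_000, seed=8)
        res = analyze_run(run, window_minutes=run.n_minutes)
        assert res.retention_pct == pytest.approx(
            truth.retained_fraction * 100.0, abs=1e-9)

    def test_seed_reproducibility_bit_identical(self, bmmnc_params):
        run_a, truth_a = simulate_run(bmmnc_params, 50_000, seed=77)
        run_b, truth_b = simulate_run(bmmnc_params, 50_000, seed=77)
        assert run_a == run_b
        assert truth_a.retained_count == truth_b.retained_count
        np.testing.assert_array_equal(truth_a.exit_minute_counts,
                                      truth_b.exit_minute_counts)
        np.testing.assert_array_equal(truth_a.retained_per_bin.counts,
                                      truth_b.retained_per_bin.counts)

    def test_monte_carlo_retention_matches_analytic_oracle(self, bmmnc_params):
        rates = []
        for s in range(30):
            _, truth = simulate_run(bmmnc_params, 20_000, seed=1000 + s)
            rates.append(truth.retained_fraction)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / math.sqrt(rates.size)
        assert abs(rates.mean() - expected_retention(bmmnc_params)) <= 3 * se

    def test_dose_invariant_retention_fraction(self, bmmnc_params):
        # retention is per-cell Bernoulli: fraction is dose-independent
        fracs = {}
        for dose in (10_000, 100_000):
            _, truth = simulate_run(bmmnc_params, dose, seed=5)
            fracs[dose] = truth.retained_fraction
        assert fracs[10_000] == pytest.approx(fracs[100_000], abs=0.02)

    def test_per_layer_retained_partition(self, small_bmmnc_run):
        _, truth = small_bmmnc_run
        assert sum(truth.per_layer_retained.values()) == pytest.approx(
            truth.retained_count)
        assert truth.per_layer_retained["endocardial"] == pytest.approx(
            3 * truth.per_layer_retained["epicardial"])

    def test_marker_labels_independent_of_retention(self, bmmnc_params):
        params = dataclasses.replace(
            bmmnc_params, marker_fractions=(("CD34+", 0.3), ("CD34-", 0.7)))
        _, truth = simulate_run(params, 200_000, seed=12)
        pre = truth.marker_counts_pre
        eff = truth.marker_counts_effluent
        assert sum(pre.values()) == truth.dose
        assert sum(eff.values()) == truth.exited_count
        pre_frac = pre["CD34+"] / truth.dose
        eff_frac = eff["CD34+"] / truth.exited_count
        assert eff_frac == pytest.approx(pre_frac, abs=0.01)


class TestWashoutKinetics:
    def test_closed_form_first_minute_fraction(self, bmmnc_params):
        # F(60) = 1 - (tau/D) e^{-60/tau} (e^{D/tau} - 1), tau=15 s, D=20 s
        tau, D = 15.0, 20.0
        expected = 1.0 - (tau / D) * math.exp(-60 / tau) * (math.exp(D / tau) - 1)
        assert expected_first_minute_fraction(bmmnc_params) == pytest.approx(expected)
        assert expected > 0.90

    def test_cdf_is_proper(self):
        ts = np.linspace(0, 400, 100)
        vals = [fraction_exited_by(t) for t in ts]
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[0] == 0.0
        assert vals[-1] == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_agrees_with_closed_form(self, bmmnc_params):
        _, truth = simulate_run(bmmnc_params, 400_000, seed=9)
        n_exit = truth.exited_count
        frac = truth.exit_minute_counts[0] / n_exit
        expected = expected_first_minute_fraction(bmmnc_params)
        se = math.sqrt(expected * (1 - expected) / n_exit)
        assert abs(frac - expected) <= 3 * se


class TestFlowModel:
    def test_bmmnc_flow_constant_at_baseline(self, bmmnc_params):
        v = simulate_flow(bmmnc_params, 10, retained_fraction=0.2)
        assert np.allclose(v, bmmnc_params.baseline_flow_ml_min)

    def test_msc_flow_drops_below_half_then_recovers(self, msc_params):
        base = msc_params.baseline_flow_ml_min
        v = simulate_flow(msc_params, 10, retained_fraction=0.775)
        assert v[0] < 0.5 * base
        assert v[9] >= 0.95 * base
        assert np.all(np.diff(v) > 0)  # monotone recovery

    def test_zero_obstruction_matches_bmmnc_mode(self, msc_params):
        no_obstruction = dataclasses.replace(msc_params, obstruction_coef=0.0)
        v = simulate_flow(no_obstruction, 6, retained_fraction=0.775)
        assert np.allclose(v, no_obstruction.baseline_flow_ml_min)

    def test_injectate_added_to_minute_one(self, bmmnc_params):
        v = simulate_flow(bmmnc_params, 5, 0.2, include_injectate=True)
        assert v[0] == pytest.approx(
            bmmnc_params.baseline_flow_ml_min + bmmnc_params.injection_volume_ml)


class TestSimulateSections:
    def test_zero_retained_gives_zero_counts(self, bmmnc_params):
        h = simulate_sections(bmmnc_params, 0.0, 1e6, seed=0)
        assert all(s.labeled_cells == 0 for s in h.sections)

    def test_expected_density_matches_worked_inversion(self, bmmnc_params):
        # retained count chosen to invert the observed 18.5% at 1242 mg
        retained = 8.94 / 0.0075 * 1242.0
        h = simulate_sections(bmmnc_params, retained, 8e6, exact=True)
        whole = [s for s in h.sections if s.layer == "whole"]
        for s in whole:
            assert s.density == pytest.approx(8.94)
        est, pct = whole_heart_estimate(h)
        assert est == pytest.approx(retained)
        assert round(pct, 1) == 18.5

    def test_transmural_weights_give_3x_gradient_in_expectation(self, bmmnc_params):
        from icretention import transmural_gradient

        h = simulate_sections(bmmnc_params, 1e6, 8e6, exact=True)
        grad = transmural_gradient(h.sections)
        assert grad.endo_epi_ratio == pytest.approx(3.0)

    def test_cross_arm_agreement_noiseless(self, bmmnc_params):
        # effluent and histology arms agree exactly when both are noiseless
        run, truth = simulate_run(_noiseless(bmmnc_params), 200_000, seed=14)
        res = analyze_run(run, window_minutes=run.n_minutes)
        h = simulate_sections(bmmnc_params, truth.retained_count,
                              run.injected_dose, exact=True)
        _, hist_pct = whole_heart_estimate(h)
        assert hist_pct == pytest.approx(res.retention_pct, abs=1e-9)

    def test_invalid_geometry_rejected(self, bmmnc_params):
        with pytest.raises(ValueError):
            simulate_sections(bmmnc_params, 100.0, 1e6, heart_mass_mg=-5.0)
        with pytest.raises(ValueError):
            simulate_sections(bmmnc_params, -1.0, 1e6)
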