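"""Simulator contracts: closed forms, event timing, kymographs, mitophagy."""

import numpy as np
import pytest
from scipy import stats

from atgdyn import (
    EngulfmentError,
    MitophagyParams,
    ModelVariant,
    NonselectiveParams,
    delay_for_cycle,
    nonselective_curve,
    simulate_kymograph,
    simulate_mitophagy,
    simulate_mitophagy_population,
    simulate_nonselective,
)


class TestNonselective:
    def test_eventless_m0_matches_analytic_exponential(self):
        # dA/dt = kprod - krem*A has the textbook closed form
        p = NonselectiveParams(kprodATG13=0.02, kremATG13=0.01, m=0.0)
        t = np.linspace(0.0, 800.0, 81)
        expected = p.kprodATG13 / p.kremATG13 + (
            p.atg13_seed - p.kprodATG13 / p.kremATG13
        ) * np.exp(-p.kremATG13 * t)
        got = nonselective_curve(t, p, ModelVariant(4))
        assert np.max(np.abs(got - expected) / np.abs(expected)) < 1e-6

    @pytest.mark.parametrize("vid", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("wtm", [False, True])
    def test_analytic_route_matches_numeric_integrator(self, vid, wtm):
        p = NonselectiveParams()
        t = np.linspace(0.0, 600.0, 61)
        a = nonselective_curve(t, p, ModelVariant(vid), wortmannin=wtm)
        b = nonselective_curve(t, p, ModelVariant(vid), wortmannin=wtm, method="numeric")
        assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-12)) < 1e-6

    @pytest.mark.parametrize("vid", [1, 2, 3])
    def test_event_variant_peaks_at_event_time(self, vid):
        p = NonselectiveParams(t=230.0)
        tc = simulate_nonselective(p, ModelVariant(vid), horizon=600.0, dt=10.0)
        peak = tc.times[np.argmax(tc.intensities)]
        assert abs(peak - p.t) <= 10.0
        # unimodal: non-decreasing to the peak, non-increasing after
        i = int(np.argmax(tc.intensities))
        assert np.all(np.diff(tc.intensities[: i + 1]) >= -1e-15)
        assert np.all(np.diff(tc.intensities[i:]) <= 1e-15)

    def test_zero_production_gives_flat_trace(self):
        p = NonselectiveParams(kprodATG13=0.0)
        tc = simulate_nonselective(p, ModelVariant(4), horizon=300.0)
        # removal never engages above the seed it starts from
        assert tc.intensities[0] == pytest.approx(p.atg13_seed)
        assert tc.intensities.max() <= p.atg13_seed + 1e-15

    def test_horizon_must_exceed_event_time(self):
        with pytest.raises(ValueError):
            simulate_nonselective(NonselectiveParams(t=500.0), ModelVariant(1), horizon=400.0)

    def test_wortmannin_reduces_amplitude_for_accumulation_targets(self):
        p = NonselectiveParams(kwrtm=0.5)
        t = np.linspace(0.0, 400.0, 41)
        ctrl = nonselective_curve(t, p, ModelVariant(3), wortmannin=False)
        wtm = nonselective_curve(t, p, ModelVariant(3), wortmannin=True)
        assert wtm.max() < ctrl.max()


class TestKymograph:
    def test_shape_normalization_and_sorting(self, nonselective_params):
        ky = simulate_kymograph(35, ("normal", 200.0, 40.0), nonselective_params, seed=3)
        assert ky.matrix.shape[0] == 35
        assert np.allclose(ky.matrix.min(axis=1), 0.0)
        assert np.allclose(ky.matrix.max(axis=1), 1.0)
        assert np.all(np.diff(ky.peak_times) <= 0)  # decreasing peak time

    def test_zero_spread_keeps_repeat_order(self, nonselective_params):
        ky = simulate_kymograph(5, ("normal", 150.0, 0.0), nonselective_params, seed=1)
        assert ky.row_order == [str(i) for i in range(5)]
        assert np.allclose(ky.matrix, ky.matrix[0])

    def test_lognormal_peak_times_match_generating_distribution(self):
        # distribution oracle at large n: KS against the generating CDF
        from atgdyn.simulate import _sample_peak_times

        rng = np.random.default_rng(11)
        sample, _ = _sample_peak_times(("lognormal", 5.0, 0.4), 10_000, rng)
        ks = stats.kstest(sample, stats.lognorm(s=0.4, scale=np.exp(5.0)).cdf)
        assert ks.pvalue > 0.01

    def test_nonpositive_normal_draws_are_resampled(self, nonselective_params):
        ky = simulate_kymograph(20, ("normal", 30.0, 40.0), nonselective_params, seed=2)
        assert np.all(ky.peak_times > 0)
        assert ky.n_resampled > 0


class TestDelayLaw:
    @pytest.mark.parametrize(
        "k,kpeak,p,expected",
        [(2, 1.0, 2.79, 2.0**2.79), (1, 3.5, 0.0, 3.5), (3, 2.0, 3.0, 54.0)],
    )
    def test_values(self, k, kpeak, p, expected):
        assert delay_for_cycle(k, kpeak, p) == pytest.approx(expected)

    def test_growth_ratio_is_exact_power_law(self):
        for p in (0.5, 1.0, 2.79, 4.0):
            for k in range(1, 9):
                ratio = delay_for_cycle(k + 1, 1.7, p) / delay_for_cycle(k, 1.7, p)
                assert ratio == pytest.approx(((k + 1) / k) ** p, rel=1e-12)

    def test_cycle_index_below_one_rejected(self):
        with pytest.raises(ValueError):
            delay_for_cycle(0, 1.0, 2.0)


class TestMitophagy:
    def test_result_invariants(self, mitophagy_params):
        res = simulate_mitophagy(mitophagy_params, seed=5)
        assert np.all(np.diff(res.peak_num) >= 0)
        assert np.all(np.diff(res.lc3.intensities) >= -1e-12)
        assert np.all(np.diff(res.peak_delay_obs) > 0)  # p > 0
        assert np.isfinite(res.termination_time)
        assert res.n_peaks() == res.peak_num[-1]

    def test_tiny_mitochondrion_terminates_after_one_cycle(self, mitophagy_params):
        p = mitophagy_params.replace(mt_diam_mean=1e-6, mt_diam_sd=0.0)
        res = simulate_mitophagy(p, seed=0)
        assert res.n_peaks() == 1

    def test_doubling_threshold_doubles_cycle_count(self, mitophagy_params):
        base = mitophagy_params.replace(t_sd=0.0, mt_diam_sd=0.0)
        n1 = simulate_mitophagy(base, seed=0).n_peaks()
        n2 = simulate_mitophagy(base.replace(engulf_coeff=2 * base.engulf_coeff), seed=0).n_peaks()
        assert abs(n2 - 2 * n1) <= 1

    def test_unreachable_engulfment_raises(self, mitophagy_params):
        with pytest.raises(EngulfmentError):
            simulate_mitophagy(mitophagy_params.replace(kprodLC3=0.0), seed=0)

    def test_termination_bound_by_lc3_budget(self, mitophagy_params):
        res = simulate_mitophagy(mitophagy_params, seed=9)
        threshold = mitophagy_params.engulf_coeff * res.mt_diam
        assert res.n_peaks() <= int(np.ceil(threshold / res.lc3_per_cycle.min())) + 1

    def test_identical_seeds_bit_identical(self, mitophagy_params):
        a = simulate_mitophagy(mitophagy_params, seed=123)
        b = simulate_mitophagy(mitophagy_params, seed=123)
        assert np.array_equal(a.trace.intensities, b.trace.intensities)
        assert np.array_equal(a.peak_times, b.peak_times)
        assert a.mt_diam == b.mt_diam

    def test_deterministic_params_give_identical_events(self, mitophagy_params):
        det = mitophagy_params.replace(t_sd=0.0, mt_diam_sd=0.0)
        pop = simulate_mitophagy_population(4, det, seed=6)
        for r in pop[1:]:
            assert np.array_equal(r.peak_times, pop[0].peak_times)
            assert r.mt_diam == pop[0].mt_diam

    def test_population_loses_synchrony_over_cycles(self, mitophagy_params):
        # variance of the k-th peak time grows with the cycle index
        pop = simulate_mitophagy_population(200, mitophagy_params, seed=7)
        counts = min(r.n_peaks() for r in pop)
        var = [np.var([r.peak_times[k] for r in pop]) for k in range(min(counts, 4))]
        assert all(v2 >= v1 - 1e-9 for v1, v2 in zip(var, var[1:]))

    def test_expected_peak_count_monotone_in_diameter(self, mitophagy_params):
        means = []
        for diam in (0.5, 1.0, 1.5):
            p = mitophagy_params.replace(mt_diam_mean=diam, mt_diam_sd=0.0)
            pop = simulate_mitophagy_population(12, p, seed=8)
            means.append(np.mean([r.n_peaks() for r in pop]))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]
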