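"""Estimation: objectives, multi-start, AIC, profile likelihood, two-stage."""

import numpy as np
import pytest
from scipy.stats import chi2

from atgdyn import (
    EstimationResult,
    MitophagyParams,
    ModelVariant,
    NonselectiveParams,
    TimeCourse,
    compute_aic,
    extract_first_peaks,
    fit_mitophagy_two_stage,
    fit_multistart,
    profile_likelihood,
    profile_objective,
    rank_variants,
    simulate_mitophagy,
    sse_objective,
)
from conftest import make_pulse_datasets

FAST_CFG = {"iterations": 60, "swarm_size": 10}


class TestObjective:
    def test_noise_free_self_fit_is_zero(self, nonselective_params, variant3, pulse_datasets):
        assert sse_objective(nonselective_params, variant3, pulse_datasets) < 1e-8

    @pytest.mark.parametrize("param,factor", [("kprodATG13", 1.1), ("kremATG13", 1.1), ("t", 1.05)])
    def test_perturbation_increases_objective(
        self, nonselective_params, variant3, pulse_datasets, param, factor
    ):
        perturbed = nonselective_params.replace(
            **{param: getattr(nonselective_params, param) * factor}
        )
        assert sse_objective(perturbed, variant3, pulse_datasets) > sse_objective(
            nonselective_params, variant3, pulse_datasets
        )

    def test_integration_failure_penalized_not_raised(self, variant3, pulse_datasets):
        # m far above 1 with a large seed blows up before the event time
        bad = NonselectiveParams(kprodATG13=9.0, m=3.5, t=500.0, atg13_seed=0.5)
        assert sse_objective(bad, variant3, pulse_datasets) == np.inf


class TestMultistart:
    def test_recovery_on_synthetic_variant3_data(self, nonselective_params):
        datasets = make_pulse_datasets(nonselective_params, noise_sd=0.0)
        res = fit_multistart(
            ModelVariant(3),
            datasets,
            n_starts=6,
            optimizer_cfg={"iterations": 150, "swarm_size": 12},
            seed=5,
        )
        bp = res.best_params
        assert bp.kprodATG13 == pytest.approx(nonselective_params.kprodATG13, rel=0.05)
        assert bp.kremATG13 == pytest.approx(nonselective_params.kremATG13, rel=0.05)
        assert bp.t == pytest.approx(nonselective_params.t, rel=0.05)
        assert res.objective < 1e-8

    def test_single_start_is_deterministic(self, nonselective_params, pulse_datasets):
        a = fit_multistart(ModelVariant(3), pulse_datasets, n_starts=1, optimizer_cfg=FAST_CFG, seed=3)
        b = fit_multistart(ModelVariant(3), pulse_datasets, n_starts=1, optimizer_cfg=FAST_CFG, seed=3)
        assert a.objective == b.objective
        assert a.best_params == b.best_params

    def test_retained_set_size_and_best(self, nonselective_params, pulse_datasets):
        res = fit_multistart(
            ModelVariant(3), pulse_datasets, n_starts=8, optimizer_cfg=FAST_CFG, seed=1
        )
        assert len(res.starts) == 8
        assert len(res.retained) == 6  # floor(0.75 * 8)
        assert res.retained[0][1] == res.objective == min(o for _, o in res.starts)

    def test_eventless_variants_fit_without_t(self, pulse_datasets):
        res = fit_multistart(
            ModelVariant(5), pulse_datasets, n_starts=2, optimizer_cfg=FAST_CFG, seed=2
        )
        assert res.n_params == 4  # kprod, krem, m, kwrtm


class TestAIC:
    def test_parameter_penalty_breaks_ties(self):
        def result(n_params, ssr=1.0):
            return EstimationResult(
                best_params=NonselectiveParams(),
                objective=ssr,
                starts=[({}, ssr)],
                retained=[({}, ssr)],
                n_data=100,
                n_params=n_params,
            )

        assert compute_aic(result(4)) < compute_aic(result(5))

    def test_zero_objective_degenerates_with_warning(self):
        res = EstimationResult(
            best_params=NonselectiveParams(),
            objective=0.0,
            starts=[({}, 0.0)],
            retained=[({}, 0.0)],
            n_data=10,
            n_params=2,
            aic=0.0,  # bypass __post_init__ recomputation
        )
        with pytest.warns(RuntimeWarning):
            assert compute_aic(res) == -np.inf

    def test_ranking_invariant_to_global_intensity_rescaling(self, nonselective_params):
        datasets = make_pulse_datasets(nonselective_params, noise_sd=0.05, seed=4)
        results, results_scaled = [], []
        for vid in (1, 4):
            res = fit_multistart(
                ModelVariant(vid), datasets, n_starts=2, optimizer_cfg=FAST_CFG, seed=10 + vid
            )
            results.append(res)
            scaled = {
                c: [TimeCourse(tc.times, tc.intensities * 1000.0, tc.condition, tc.repeat_id) for tc in lst]
                for c, lst in datasets.items()
            }
            # rescale the model consistently through the seed/bounds
            res_s = fit_multistart(
                ModelVariant(vid),
                scaled,
                n_starts=2,
                optimizer_cfg=FAST_CFG,
                seed=10 + vid,
                bounds={"atg13_seed": (1e-4, 1000.0)},
                base_params=NonselectiveParams(atg13_seed=10.0),
            )
            results_scaled.append(res_s)
        order = [r.variant.variant_id for r in rank_variants(results)]
        order_scaled = [r.variant.variant_id for r in rank_variants(results_scaled)]
        assert order == order_scaled

    def test_event_variant_outranks_eventless_on_pulse_data(self, nonselective_params):
        datasets = make_pulse_datasets(nonselective_params, noise_sd=0.05, seed=6)
        results = [
            fit_multistart(ModelVariant(v), datasets, n_starts=3, optimizer_cfg=FAST_CFG, seed=20 + v)
            for v in (3, 6)
        ]
        ranked = rank_variants(results)
        assert ranked[0].variant.event_based


class TestProfileLikelihood:
    def test_linear_toy_matches_analytic_interval(self):
        # y = theta * x + e: SSR(theta) is quadratic, so the profile CI has
        # the closed form theta_hat +- sqrt(SSR_min*(exp(q/n)-1)/Sxx)
        rng = np.random.default_rng(8)
        x = np.linspace(1.0, 10.0, 40)
        theta_true = 2.0
        y = theta_true * x + rng.normal(0, 0.5, x.size)
        sxx = float(x @ x)
        theta_hat = float(x @ y) / sxx
        ssr_min = float(np.sum((y - theta_hat * x) ** 2))

        def reopt(theta):
            return float(np.sum((y - theta * x) ** 2))

        grid = np.linspace(theta_hat - 0.2, theta_hat + 0.2, 401)
        curve = profile_objective(reopt, grid, theta_hat, ssr_min, n_data=x.size)
        for level in (0.66, 0.95, 0.99):
            q = chi2.ppf(level, df=1)
            half = np.sqrt(ssr_min * (np.exp(q / x.size) - 1.0) / sxx)
            lo, hi, lo_open, hi_open = curve.ci[level]
            assert not lo_open and not hi_open
            assert lo == pytest.approx(theta_hat - half, abs=2 * (grid[1] - grid[0]))
            assert hi == pytest.approx(theta_hat + half, abs=2 * (grid[1] - grid[0]))

    def test_nested_intervals_on_model_fit(self, nonselective_params):
        datasets = make_pulse_datasets(nonselective_params, noise_sd=0.03, seed=9)
        res = fit_multistart(
            ModelVariant(3), datasets, n_starts=4, optimizer_cfg=FAST_CFG, seed=11
        )
        curve = profile_likelihood(
            "kprodATG13", res, ModelVariant(3), datasets, grid_size=15,
            bounds={"kprodATG13": (1e-4, 0.5)},
        )
        l66, l95, l99 = curve.ci[0.66], curve.ci[0.95], curve.ci[0.99]
        assert l95[0] <= l66[0] and l66[1] <= l95[1]
        assert l99[0] <= l95[0] and l95[1] <= l99[1]
        # the true value lies inside the widest interval
        assert l99[0] <= nonselective_params.kprodATG13 <= l99[1]

    def test_unknown_parameter_rejected(self, nonselective_params, pulse_datasets):
        res = fit_multistart(
            ModelVariant(3), pulse_datasets, n_starts=1, optimizer_cfg=FAST_CFG, seed=0
        )
        with pytest.raises(ValueError):
            profile_likelihood("nope", res, ModelVariant(3), pulse_datasets)


class TestTwoStage:
    @pytest.fixture(scope="class")
    def stage2_trace(self):
        truth = MitophagyParams()
        det = truth.replace(t_sd=0.0, mt_diam_sd=0.0)
        sim = simulate_mitophagy(det, seed=0)
        rng = np.random.default_rng(31)
        y = sim.trace.intensities * rng.lognormal(-0.5 * 0.05**2, 0.05, size=len(sim.trace))
        return TimeCourse(sim.trace.times, y, "ivermectin", "mean"), truth

    def test_missing_statistics_rejected(self, stage2_trace):
        full, truth = stage2_trace
        with pytest.raises(ValueError):
            fit_mitophagy_two_stage([full], [full], None, (1.0, 0.3))

    def test_single_pulse_input_refused(self):
        t = np.arange(0.0, 200.0, 10.0)
        pulse = TimeCourse(t, 0.01 * np.exp(-((t - 100.0) ** 2) / 2000.0) + 0.01, "ivm", "x")
        with pytest.raises(ValueError, match="stage 2"):
            fit_mitophagy_two_stage(
                [pulse], [pulse], t_stats=(45.0, 9.0), diam_stats=(1.0, 0.3)
            )

    def test_stage1_recovers_kinetics_from_population_first_peaks(self):
        from atgdyn import NoiseConfig, gen_mitophagy_population

        truth = MitophagyParams()
        pop = gen_mitophagy_population(17, truth, noise_cfg=NoiseConfig(0.05, None), seed=1004)
        fps = extract_first_peaks(pop.traces)
        det = truth.replace(t_sd=0.0, mt_diam_sd=0.0)
        sim = simulate_mitophagy(det, seed=0)
        rng = np.random.default_rng(32)
        y = sim.trace.intensities * rng.lognormal(-0.5 * 0.05**2, 0.05, size=len(sim.trace))
        full = TimeCourse(sim.trace.times, y, "ivermectin", "mean")
        res = fit_mitophagy_two_stage(
            fps,
            [full],
            t_stats=(truth.t_mean, truth.t_sd),
            diam_stats=(truth.mt_diam_mean, truth.mt_diam_sd),
            cfg={"n_starts_stage1": 4, "n_starts_stage2": 4, "optimizer_cfg": FAST_CFG},
            seed=7,
        )
        s1 = res.details["stage1"].best_params
        assert s1.kprodATG13 == pytest.approx(truth.kprodATG13, rel=0.15)
        assert s1.kremATG13 == pytest.approx(truth.kremATG13, rel=0.2)
        assert res.best_params.p == pytest.approx(truth.p, rel=0.25)
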