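"""Composite-likelihood fitting machinery, AIC tables and bootstrap CIs."""

import numpy as np
import pytest

from basinflow import (
    DemographicModel,
    FoldedJointSFS,
    InferenceConfig,
    SimulationConfig,
    aic,
    composite_loglik,
    expected_sfs,
    fit_battery,
    fit_model,
    model_average,
    model_table,
    ne_from_pi,
    parametric_bootstrap,
)
from basinflow.demography import FitResult, generations_to_years


class TestScalarHelpers:
    def test_effective_size_from_diversity(self):
        # Ne = pi / (4 mu)
        assert ne_from_pi(0.0011, 3.5e-9) == pytest.approx(78571.4285714, rel=1e-9)
        assert ne_from_pi(0.0, 1e-8) == 0.0
        with pytest.raises(ValueError):
            ne_from_pi(0.001, 0.0)

    def test_generation_time_conversion(self):
        assert generations_to_years(125_711, 1.0) == 125_711.0
        assert generations_to_years(100, 2.5) == 250.0

    def test_aic_definition(self):
        assert aic(-10.0, 3) == 26.0
        assert aic(0.0, 0) == 0.0
        with pytest.raises(ValueError):
            aic(-1.0, -1)


class TestCompositeLoglik:
    def test_hand_computed_value(self):
        obs = np.array([2.0, 3.0, 0.0])
        p = np.array([0.5, 0.3, 0.2])
        want = 2 * np.log(0.5) + 3 * np.log(0.3)
        assert composite_loglik(obs, p, 1e-8) == pytest.approx(want)

    def test_floor_applies_to_zero_probability_cells(self):
        obs = np.array([1.0, 1.0])
        p = np.array([1.0, 0.0])
        assert composite_loglik(obs, p, 1e-4) == pytest.approx(np.log(1e-4))

    def test_maximized_at_observed_proportions(self):
        # multinomial likelihood peaks at p = obs / sum(obs)
        rng = np.random.default_rng(5)
        obs = rng.integers(1, 50, size=12).astype(float)
        p_hat = obs / obs.sum()
        best = composite_loglik(obs, p_hat, 1e-12)
        for _ in range(50):
            q = rng.dirichlet(np.ones(12))
            assert composite_loglik(obs, q, 1e-12) <= best + 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            composite_loglik(np.ones(3), np.ones(4) / 4, 1e-8)


class TestModelTable:
    def test_delta_aic_weights_and_best_flag(self):
        df = model_table([("A", -100.0, 4), ("B", -101.0, 3), ("C", -110.0, 3)])
        assert df.loc["A", "AIC"] == pytest.approx(208.0)
        assert df.loc["B", "AIC"] == pytest.approx(208.0)
        assert df.loc["C", "dAIC"] == pytest.approx(18.0)
        assert df["weight"].sum() == pytest.approx(1.0)
        assert bool(df.loc["A", "best"]) and bool(df.loc["B", "best"])
        assert not bool(df.loc["C", "best"])

    def test_accepts_fit_results(self):
        fr = FitResult("F", {}, -50.0, 8, 1, [-50.0], True, {})
        df = model_table([fr, ("E", -49.0, 9)])
        assert df.loc["F", "AIC"] == pytest.approx(116.0)
        assert df.loc["E", "AIC"] == pytest.approx(116.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no models"):
            model_table([])


class TestModelAverage:
    def test_weighted_mean_of_shared_parameter(self):
        est = {"A": {"t": 10.0}, "B": {"t": 20.0}}
        w = {"A": 0.75, "B": 0.25}
        assert model_average(est, w)["t"] == pytest.approx(12.5)

    def test_parameter_missing_from_one_model_renormalizes(self):
        est = {"A": {"t": 10.0, "m": 1e-6}, "B": {"t": 20.0}}
        w = {"A": 0.5, "B": 0.5}
        out = model_average(est, w)
        assert out["m"] == pytest.approx(1e-6)
        assert out["t"] == pytest.approx(15.0)

    def test_restriction_to_best_set(self):
        est = {"A": {"t": 10.0}, "B": {"t": 20.0}, "C": {"t": 90.0}}
        w = {"A": 0.5, "B": 0.3, "C": 0.2}
        out = model_average(est, w, restrict_to_best=True, best={"A", "B"})
        assert out["t"] == pytest.approx((0.5 * 10 + 0.3 * 20) / 0.8)
        with pytest.raises(ValueError, match="best"):
            model_average(est, w, restrict_to_best=True)


class TestInferenceConfig:
    def test_default_probability_floor_tracks_simulation_count(self):
        cfg = InferenceConfig(theta_s=7.8e4, n_sims=2000)
        assert cfg.floor == pytest.approx(1.0 / 20_000)
        assert InferenceConfig(theta_s=7.8e4, p_min=1e-7).floor == 1e-7

    def test_bounds_dispatch_by_parameter_kind(self):
        cfg = InferenceConfig(theta_s=7.8e4)
        assert cfg.bound("theta_nc") == (1e2, 1e7)
        assert cfg.bound("t_div1") == (1e2, 1e7)
        assert cfg.bound("m_anc") == (1e-9, 1e-2)
        cfg2 = InferenceConfig(theta_s=7.8e4, bounds={"t_div2": (1e3, 1e6)})
        assert cfg2.bound("t_div2") == (1e3, 1e6)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            InferenceConfig(theta_s=0.0)
        with pytest.raises(ValueError):
            InferenceConfig(theta_s=1e4, ecm_min_cycles=5, ecm_max_cycles=2)


def _small_dataset(seed=0, n_sites=3000):
    truth = DemographicModel(
        "F", 1.3e5, 1.0e5, 7.857e4, 1.5e5, 1.0e5, 2.0e4, 1.0e5
    )
    sim = SimulationConfig(n_n=4, n_c=4, n_s=2, n_sims=20_000)
    p = expected_sfs(truth, sim, seed=1234)
    rng = np.random.default_rng(seed + 77)
    counts = rng.multinomial(n_sites, p.ravel()).reshape(p.shape).astype(float)
    return FoldedJointSFS((4, 4, 2), counts, monomorphic_masked=True)


def _cheap_cfg(**kw):
    base = dict(
        theta_s=7.857e4,
        n_replicates=2,
        n_sims=800,
        ecm_min_cycles=2,
        ecm_max_cycles=3,
        golden_iters=8,
        polish_maxfev=0,
        seed=0,
    )
    base.update(kw)
    return InferenceConfig(**base)


class TestFitModel:
    def test_fit_is_deterministic_in_seed(self):
        obs = _small_dataset()
        cfg = _cheap_cfg()
        f1 = fit_model(obs, "F", cfg)
        f2 = fit_model(obs, "F", cfg)
        assert f1.estimates == f2.estimates
        assert f1.lnl == f2.lnl

    def test_reported_lnl_is_best_replicate_when_polish_disabled(self):
        obs = _small_dataset()
        fit = fit_model(obs, "F", _cheap_cfg())
        assert fit.lnl == max(fit.replicate_lnls)
        assert len(fit.replicate_lnls) == 2

    def test_estimates_respect_bounds_and_parameter_count(self):
        obs = _small_dataset()
        cfg = _cheap_cfg()
        fit = fit_model(obs, "E", cfg)
        assert fit.k == 7  # 4 sizes + 2 times + m_nc
        for name, v in fit.estimates.items():
            lo, hi = cfg.bound(name)
            assert lo <= v <= hi
        assert "theta_s" not in fit.estimates

    def test_fixed_southern_size_excluded_from_model_but_used(self):
        obs = _small_dataset()
        fit = fit_model(obs, "F", _cheap_cfg())
        assert fit.k == 6
        assert set(fit.estimates) == {
            "theta_n", "theta_c", "theta_nc", "theta_anc", "t_div1", "t_div2"
        }

    def test_extra_start_enters_candidate_pool(self):
        # with polish disabled the fit returns the best-scoring candidate,
        # so supplying a near-truth extra start can only improve the lnl
        obs = _small_dataset()
        cfg = _cheap_cfg()
        base = fit_model(obs, "F", cfg)
        good = dict(theta_n=1.3e5, theta_c=1.0e5, theta_nc=1.5e5,
                    theta_anc=1.0e5, t_div1=2.0e4, t_div2=1.0e5)
        warm = fit_model(obs, "F", cfg, extra_starts=[good])
        assert warm.lnl >= base.lnl
        assert len(warm.replicate_lnls) == len(base.replicate_lnls) + 1

    def test_extra_start_missing_size_parameter_rejected(self):
        obs = _small_dataset()
        with pytest.raises(ValueError, match="missing"):
            fit_model(obs, "F", _cheap_cfg(), extra_starts=[{"theta_n": 1e5}])

    def test_extra_start_fills_absent_migration_at_lower_bound(self):
        # an F optimum used as an extra start for E lacks m_nc; it must be
        # admitted with the rate at its lower bound rather than rejected
        obs = _small_dataset()
        cfg = _cheap_cfg()
        good = dict(theta_n=1.3e5, theta_c=1.0e5, theta_nc=1.5e5,
                    theta_anc=1.0e5, t_div1=2.0e4, t_div2=1.0e5)
        fit = fit_model(obs, "E", cfg, extra_starts=[good])
        assert len(fit.replicate_lnls) == cfg.n_replicates + 1

    def test_battery_guarantees_nested_likelihood_ordering(self):
        # B nests D, E and F; the warm-started battery scores each nested
        # optimum inside the richer model's candidate pool on a shared
        # surface, so the fitted lnl ordering of exact maximum likelihood
        # is preserved — which independent multistart fits cannot promise
        obs = _small_dataset()
        cfg = _cheap_cfg(
            ecm_min_cycles=3,
            ecm_max_cycles=5,
            golden_iters=10,
            polish_maxfev=100,
            polish_n_sims=2_000,
            final_n_sims=20_000,
            bounds={"m_anc": (1e-9, 1e-4), "m_nc": (1e-9, 1e-4)},
        )
        fits = fit_battery(obs, ["F", "D", "E", "B"], cfg)
        assert set(fits) == {"F", "D", "E", "B"}
        for rich in ("D", "E", "B"):
            assert fits[rich].lnl >= fits["F"].lnl - 1.0
        assert fits["B"].lnl >= fits["D"].lnl - 1.0
        assert fits["B"].lnl >= fits["E"].lnl - 1.0

    def test_time_ordering_constraint_respected(self):
        obs = _small_dataset(seed=3)
        fit = fit_model(obs, "F", _cheap_cfg(seed=3))
        assert fit.estimates["t_div1"] <= fit.estimates["t_div2"]


class TestParametricBootstrap:
    def test_single_replicate_interval_degenerates_to_a_point(self):
        obs = _small_dataset()
        cfg = _cheap_cfg(n_bootstrap=1, bootstrap_replicates=1)
        fit = fit_model(obs, "F", cfg)
        boot = parametric_bootstrap(fit, obs, cfg)
        assert boot.n_failures == 0
        for name, (lo, hi) in boot.intervals.items():
            assert lo == pytest.approx(hi)
            assert len(boot.estimates[name]) == 1

    def test_intervals_are_ordered_and_coverage_query_works(self):
        obs = _small_dataset(seed=1)
        cfg = _cheap_cfg(seed=1, n_bootstrap=4, bootstrap_replicates=1)
        fit = fit_model(obs, "F", cfg)
        boot = parametric_bootstrap(fit, obs, cfg)
        for name, (lo, hi) in boot.intervals.items():
            assert lo <= hi
            mid = np.sqrt(lo * hi)
            assert boot.covers(name, mid)
            assert not boot.covers(name, hi * 10.0)

    def test_empty_observation_rejected(self):
        counts = np.zeros((5, 5, 3))
        obs = FoldedJointSFS((4, 4, 2), counts, monomorphic_masked=True)
        cfg = _cheap_cfg()
        fit = FitResult(
            "F",
            {"theta_n": 1e5, "theta_c": 1e5, "theta_nc": 1e5,
             "theta_anc": 1e5, "t_div1": 1e4, "t_div2": 1e5},
            -1.0, 6, 1, [-1.0], True, {},
        )
        with pytest.raises(ValueError, match="no mass"):
            parametric_bootstrap(fit, obs, cfg)
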