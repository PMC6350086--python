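"""Distribution fitting, copula sampling, PSA propagation, tornado."""

import numpy as np
import pytest
from scipy import stats

from pymslt.errors import ConfigurationError, FitError
from pymslt.pipeline import ModelInputs, Scenario
from pymslt.psa import (ParameterSpec, apply_draw, expected_value_inputs,
                        fit_distribution, load_parameter_specs, run_psa,
                        sample_parameters, spec_mean, tornado)


def _spec(**kw):
    defaults = dict(name="x", family="normal", target="effect.delta_kg",
                    central=1.0, sd=0.1)
    defaults.update(kw)
    return ParameterSpec(**defaults)


class TestFitDistribution:
    def test_gamma_twenty_percent_sd_gives_shape_25(self):
        dist = fit_distribution(_spec(family="gamma", central=2_883_000.0,
                                      sd=None, sd_frac=0.2))
        assert dist.kwds["a"] == pytest.approx(25.0)
        assert dist.mean() == pytest.approx(2_883_000.0, rel=1e-12)

    def test_beta_moment_matching(self):
        dist = fit_distribution(_spec(family="beta", central=0.26, sd=0.052))
        assert dist.mean() == pytest.approx(0.26, rel=1e-9)
        assert dist.std() == pytest.approx(0.052, rel=1e-9)
        rng = np.random.default_rng(0)
        samples = dist.rvs(size=100_000, random_state=rng)
        assert samples.mean() == pytest.approx(0.26, rel=0.01)

    def test_beta_from_interval(self):
        dist = fit_distribution(_spec(family="beta", central=0.1346, sd=None,
                                      ci95=(0.025, 0.25)))
        assert dist.mean() == pytest.approx(0.1346, rel=1e-9)
        assert dist.std() == pytest.approx((0.25 - 0.025) / 3.92, rel=1e-9)

    def test_lognormal_arithmetic_moments(self):
        dist = fit_distribution(_spec(family="lognormal", central=0.03,
                                      sd=None, sd_frac=0.2))
        assert dist.mean() == pytest.approx(0.03, rel=1e-9)
        assert dist.std() == pytest.approx(0.006, rel=1e-9)

    def test_uniform_mean(self):
        dist = fit_distribution(_spec(family="uniform", low=0.0, high=1.0, sd=None))
        assert dist.mean() == pytest.approx(0.5)

    def test_infeasible_beta_moments(self):
        with pytest.raises(FitError):
            fit_distribution(_spec(family="beta", central=0.5, sd=0.6))

    @pytest.mark.parametrize("family,kw", [
        ("normal", dict(central=-0.43, sd=None, ci95=(-0.61, -0.25))),
        ("gamma", dict(central=1.0, sd=None, sd_frac=0.1)),
        ("beta", dict(central=0.7442, sd=None, ci95=(0.5749, 0.8819))),
    ])
    def test_mean_correct_at_1e5_draws(self, family, kw):
        dist = fit_distribution(_spec(family=family, **kw))
        samples = dist.rvs(size=100_000, random_state=np.random.default_rng(7))
        assert samples.mean() == pytest.approx(dist.mean(), rel=0.01)


class TestSampling:
    def test_seed_reproducibility(self):
        specs = load_parameter_specs()
        a = sample_parameters(specs, 50, seed=9)
        b = sample_parameters(specs, 50, seed=9)
        assert a.equals(b)
        assert not a.equals(sample_parameters(specs, 50, seed=10))

    def test_rank_correlation_within_group(self):
        specs = load_parameter_specs()
        draws = sample_parameters(specs, 10_000, seed=4)
        rho = stats.spearmanr(draws["intervention_cost"], draws["p_download"]).statistic
        assert rho == pytest.approx(0.75, abs=0.03)
        rho2 = stats.spearmanr(draws["p_smartphone"], draws["p_exposed"]).statistic
        assert rho2 == pytest.approx(0.75, abs=0.03)

    def test_uncorrelated_parameters_independent(self):
        specs = load_parameter_specs()
        draws = sample_parameters(specs, 10_000, seed=4)
        for other in ("effect_size_kg", "bmi_decay_rate", "pyld_multiplier"):
            rho = stats.spearmanr(draws["p_download"], draws[other]).statistic
            assert abs(rho) < 0.05

    def test_marginals_preserved_under_copula(self):
        specs = load_parameter_specs()
        draws = sample_parameters(specs, 10_000, seed=12)
        for name in ("p_download", "p_regular_use", "intervention_cost",
                     "effect_size_kg", "bmi_decay_rate"):
            spec = next(s for s in specs if s.name == name)
            dist = fit_distribution(spec)
            assert draws[name].mean() == pytest.approx(dist.mean(), rel=0.02)
            assert draws[name].std() == pytest.approx(dist.std(), rel=0.05)

    def test_linear_toy_model_interval_matches_analytic(self):
        # y = 2 x1 - 3 x2 with independent normal inputs has a known
        # normal output; the empirical 95% interval must match it
        specs = [
            _spec(name="x1", family="normal", central=1.0, sd=0.2),
            _spec(name="x2", family="normal", central=-1.0, sd=0.3),
        ]
        draws = sample_parameters(specs, 40_000, seed=5)
        y = 2.0 * draws["x1"] - 3.0 * draws["x2"]
        mu, sigma = 5.0, np.hypot(2 * 0.2, 3 * 0.3)
        lo, hi = np.percentile(y, [2.5, 97.5])
        assert lo == pytest.approx(mu - 1.959964 * sigma, abs=0.03)
        assert hi == pytest.approx(mu + 1.959964 * sigma, abs=0.03)


class TestApplyDraw:
    def test_targets_land(self, central_inputs):
        specs = load_parameter_specs()
        means = {s.name: spec_mean(s) for s in specs}
        means["p_download"] = 0.2
        means["effect_size_kg"] = -0.5
        means["rate_chd_incidence"] = 1.1
        means["tmrel_fraction"] = 1.0
        means["intervention_cost"] = 1_000_000.0
        perturbed = apply_draw(central_inputs, means, specs)
        assert perturbed.cascade.p_download == 0.2
        assert perturbed.effect.delta_kg == -0.5
        assert perturbed.tmrel == pytest.approx(23.0)
        assert perturbed.intervention_cost == 1_000_000.0
        assert np.allclose(
            perturbed.ds.diseases["chd"].incidence,
            np.clip(central_inputs.ds.diseases["chd"].incidence * 1.1, 0, 1))
        # untouched inputs stay at their central values
        assert perturbed.cascade.p_regular_use == central_inputs.cascade.p_regular_use

    def test_effect_size_truncated_at_zero(self, central_inputs):
        specs = load_parameter_specs()
        draw = {s.name: spec_mean(s) for s in specs}
        draw["effect_size_kg"] = 0.4  # harmful draw
        perturbed = apply_draw(central_inputs, draw, specs)
        assert perturbed.effect.delta_kg == 0.0

    def test_lag_draws_rounded_and_ordered(self, central_inputs):
        specs = load_parameter_specs()
        draw = {s.name: spec_mean(s) for s in specs}
        draw["lag_noncancer_upper"] = 6.4
        draw["lag_cancer_lower"] = 11.6
        draw["lag_cancer_upper"] = 11.2
        perturbed = apply_draw(central_inputs, draw, specs)
        assert perturbed.lag_noncancer.upper == 6
        assert perturbed.lag_cancer.lower == 12
        assert perturbed.lag_cancer.upper == 13  # forced above the lower bound


class TestRunPSA:
    def test_degenerate_psa_equals_expected_value_run(self, central_inputs):
        specs = [
            ParameterSpec(name="p_download_fixed", family="uniform",
                          low=0.1346, high=0.1346, target="uptake.p_download",
                          group="app_downloaded"),
        ]
        res = run_psa(central_inputs, Scenario(), specs, n=3, seed=1)
        assert res.n_draws == 3
        assert np.allclose(res.draws["delta_qalys"], res.expected.delta_qalys,
                           rtol=1e-12)
        assert np.allclose(res.draws["net_cost"], res.expected.net_cost,
                           rtol=1e-12)

    def test_interval_orders_and_probability(self, central_inputs):
        specs = load_parameter_specs()
        res = run_psa(central_inputs, Scenario(), specs, n=30, seed=2)
        assert res.ui_qalys[0] <= res.median_qalys <= res.ui_qalys[1]
        assert 0.0 <= res.prob_cost_effective <= 1.0
        assert res.n_rejected == 0

    def test_invalid_n(self, central_inputs):
        with pytest.raises(ConfigurationError):
            run_psa(central_inputs, Scenario(), load_parameter_specs(), n=0)


class TestTornado:
    def test_zero_width_group_has_zero_span_and_ranks_last(self, central_inputs):
        specs = [
            ParameterSpec(name="p_download_wide", family="beta", central=0.1346,
                          ci95=(0.025, 0.25), target="uptake.p_download",
                          group="app_downloaded"),
            ParameterSpec(name="frozen", family="uniform", low=0.26, high=0.26,
                          target="uptake.p_regular_use", group="regular_use"),
        ]
        entries = tornado(central_inputs, Scenario(), specs, n=15, seed=3)
        assert [e.group for e in entries] == ["app_downloaded", "regular_use"]
        assert entries[-1].span == pytest.approx(0.0, abs=1e-9)
        assert all(e.span >= 0.0 for e in entries)

    def test_unknown_group_member_rejected(self, central_inputs):
        specs = load_parameter_specs()
        with pytest.raises(ConfigurationError):
            tornado(central_inputs, Scenario(), specs,
                    grouping={"bad": ["no_such_parameter"]}, n=5)

    def test_empty_grouping_rejected(self, central_inputs):
        with pytest.raises(ConfigurationError):
            tornado(central_inputs, Scenario(), load_parameter_specs(),
                    grouping={}, n=5)


def test_expected_value_inputs_use_distribution_means(central_inputs):
    specs = load_parameter_specs()
    ev = expected_value_inputs(central_inputs, specs)
    assert ev.cascade.p_download == pytest.approx(0.1346, rel=1e-9)
    assert ev.tmrel == pytest.approx(22.0)  # uniform TMREL fraction mean 0.5
    assert ev.effect.delta_kg == pytest.approx(-0.43, rel=1e-9)
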