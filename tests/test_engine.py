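"""Life-table engine: trends, state stepping, paired runs, equity swap."""

import numpy as np
import pytest

from pymslt.engine import (BAU, INT, LAG_NONCANCER, N_YEARS, apply_trends,
                           equity_swap, qaly_accrual, run_mslt, step_disease,
                           step_main)
from pymslt.errors import NumericError
from pymslt.synthpop import N_AGES, generate_baseline


class TestTrends:
    def test_zero_trend_constant(self, ds):
        spec = ds.diseases["osteoarthritis"]  # zero trends by construction
        for year in (2011, 2020, 2080):
            inc, cf, rem = apply_trends(spec, year)
            assert np.array_equal(inc, spec.incidence)
            assert np.array_equal(cf, spec.case_fatality)

    def test_compounding(self, ds):
        spec = ds.diseases["chd"]
        inc, _, _ = apply_trends(spec, 2013)
        factor = (1.0 + spec.trend_inc) ** 2
        assert np.allclose(inc, np.clip(spec.incidence * factor, 0, 1), rtol=1e-12)

    def test_negative_two_percent_example(self, ds):
        import dataclasses
        spec = dataclasses.replace(ds.diseases["chd"], trend_inc=-0.02)
        inc, _, _ = apply_trends(spec, 2013)
        assert np.allclose(inc, spec.incidence * 0.9604, rtol=1e-12)

    def test_frozen_after_2026(self, ds):
        spec = ds.diseases["chd"]
        inc26, cf26, rem26 = apply_trends(spec, 2026)
        inc40, cf40, rem40 = apply_trends(spec, 2040)
        assert np.array_equal(inc26, inc40)
        assert np.array_equal(cf26, cf40)
        assert np.array_equal(rem26, rem40)


class TestStepDisease:
    def test_arithmetic_example(self):
        state = (0.9, 0.1, 0.0)
        (h, p, d), (new, rem, dth) = step_disease(state, 0.01, 0.1, 0.0)
        assert p == pytest.approx(0.1 + 0.009 - 0.01, rel=1e-12)  # 0.099
        assert new == pytest.approx(0.009)
        assert dth == pytest.approx(0.01)
        assert h + p + d == pytest.approx(1.0, abs=1e-15)

    def test_full_pif_stops_inflow(self):
        state = (0.9, 0.1, 0.0)
        (_, p, _), (new, _, _) = step_disease(state, 0.5, 0.0, 0.0, pif_value=1.0)
        assert new == 0.0
        assert p == pytest.approx(0.1)

    def test_conservation_exact(self):
        rng = np.random.default_rng(0)
        state = (0.7, 0.25, 0.05)
        for _ in range(200):
            i, f, r = rng.uniform(0, 0.2, 3)
            state, _ = step_disease(state, i, f, r)
        assert sum(state) == pytest.approx(1.0, abs=1e-12)

    def test_incoherent_rates_raise(self):
        with pytest.raises(NumericError):
            step_disease((0.5, 0.5, 0.0), 0.5, 0.0, 0.0, pif_value=-10.0)


class TestStepMain:
    def test_zero_gap_identity(self):
        a_bau, a_int = step_main(0.8, 0.8, 0.02, 0.2, 0.05, 0.05)
        assert a_bau == a_int

    def test_mortality_relief_arithmetic(self):
        # prevalence gap 0.001 with case fatality 0.2 -> rate reduced by 2e-4
        a_bau, a_int = step_main(1.0, 1.0, 0.02, 0.2, 0.051, 0.050)
        assert a_bau == pytest.approx(0.98)
        assert a_int == pytest.approx(1.0 - (0.02 - 0.0002), rel=1e-12)

    def test_terminal_age_closes_cohort(self):
        a_bau, a_int = step_main(0.3, 0.3, 1.0, 0.0, 0.0, 0.0)
        assert a_bau == 0.0 and a_int == 0.0

    def test_invalid_rate_raises(self):
        with pytest.raises(NumericError):
            step_main(1.0, 1.0, 1.5, 0.0, 0.0, 0.0)


class TestQALYAccrual:
    def test_no_morbidity(self):
        ly, qaly = qaly_accrual(1.0, 0.98, 0.0, 0.0, 0.0, 0.0)
        assert ly == pytest.approx(0.99)
        assert qaly == pytest.approx(ly)

    def test_morbidity_weight(self):
        ly, qaly = qaly_accrual(1.0, 0.98, 0.12, 0.0, 0.0, 0.0)
        assert qaly == pytest.approx(0.88 * ly, rel=1e-12)

    def test_morbidity_relief(self):
        # averted prevalence 0.01 at disability rate 0.2 improves the
        # quality weight by 0.002
        _, q_without = qaly_accrual(1.0, 1.0, 0.12, 0.2, 0.05, 0.05)
        _, q_with = qaly_accrual(1.0, 1.0, 0.12, 0.2, 0.05, 0.04)
        assert q_with - q_without == pytest.approx(0.002, rel=1e-9)


class TestConstantMortalityOracle:
    def test_survival_matches_geometric_closed_form(self, ds):
        flat = ds.copy()
        m = 0.02
        flat.acm_rate[:] = m
        flat.acm_rate[:, :, 110] = 1.0
        flat.pyld_rate[:] = 0.0
        for d in flat.diseases.values():
            d.incidence[:] = 0.0
            d.case_fatality[:] = 0.0
            d.remission[:] = 0.0
        run = run_mslt(flat, np.zeros((1, 2, 2, N_AGES)))
        alive = run.alive[:, 0, 0, 0, BAU]  # age-0 stratum, full horizon
        t = np.arange(111)
        assert np.allclose(alive[:111], (1 - m) ** t, atol=1e-12)
        # undiscounted life expectancy vs the closed-form midpoint sum
        le = run.life_years[:, 0, 0, 0, BAU].sum()
        survival = (1 - m) ** np.arange(112)
        survival[111] = 0.0  # certain death during the age-110 year
        expected = 0.5 * (survival[:-1] + survival[1:]).sum()
        assert le == pytest.approx(expected, abs=1e-6)


class TestPairedRun:
    def test_zero_profile_gives_identical_arms(self, null_run):
        assert np.array_equal(null_run.alive[..., BAU], null_run.alive[..., INT])
        assert np.array_equal(null_run.qalys[..., BAU], null_run.qalys[..., INT])

    def test_alive_non_increasing_and_bounded(self, base_run):
        assert np.all(np.diff(base_run.alive, axis=0) <= 1e-15)
        assert base_run.alive.min() >= 0.0 and base_run.alive.max() <= 1.0

    def test_qalys_bounded_by_life_years(self, base_run):
        assert np.all(base_run.qalys <= base_run.life_years + 1e-15)

    def test_cohort_extinct_at_horizon(self, base_run):
        assert np.all(base_run.alive[-1] == 0.0)

    def test_weight_loss_gains_qalys(self, base_run):
        dq = (base_run.qalys[..., INT] - base_run.qalys[..., BAU]).sum()
        assert dq > 0.0

    def test_monotone_in_effect_size(self, ds):
        from pymslt.intervention import EffectSize, UptakeCascade, effect_profile
        from pymslt.risk import DecayModel
        totals = []
        for kg in (-0.2, -0.43, -0.9):
            profile = effect_profile(ds, UptakeCascade(), EffectSize(delta_kg=kg),
                                     DecayModel())
            run = run_mslt(ds, profile)
            totals.append((run.qalys[..., INT] - run.qalys[..., BAU]).sum())
        assert totals[0] < totals[1] < totals[2]

    def test_effect_locality_by_ethnicity(self, ds, central_inputs):
        from pymslt.intervention import effect_profile
        i = central_inputs
        profile = effect_profile(ds, i.cascade, i.effect, i.decay)
        restricted = profile.delta.copy()
        restricted[:, :, 1, :] = 0.0  # Maori-only intervention
        run = run_mslt(ds, restricted)
        dq = run.qalys[..., INT] - run.qalys[..., BAU]
        assert np.all(dq[:, :, 1, :] == 0.0)
        assert dq[:, :, 0, :].sum() > 0.0


class TestEquitySwap:
    def test_idempotent(self, ds):
        once = equity_swap(ds)
        twice = equity_swap(once)
        assert once == twice

    def test_rates_equalised(self, ds):
        swapped = equity_swap(ds)
        assert np.array_equal(swapped.acm_rate[:, 0], swapped.acm_rate[:, 1])
        assert np.array_equal(swapped.pyld_rate[:, 0], swapped.pyld_rate[:, 1])
        # everything else untouched
        assert np.array_equal(swapped.population, ds.population)
        assert swapped.diseases["chd"].equals(ds.diseases["chd"])
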