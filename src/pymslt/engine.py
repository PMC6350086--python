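"""Proportional multistate life table engine.

A closed cohort (everyone alive in the base year, 2011) is advanced in
annual cycles until extinction at age 110.  Each sex x ethnicity x age
stratum occupies a main life table (alive / dead) and, simultaneously, 14
independent disease life tables with states healthy / prevalent / dead of
the disease, driven by incidence, case fatality and remission (cancers
only).  The intervention arm differs from business-as-usual (BAU) only
through population impact fractions that scale disease inflow, with
mortality and morbidity relief fed back into the main table through the
prevalence difference between the arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericError
from .risk import LagWindow, lagged_series, mean_rr_lognormal
from .synthpop import (AGES, BASE_YEAR, BaselineDataset, DISEASES,
                       DiseaseSpec, MAX_AGE, N_AGES, TREND_END_YEAR)

N_YEARS = N_AGES  # 2011 .. 2121; the youngest stratum reaches age 110

#: default lag windows (years) between BMI change and incidence change
LAG_NONCANCER = LagWindow(0, 5)
LAG_CANCER = LagWindow(10, 30)

#: relative risks act from this attained age onward
MIN_RISK_AGE = 25

BAU, INT = 0, 1  # arm indices


def apply_trends(spec: DiseaseSpec, year: int):
    """Disease rates for a calendar year: annual proportional trends
    compound from the base year and freeze after 2026."""
    n = min(year, TREND_END_YEAR) - BASE_YEAR
    return (
        np.clip(spec.incidence * (1.0 + spec.trend_inc) ** n, 0.0, 1.0),
        np.clip(spec.case_fatality * (1.0 + spec.trend_cf) ** n, 0.0, 1.0),
        np.clip(spec.remission * (1.0 + spec.trend_rem) ** n, 0.0, 1.0),
    )


def trend_factor(trend: float, year: int) -> float:
    return (1.0 + trend) ** (min(year, TREND_END_YEAR) - BASE_YEAR)


def step_disease(state, incidence, case_fatality, remission, pif_value=0.0):
    """One annual cycle of a disease life table.

    ``state`` is ``(healthy, prevalent, dead)``; inflow is scaled by
    ``1 - pif_value``.  Returns ``(new_state, (new_cases, remissions,
    deaths))``; the three states are conserved exactly.
    """
    healthy, prevalent, dead = state
    inflow = incidence * (1.0 - pif_value)
    new_cases = healthy * inflow
    remissions = prevalent * remission
    deaths = prevalent * case_fatality
    healthy2 = healthy - new_cases + remissions
    prevalent2 = prevalent + new_cases - remissions - deaths
    dead2 = dead + deaths
    for name, arr in (("healthy", healthy2), ("prevalent", prevalent2), ("dead", dead2)):
        a = np.asarray(arr)
        if np.any(a < -1e-12) or np.any(a > 1.0 + 1e-12):
            raise NumericError(f"disease state '{name}' left [0, 1] (incoherent rates)")
    return (healthy2, prevalent2, dead2), (new_cases, remissions, deaths)


def step_main(alive_bau, alive_int, acm, case_fatality, prev_bau, prev_int):
    """One annual cycle of the main life table, both arms.

    BAU dies at the all-cause rate; the intervention arm's rate is relieved
    by ``sum_d cf_d * (prev_bau_d - prev_int_d)``, the mortality averted by
    lower disease prevalence (it may be negative once survivors age into
    disease).  Returns ``(alive_bau', alive_int')``.
    """
    relief = np.sum(case_fatality * (np.asarray(prev_bau) - np.asarray(prev_int)),
                    axis=0) if np.ndim(case_fatality) else \
        case_fatality * (prev_bau - prev_int)
    rate_int = np.asarray(acm - relief)
    for rate in (np.asarray(acm), rate_int):
        if np.any(rate < -1e-6) or np.any(rate > 1.0 + 1e-6):
            raise NumericError("mortality rate left [0, 1]")
    # late-sign reversals of the relief can overshoot the closed [0, 1]
    # bounds by float-level amounts at the terminal age; clamp those
    rate_int = np.clip(rate_int, 0.0, 1.0)
    return alive_bau * (1.0 - acm), alive_int * (1.0 - rate_int)


def qaly_accrual(alive_start, alive_end, pyld, dr, prev_bau, prev_arm):
    """Life-years and QALYs lived this year.

    Deaths are credited half a year (midpoint rule); the quality weight is
    ``1 - pyld`` with the morbidity relief ``sum_d dr_d * (prev_bau_d -
    prev_arm_d)`` subtracted from the prevalent-YLD rate, clamped to [0, 1].
    """
    ly = 0.5 * (alive_start + alive_end)
    relief = np.sum(np.asarray(dr) * (np.asarray(prev_bau) - np.asarray(prev_arm)),
                    axis=0) if np.ndim(dr) else dr * (prev_bau - prev_arm)
    weight = 1.0 - np.clip(pyld - relief, 0.0, 1.0)
    return ly, ly * weight


@dataclass
class RunResult:
    """Paired BAU / intervention life-table trajectories.

    All arrays carry the arm on the last axis (0 = BAU, 1 = intervention)
    and are per initial cohort member (proportions), indexed
    ``[year, sex, ethnicity, age_in_2011, ...]``.
    """

    years: np.ndarray                 # (T,) calendar years
    alive: np.ndarray                 # (T+1, 2, 2, 111, 2) start-of-year
    life_years: np.ndarray            # (T, 2, 2, 111, 2)
    qalys: np.ndarray                 # (T, 2, 2, 111, 2)
    prevalent: np.ndarray             # (T, 2, 2, 111, D, 2) start-of-year
    incident: np.ndarray              # (T, 2, 2, 111, D, 2) flow in year
    disease_deaths: np.ndarray        # (T, 2, 2, 111, D, 2) flow in year
    healthy: np.ndarray               # (T, 2, 2, 111, D, 2) start-of-year
    dead_of_disease: np.ndarray       # (T, 2, 2, 111, D, 2) start-of-year
    disease_names: list[str]

    @property
    def n_years(self) -> int:
        return self.years.size


def _group_view(arr: np.ndarray) -> np.ndarray:
    """(2, 2, 111, ...) -> (4, 111, ...) without copying."""
    return arr.reshape((4,) + arr.shape[2:])


def run_mslt(ds: BaselineDataset, profile, tmrel: float = 21.0,
             lag_noncancer: LagWindow = LAG_NONCANCER,
             lag_cancer: LagWindow = LAG_CANCER) -> RunResult:
    """Run both arms to cohort extinction.

    ``profile`` is a :class:`~pymslt.intervention.BMIEffectProfile` or an
    array ``(T, 2, 2, 111)`` of population-mean BMI changes; shorter
    horizons are zero-padded.  Per-year PIFs are derived from the
    lag-window mean of the BMI-change series applied as a location shift
    of each stratum's log-normal BMI distribution, and are forced to zero
    below attained age 25.
    """
    delta = getattr(profile, "delta", profile)
    delta = np.asarray(delta, dtype=float)
    if delta.shape[0] < N_YEARS:
        pad = np.zeros((N_YEARS - delta.shape[0],) + delta.shape[1:])
        delta = np.concatenate([delta, pad], axis=0)
    delta_g = delta.reshape(N_YEARS, 4, N_AGES)

    names = [n for n in DISEASES if n in ds.diseases]
    specs = [ds.diseases[n] for n in names]
    nd = len(names)
    is_cancer = np.array([s.group == "cancer" for s in specs])

    # rate tables in (D, 4, attained-age) layout
    inc0 = np.stack([_group_view(s.incidence) for s in specs])
    cf0 = np.stack([_group_view(s.case_fatality) for s in specs])
    rem0 = np.stack([_group_view(s.remission) for s in specs])
    dr0 = np.stack([_group_view(s.dr) for s in specs])
    rr0 = np.stack([_group_view(s.rr_per_unit) for s in specs])
    log_rr0 = np.log(rr0)
    t_inc = np.array([s.trend_inc for s in specs])
    t_cf = np.array([s.trend_cf for s in specs])
    t_rem = np.array([s.trend_rem for s in specs])

    acm0 = _group_view(ds.acm_rate)
    pyld0 = _group_view(ds.pyld_rate)
    bmi_m0 = _group_view(ds.bmi_mean)
    bmi_s0 = _group_view(ds.bmi_sd)

    # lagged BMI-change series per lag group, (T, 4, 111)
    flat = delta_g.reshape(N_YEARS, -1)
    lag_nc = lagged_series(flat, lag_noncancer).reshape(N_YEARS, 4, N_AGES)
    lag_ca = lagged_series(flat, lag_cancer).reshape(N_YEARS, 4, N_AGES)

    # baseline expected relative risk per (disease, group, attained age):
    # independent of the simulation year, so computed once
    e_rr0 = mean_rr_lognormal(
        bmi_m0[None, :, :], bmi_s0[None, :, :], np.zeros((1, 1, 1)),
        log_rr0, np.full((1, 1, 1), tmrel),
    )  # (D, 4, 111)

    # state arrays: (arm, D, 4, 111)
    p0 = np.stack([_group_view(s.steady_state_prevalence()) for s in specs])
    healthy = np.broadcast_to(1.0 - p0, (2, nd, 4, N_AGES)).copy()
    prevalent = np.broadcast_to(p0, (2, nd, 4, N_AGES)).copy()
    dead = np.zeros((2, nd, 4, N_AGES))
    alive = np.ones((2, 4, N_AGES))

    out_alive = np.zeros((N_YEARS + 1, 4, N_AGES, 2))
    out_ly = np.zeros((N_YEARS, 4, N_AGES, 2))
    out_qaly = np.zeros((N_YEARS, 4, N_AGES, 2))
    out_prev = np.zeros((N_YEARS, 4, N_AGES, nd, 2))
    out_inc = np.zeros((N_YEARS, 4, N_AGES, nd, 2))
    out_dths = np.zeros((N_YEARS, 4, N_AGES, nd, 2))
    out_healthy = np.zeros((N_YEARS, 4, N_AGES, nd, 2))
    out_dead = np.zeros((N_YEARS, 4, N_AGES, nd, 2))

    years = np.arange(BASE_YEAR, BASE_YEAR + N_YEARS)
    out_alive[0] = alive.transpose(1, 2, 0)

    for t in range(N_YEARS):
        year = int(years[t])
        attained = np.minimum(AGES + t, MAX_AGE)
        n_tr = min(year, TREND_END_YEAR) - BASE_YEAR

        inc_t = np.clip(inc0[:, :, attained] * ((1.0 + t_inc) ** n_tr)[:, None, None], 0.0, 1.0)
        cf_t = np.clip(cf0[:, :, attained] * ((1.0 + t_cf) ** n_tr)[:, None, None], 0.0, 1.0)
        rem_t = np.clip(rem0[:, :, attained] * ((1.0 + t_rem) ** n_tr)[:, None, None], 0.0, 1.0)
        dr_t = dr0[:, :, attained]
        acm_t = acm0[:, attained]
        pyld_t = pyld0[:, attained]

        # --- population impact fractions -------------------------------
        pif = np.zeros((nd, 4, N_AGES))
        adult = attained >= MIN_RISK_AGE
        for window_delta, dis_mask in ((lag_nc[t], ~is_cancer), (lag_ca[t], is_cancer)):
            cells = (window_delta != 0.0) & adult[None, :]
            if not cells.any():
                continue
            g_idx, a_idx = np.nonzero(cells)
            d_idx = np.nonzero(dis_mask)[0]
            m = bmi_m0[g_idx, attained[a_idx]]
            s = bmi_s0[g_idx, attained[a_idx]]
            dlt = window_delta[g_idx, a_idx]
            lrr = log_rr0[d_idx][:, g_idx, attained[a_idx]]  # (d, cells)
            e1 = mean_rr_lognormal(m[None, :], s[None, :], dlt[None, :],
                                   lrr, np.full((1, 1), tmrel))
            e0 = e_rr0[d_idx][:, g_idx, attained[a_idx]]
            pif[d_idx[:, None], g_idx[None, :], a_idx[None, :]] = 1.0 - e1 / e0

        # --- disease life tables (both arms) ----------------------------
        out_prev[t] = prevalent.transpose(2, 3, 1, 0)
        out_healthy[t] = healthy.transpose(2, 3, 1, 0)
        out_dead[t] = dead.transpose(2, 3, 1, 0)
        inflow = np.stack([inc_t, inc_t * (1.0 - pif)])  # (arm, D, 4, 111)
        new_cases = healthy * inflow
        remissions = prevalent * rem_t[None]
        dths = prevalent * cf_t[None]
        healthy = healthy - new_cases + remissions
        prevalent = prevalent + new_cases - remissions - dths
        dead = dead + dths
        if np.any(prevalent < -1e-12) or np.any(prevalent > 1.0 + 1e-12) \
                or np.any(healthy < -1e-12):
            raise NumericError(f"disease state left [0, 1] in {year} (incoherent rates)")
        out_inc[t] = new_cases.transpose(2, 3, 1, 0)
        out_dths[t] = dths.transpose(2, 3, 1, 0)

        # --- main life table --------------------------------------------
        prev_start = out_prev[t]  # (4, 111, D, arm)
        prev_gap = (prev_start[..., BAU] - prev_start[..., INT]).transpose(2, 0, 1)
        relief_m = np.einsum("dga,dga->ga", cf_t, prev_gap)
        rate_int = acm_t - relief_m
        if np.any(rate_int < -1e-6) or np.any(rate_int > 1.0 + 1e-6):
            raise NumericError(f"adjusted mortality left [0, 1] in {year}")
        # the cohort closes with certainty at the terminal age regardless
        # of any residual prevalence-gap relief
        rate_int = np.where(acm_t >= 1.0, acm_t, np.clip(rate_int, 0.0, 1.0))
        alive_end = np.stack([alive[BAU] * (1.0 - acm_t),
                              alive[INT] * (1.0 - rate_int)])
        ly = 0.5 * (alive + alive_end)

        relief_q = np.einsum("dga,dga->ga", dr_t, prev_gap)
        weight = np.stack([1.0 - np.clip(pyld_t, 0.0, 1.0),
                           1.0 - np.clip(pyld_t - relief_q, 0.0, 1.0)])
        qaly = ly * weight

        out_ly[t] = ly.transpose(1, 2, 0)
        out_qaly[t] = qaly.transpose(1, 2, 0)
        alive = alive_end
        out_alive[t + 1] = alive.transpose(1, 2, 0)

    shape5 = (2, 2, N_AGES, 2)
    shape6 = (2, 2, N_AGES, nd, 2)
    return RunResult(
        years=years,
        alive=out_alive.reshape((N_YEARS + 1,) + shape5),
        life_years=out_ly.reshape((N_YEARS,) + shape5),
        qalys=out_qaly.reshape((N_YEARS,) + shape5),
        prevalent=out_prev.reshape((N_YEARS,) + shape6),
        incident=out_inc.reshape((N_YEARS,) + shape6),
        disease_deaths=out_dths.reshape((N_YEARS,) + shape6),
        healthy=out_healthy.reshape((N_YEARS,) + shape6),
        dead_of_disease=out_dead.reshape((N_YEARS,) + shape6),
        disease_names=names,
    )


def equity_swap(ds: BaselineDataset) -> BaselineDataset:
    """Replace Maori all-cause mortality and morbidity with the same-sex,
    same-age non-Maori rates (equity counterfactual); idempotent."""
    out = ds.copy()
    out.acm_rate[:, 0, :] = ds.acm_rate[:, 1, :]
    out.pyld_rate[:, 0, :] = ds.pyld_rate[:, 1, :]
    return out
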