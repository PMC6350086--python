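"""Health-system costs, discounting, ICERs and result summaries.

Costs follow the staged model: everyone alive and free of a modelled
disease (and not dying of one) accrues a sex- and age-specific baseline
annual cost; excess costs attach to the first year after diagnosis, to
otherwise-prevalent years, and to the last six months of life when dying
of the disease.  Net cost of a scenario is the one-off intervention cost
plus the discounted difference in projected health-system expenditure —
so extra longevity in the intervention arm buys extra baseline cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NumericError, UndefinedICERError
from .synthpop import AGES, BASE_YEAR, BaselineDataset, MAX_AGE, N_AGES
from .engine import BAU, INT, RunResult

PPP_NZD_PER_USD = 1.486


def accrue_costs(run: RunResult, ds: BaselineDataset) -> np.ndarray:
    """Per-year, per-stratum, per-arm health-system cost, NZ$ per initial
    cohort member (undiscounted).

    Disease-table proportions are applied to the mid-year alive
    population; the baseline cost covers the alive fraction net of
    prevalent cases (disease deaths occur out of the prevalent state, so
    they are already excluded).
    """
    T = run.n_years
    cost = np.zeros((T, 2, 2, N_AGES, 2))
    cfy = np.array([ds.diseases[n].cost_first_year for n in run.disease_names])
    cp = np.array([ds.diseases[n].cost_prevalent for n in run.disease_names])
    c6m = np.array([ds.diseases[n].cost_last6m for n in run.disease_names])
    if np.any(cfy < 0) or np.any(cp < 0) or np.any(c6m < 0) or np.any(ds.base_cost < 0):
        raise NumericError("negative cost component")
    for t in range(T):
        attained = np.minimum(AGES + t, MAX_AGE)
        base_t = ds.base_cost[:, attained]  # (sex, age0)
        ly = run.life_years[t]              # (2, 2, 111, arm)
        prev = run.prevalent[t]             # (2, 2, 111, D, arm)
        inc = run.incident[t]
        dths = run.disease_deaths[t]
        healthy_share = np.clip(1.0 - prev.sum(axis=3), 0.0, 1.0)
        disease_cost = (
            np.einsum("seadr,d->sear", inc, cfy)
            + np.einsum("seadr,d->sear", np.clip(prev - inc, 0.0, None), cp)
            + np.einsum("seadr,d->sear", dths, c6m)
        )
        cost[t] = ly * (base_t[:, None, :, None] * healthy_share + disease_cost)
    return cost


def discount(stream: np.ndarray, rate: float, base: int = BASE_YEAR,
             years: np.ndarray | None = None):
    """Discounted total of a per-year stream (year-end convention).

    ``stream`` has years on axis 0; ``years`` defaults to consecutive
    calendar years starting at ``base``.
    """
    if rate < 0.0:
        raise ConfigurationError("discount rate must be non-negative")
    stream = np.asarray(stream, dtype=float)
    if years is None:
        years = base + np.arange(stream.shape[0])
    factors = (1.0 + rate) ** -(np.asarray(years) - base)
    return np.tensordot(factors, stream, axes=(0, 0))


@dataclass
class ICER:
    """Incremental cost-effectiveness ratio with a dominance flag."""

    value: float
    cost_saving: bool = False

    def __float__(self) -> float:
        return self.value


def icer(delta_cost: float, delta_qalys: float) -> ICER:
    """NZ$ per QALY gained; flagged cost-saving when costs fall while
    health improves."""
    if delta_qalys == 0.0:
        raise UndefinedICERError("ICER undefined for zero QALY difference")
    return ICER(value=delta_cost / delta_qalys,
                cost_saving=delta_cost < 0.0 < delta_qalys)


def to_usd(nzd: float, ppp: float = PPP_NZD_PER_USD,
           sig_figs: int | None = None) -> float:
    """Convert NZ$ to US$ at purchasing power parity, optionally rounding
    to a number of significant figures for reporting."""
    if ppp <= 0.0:
        raise ConfigurationError("ppp factor must be positive")
    usd = nzd / ppp
    if sig_figs is not None and usd != 0.0:
        from math import floor, log10
        ndigits = sig_figs - 1 - floor(log10(abs(usd)))
        usd = round(usd, ndigits)
        if ndigits <= 0:
            usd = float(int(usd))
    return usd


@dataclass
class ScenarioResult:
    """Discounted outcomes of one scenario run."""

    delta_qalys: float                       # total, scope age >= 25 in 2011
    net_cost: float                          # NZ$, intervention cost included
    cost_offsets: float                      # NZ$, future expenditure change
    intervention_cost: float                 # NZ$
    delta_qalys_by_stratum: np.ndarray       # (2, 2, 111)
    delta_cost_by_stratum: np.ndarray        # (2, 2, 111) offsets only
    per_1000_adults: float
    per_1000_overweight: float
    by_ethnicity: dict[str, float] = field(default_factory=dict)
    by_sex: dict[str, float] = field(default_factory=dict)
    age_standardized_per_1000: dict[str, float] = field(default_factory=dict)
    icer_nzd: float | None = None
    icer_usd: float | None = None
    cost_saving: bool = False

    @property
    def summary(self) -> dict:
        return {
            "delta_qalys": self.delta_qalys,
            "net_cost_nzd": self.net_cost,
            "icer_nzd_per_qaly": self.icer_nzd,
            "icer_usd_per_qaly": self.icer_usd,
            "cost_saving": self.cost_saving,
            "per_1000_adults": self.per_1000_adults,
            "per_1000_overweight": self.per_1000_overweight,
            "by_ethnicity": dict(self.by_ethnicity),
            "by_sex": dict(self.by_sex),
            "age_standardized_per_1000": dict(self.age_standardized_per_1000),
        }


def summarize(run: RunResult, ds: BaselineDataset, *, discount_rate: float = 0.03,
              intervention_cost_total: float = 0.0, min_age: int = 25,
              ppp: float = PPP_NZD_PER_USD) -> ScenarioResult:
    """Reduce a paired run to discounted scenario outcomes.

    Results are scoped to strata aged ``min_age`` and over in the base
    year (relative risks act from age 25, so younger strata are pure
    noise-free zeros).  Per-capita rates are QALYs per 1000 adults;
    ethnic-group rates are also directly age-standardized with the
    dataset's standard population weights.
    """
    if min_age > MAX_AGE:
        raise ConfigurationError("empty reporting scope")
    dq_y = run.qalys[..., INT] - run.qalys[..., BAU]       # (T, 2, 2, 111)
    cost = accrue_costs(run, ds)
    dc_y = cost[..., INT] - cost[..., BAU]

    dq_s = discount(dq_y, discount_rate) * ds.population   # (2, 2, 111)
    dc_s = discount(dc_y, discount_rate) * ds.population

    scope = AGES >= min_age
    dq_scope = dq_s[:, :, scope]
    dc_scope = dc_s[:, :, scope]
    pop_scope = ds.population[:, :, scope]

    total_dq = float(dq_scope.sum())
    offsets = float(dc_scope.sum())
    net = intervention_cost_total + offsets

    adults = float(pop_scope.sum())
    ow_adults = float((pop_scope * ds.overweight_prop[:, :, scope]).sum())
    per_1000 = 1000.0 * total_dq / adults
    per_1000_ow = 1000.0 * total_dq / ow_adults if ow_adults > 0 else 0.0

    by_eth = {}
    age_std = {}
    w = ds.standard_population[scope]
    for ei, eth in enumerate(("maori", "non_maori")):
        by_eth[eth] = float(dq_scope[:, ei].sum())
        rate_a = dq_scope[:, ei].sum(axis=0)
        pop_a = pop_scope[:, ei].sum(axis=0)
        valid = pop_a > 0
        rates = np.zeros_like(rate_a)
        rates[valid] = rate_a[valid] / pop_a[valid]
        age_std[eth] = float(1000.0 * (w[valid] * rates[valid]).sum() / w[valid].sum())
    by_sex = {sex: float(dq_scope[si].sum()) for si, sex in enumerate(("male", "female"))}

    icer_nzd = icer_usd = None
    saving = False
    if total_dq > 0:
        ratio = icer(net, total_dq)
        icer_nzd, saving = ratio.value, ratio.cost_saving
        icer_usd = to_usd(icer_nzd, ppp)

    return ScenarioResult(
        delta_qalys=total_dq,
        net_cost=net,
        cost_offsets=offsets,
        intervention_cost=intervention_cost_total,
        delta_qalys_by_stratum=dq_s,
        delta_cost_by_stratum=dc_s,
        per_1000_adults=per_1000,
        per_1000_overweight=per_1000_ow,
        by_ethnicity=by_eth,
        by_sex=by_sex,
        age_standardized_per_1000=age_std,
        icer_nzd=icer_nzd,
        icer_usd=icer_usd,
        cost_saving=saving,
    )
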