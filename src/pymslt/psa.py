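"""Probabilistic sensitivity analysis and tornado decomposition.

Parameter uncertainty is described by a catalogue of marginal
distributions (beta / gamma / log-normal / normal / uniform, fitted by
moment matching from a mean plus an sd or 95% interval).  Draws are taken
through a Gaussian copula so that parameters sharing a correlation group
have rank correlation 0.75 while every marginal is preserved; each draw
is pushed through the whole pipeline (cascade -> BMI profile -> life
table -> economics).  The tornado decomposition re-runs the PSA one
parameter group at a time, holding everything else at its central value,
and ranks groups by the 2.5-97.5 percentile span of the output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace as dc_replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import ndtr

from . import intervention as iv
from .econ import ScenarioResult
from .errors import ConfigurationError, FitError, NumericError
from .pipeline import ModelInputs, Scenario, run_scenario
from .risk import DecayModel, LagWindow
from .synthpop import CANCERS, DISEASES, ETHNICITIES, SEXES

#: rank correlation within a correlation group
GROUP_RANK_CORRELATION = 0.75
#: latent (Pearson) correlation giving that Spearman value under the copula
_LATENT_RHO = 2.0 * np.sin(np.pi * GROUP_RANK_CORRELATION / 6.0)

DEFAULT_THRESHOLD_NZD = 45_000.0


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input."""

    name: str
    family: str                       # normal | lognormal | beta | gamma | uniform
    target: str
    central: float = 0.0
    sd: float | None = None
    sd_frac: float | None = None
    ci95: tuple[float, float] | None = None
    low: float | None = None
    high: float | None = None
    group: str = "other"
    correlation_group: str | None = None
    truncate_max: float | None = None

    def resolved_sd(self) -> float | None:
        if self.sd is not None:
            return self.sd
        if self.sd_frac is not None:
            return abs(self.central) * self.sd_frac
        if self.ci95 is not None:
            return (self.ci95[1] - self.ci95[0]) / 3.92
        return None


def load_parameter_specs() -> list[ParameterSpec]:
    """Load the packaged parameter catalogue, expanding the per-disease
    rate, trend and relative-risk templates."""
    text = resources.files("pymslt.data").joinpath("parameters.yaml").read_text()
    raw = yaml.safe_load(text)
    specs: list[ParameterSpec] = []
    for entry in raw["parameters"]:
        entry = dict(entry)
        if "ci95" in entry:
            entry["ci95"] = tuple(entry["ci95"])
        specs.append(ParameterSpec(**entry))
    for tmpl in raw.get("expansions", []):
        kind = tmpl["kind"]
        if kind == "disease_rates":
            for name in DISEASES:
                rates = ["incidence", "case_fatality"]
                if name in CANCERS:
                    rates.append("remission")
                for rate in rates:
                    specs.append(ParameterSpec(
                        name=f"rate_{name}_{rate}", family=tmpl["family"],
                        central=tmpl["central"], sd_frac=tmpl["sd_frac"],
                        group=tmpl["group"], target=f"disease.{name}.{rate}"))
        elif kind == "disease_trends":
            for name in DISEASES:
                sd = tmpl["diabetes_sd"] if name == "diabetes" else tmpl["sd"]
                trends = ["trend_inc", "trend_cf"]
                if name in CANCERS:
                    trends.append("trend_rem")
                for tr in trends:
                    specs.append(ParameterSpec(
                        name=f"{tr}_{name}", family=tmpl["family"],
                        central=tmpl["central"], sd=sd,
                        group=tmpl["group"], target=f"disease.{name}.{tr}"))
        elif kind == "relative_risks":
            for name in DISEASES:
                specs.append(ParameterSpec(
                    name=f"rr_{name}", family=tmpl["family"],
                    central=tmpl["central"], sd_frac=tmpl["sd_frac"],
                    group=tmpl["group"], target=f"disease.{name}.rr_exponent"))
        else:
            raise ConfigurationError(f"unknown expansion kind '{kind}'")
    return specs


class _Degenerate:
    """Point-mass 'distribution' for zero-width uncertainty."""

    def __init__(self, value: float):
        self.value = float(value)

    def ppf(self, u):
        return np.full_like(np.asarray(u, dtype=float), self.value)

    def mean(self):
        return self.value

    def std(self):
        return 0.0

    def rvs(self, size=1, random_state=None):
        return np.full(size, self.value)


def fit_distribution(spec: ParameterSpec):
    """Frozen scipy distribution matching the spec's mean and sd.

    Beta and gamma are fitted by the method of moments; the log-normal is
    parameterised from its *arithmetic* mean and sd; uniform uses its
    bounds directly.  Zero-width uncertainty yields a point mass.
    """
    if spec.family == "uniform":
        if spec.low is None or spec.high is None or spec.high < spec.low:
            raise FitError(f"{spec.name}: uniform needs low <= high")
        if spec.high == spec.low:
            return _Degenerate(spec.low)
        return stats.uniform(loc=spec.low, scale=spec.high - spec.low)
    sd = spec.resolved_sd()
    if sd is None or sd < 0:
        raise FitError(f"{spec.name}: no usable sd")
    if sd == 0.0:
        return _Degenerate(spec.central)
    m = spec.central
    if spec.family == "normal":
        return stats.norm(loc=m, scale=sd)
    if spec.family == "lognormal":
        if m <= 0:
            raise FitError(f"{spec.name}: log-normal needs positive mean")
        cv2 = (sd / m) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        return stats.lognorm(s=sigma, scale=m * np.exp(-sigma ** 2 / 2.0))
    if spec.family == "beta":
        if not 0 < m < 1:
            raise FitError(f"{spec.name}: beta needs mean in (0, 1)")
        if sd ** 2 >= m * (1 - m):
            raise FitError(f"{spec.name}: sd^2 >= m(1-m), infeasible beta moments")
        nu = m * (1 - m) / sd ** 2 - 1.0
        return stats.beta(a=m * nu, b=(1 - m) * nu)
    if spec.family == "gamma":
        if m <= 0:
            raise FitError(f"{spec.name}: gamma needs positive mean")
        shape = (m / sd) ** 2
        return stats.gamma(a=shape, scale=sd ** 2 / m)
    raise FitError(f"{spec.name}: unknown family '{spec.family}'")


def spec_mean(spec: ParameterSpec) -> float:
    """Expected value of the fitted marginal (for expected-value runs)."""
    return float(fit_distribution(spec).mean())


def sample_parameters(specs: list[ParameterSpec], n: int,
                      seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` correlated parameter sets through a Gaussian copula.

    Latent normals within a named correlation group share pairwise
    correlation ``2 sin(pi 0.75 / 6)`` so the resulting rank correlation
    is 0.75; marginals are recovered through each inverse CDF.
    """
    k = len(specs)
    corr = np.eye(k)
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        if s.correlation_group:
            groups.setdefault(s.correlation_group, []).append(i)
    for idx in groups.values():
        for i in idx:
            for j in idx:
                if i != j:
                    corr[i, j] = _LATENT_RHO
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("correlation matrix not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k)) @ chol.T
    u = np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)
    out = {}
    for i, s in enumerate(specs):
        x = fit_distribution(s).ppf(u[:, i])
        if s.truncate_max is not None:
            x = np.minimum(x, s.truncate_max)
        out[s.name] = x
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# applying a draw to the model inputs
# ---------------------------------------------------------------------------

def apply_draw(base: ModelInputs, draw: dict[str, float],
               specs: list[ParameterSpec]) -> ModelInputs:
    """Build a perturbed copy of the model inputs from one parameter draw."""
    by_name = {s.name: s for s in specs}
    ds = base.ds.copy()
    cascade_kw = dict(
        p_smartphone=base.cascade.p_smartphone,
        p_exposed=base.cascade.p_exposed,
        p_download=base.cascade.p_download,
        p_regular_use=base.cascade.p_regular_use,
        download_multiplier=base.cascade.download_multiplier,
    )
    effect_kg = base.effect.delta_kg
    decay_rate = base.decay.rate
    tmrel = base.tmrel
    lag_nc_upper = base.lag_noncancer.upper
    lag_ca = [base.lag_cancer.lower, base.lag_cancer.upper]
    cost_override = base.intervention_cost_override

    for name, value in draw.items():
        target = by_name[name].target
        parts = target.split(".")
        if parts[0] == "uptake":
            cascade_kw[parts[1]] = float(np.clip(value, 0.0, 1.0))
        elif target == "effect.delta_kg":
            effect_kg = min(0.0, float(value))
        elif target == "decay.rate":
            decay_rate = max(0.0, float(value))
        elif target == "cost.total":
            cost_override = max(0.0, float(value))
        elif target == "cost.base":
            ds.base_cost *= max(0.0, value)
        elif target == "cost.disease":
            v = max(0.0, float(value))
            for d in ds.diseases.values():
                d.cost_first_year *= v
                d.cost_prevalent *= v
                d.cost_last6m *= v
        elif target == "risk.tmrel_fraction":
            tmrel = 21.0 + 2.0 * float(np.clip(value, 0.0, 1.0))
        elif target == "lag.noncancer_upper":
            lag_nc_upper = max(1, int(round(value)))
        elif target == "lag.cancer_lower":
            lag_ca[0] = max(1, int(round(value)))
        elif target == "lag.cancer_upper":
            lag_ca[1] = int(round(value))
        elif target == "morbidity.pyld":
            ds.pyld_rate = np.clip(ds.pyld_rate * max(0.0, value), 0.0, 1.0)
        elif target == "morbidity.dr":
            v = max(0.0, float(value))
            for d in ds.diseases.values():
                d.dr = d.dr * v
        elif parts[0] == "height":
            si = SEXES.index(parts[1])
            ei = ETHNICITIES.index(parts[2])
            ds.height_mean[si, ei] *= max(0.1, value)
        elif parts[0] == "disease":
            dis = ds.diseases[parts[1]]
            field = parts[2]
            if field in ("incidence", "case_fatality", "remission"):
                arr = getattr(dis, field)
                setattr(dis, field, np.clip(arr * max(0.0, value), 0.0, 1.0))
            elif field.startswith("trend_"):
                setattr(dis, field, getattr(dis, field) + float(value))
            elif field == "rr_exponent":
                dis.rr_per_unit = np.maximum(dis.rr_per_unit ** max(0.0, value), 1.0)
            else:
                raise ConfigurationError(f"unknown disease target '{target}'")
        else:
            raise ConfigurationError(f"unknown parameter target '{target}'")

    lag_ca[1] = max(lag_ca[0] + 1, lag_ca[1])
    return ModelInputs(
        ds=ds,
        cascade=iv.UptakeCascade(**cascade_kw),
        effect=iv.EffectSize(delta_kg=effect_kg, ci_95=base.effect.ci_95),
        decay=DecayModel(rate=decay_rate, enabled=base.decay.enabled),
        costs=base.costs,
        tmrel=tmrel,
        lag_noncancer=LagWindow(0, lag_nc_upper),
        lag_cancer=LagWindow(lag_ca[0], lag_ca[1]),
        intervention_cost_override=cost_override,
    )


# ---------------------------------------------------------------------------
# PSA driver
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Draws and summaries of one probabilistic run."""

    n_draws: int
    draws: pd.DataFrame               # delta_qalys, net_cost, icer per draw
    expected: ScenarioResult          # run at every parameter's mean
    mean_qalys: float
    median_qalys: float
    ui_qalys: tuple[float, float]
    mean_cost: float
    median_cost: float
    ui_cost: tuple[float, float]
    prob_cost_effective: float
    threshold_nzd: float
    n_rejected: int = 0


def _percentiles(x: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))


def expected_value_inputs(base: ModelInputs,
                          specs: list[ParameterSpec]) -> ModelInputs:
    """Inputs with every catalogued parameter at its distribution mean."""
    means = {s.name: spec_mean(s) for s in specs}
    return apply_draw(base, means, specs)


def run_psa(base: ModelInputs, scenario: Scenario, specs: list[ParameterSpec],
            n: int = 2000, seed: int = 0,
            threshold: float = DEFAULT_THRESHOLD_NZD,
            vary: set[str] | None = None) -> PSAResult:
    """Propagate ``n`` correlated draws through the full pipeline.

    ``vary`` restricts sampling to a subset of parameter names, holding
    the rest at their distribution means (used by the tornado).  Draws
    that break the model's numeric invariants are rejected and counted;
    more than 1% rejections aborts.
    """
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    means = {s.name: spec_mean(s) for s in specs}
    varied = [s for s in specs if vary is None or s.name in vary]
    samples = sample_parameters(varied, n, seed)

    rows = []
    n_rejected = 0
    for i in range(n):
        draw = dict(means)
        for s in varied:
            draw[s.name] = float(samples[s.name].iloc[i])
        try:
            inputs = apply_draw(base, draw, specs)
            res = run_scenario(inputs, scenario)
        except NumericError:
            n_rejected += 1
            if n_rejected > max(1, 0.01 * n):
                raise RuntimeError(f"more than 1% of draws rejected ({n_rejected}/{i + 1})")
            continue
        rows.append((res.delta_qalys, res.net_cost))
    draws = pd.DataFrame(rows, columns=["delta_qalys", "net_cost"])
    with np.errstate(divide="ignore", invalid="ignore"):
        draws["icer"] = draws["net_cost"] / draws["delta_qalys"]

    expected = run_scenario(expected_value_inputs(base, specs), scenario)
    dq = draws["delta_qalys"].to_numpy()
    dc = draws["net_cost"].to_numpy()
    ce = (dq > 0) & ((dc < 0) | (dc / np.where(dq > 0, dq, np.inf) < threshold))
    return PSAResult(
        n_draws=len(draws),
        draws=draws,
        expected=expected,
        mean_qalys=float(dq.mean()),
        median_qalys=float(np.median(dq)),
        ui_qalys=_percentiles(dq),
        mean_cost=float(dc.mean()),
        median_cost=float(np.median(dc)),
        ui_cost=_percentiles(dc),
        prob_cost_effective=float(ce.mean()),
        threshold_nzd=threshold,
        n_rejected=n_rejected,
    )


# ---------------------------------------------------------------------------
# tornado decomposition
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    group: str
    low: float
    high: float

    @property
    def span(self) -> float:
        return self.high - self.low


def tornado(base: ModelInputs, scenario: Scenario, specs: list[ParameterSpec],
            grouping: dict[str, list[str]] | None = None, n: int = 500,
            seed: int = 0, output: str = "delta_qalys") -> list[TornadoEntry]:
    """One-group-at-a-time percentile-span tornado.

    For each group, only its parameters are drawn (everything else held
    central) and the 2.5-97.5 percentile span of the chosen output
    (``delta_qalys`` or ``net_cost``) is recorded; entries come back
    sorted by descending span.
    """
    if output not in ("delta_qalys", "net_cost"):
        raise ConfigurationError(f"unknown tornado output '{output}'")
    if grouping is None:
        grouping = {}
        for s in specs:
            grouping.setdefault(s.group, []).append(s.name)
    if not grouping:
        raise ConfigurationError("empty tornado grouping")
    known = {s.name for s in specs}
    for group, names in grouping.items():
        unknown = set(names) - known
        if unknown:
            raise ConfigurationError(
                f"tornado group '{group}' names unknown parameter {sorted(unknown)[0]!r}")

    entries = []
    rng = np.random.default_rng(seed)
    for group in sorted(grouping):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        res = run_psa(base, scenario, specs, n=n, seed=sub_seed,
                      vary=set(grouping[group]))
        values = res.draws[output].to_numpy()
        low, high = _percentiles(values)
        entries.append(TornadoEntry(group=group, low=low, high=high))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.group, e.low, e.high, e.span, rank + 1)
         for rank, e in enumerate(entries)],
        columns=["group", "low", "high", "span", "rank"],
    )
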