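"""Synthetic baseline dataset generator.

Builds a seeded, New-Zealand-like baseline for the cost-effectiveness model:
a closed cohort of sex x ethnicity (Maori / non-Maori) x single-year-of-age
strata with population counts, all-cause mortality, prevalent-YLD morbidity,
health-system costs, BMI and height distributions, and a coherent
incidence / case-fatality / remission rate table for each of the 14
BMI-related diseases.  No real registry data are used anywhere; the
generator reproduces the *statistical structure* the model assumes
(Gompertz-Makeham mortality with a Maori hazard excess, right-skewed
log-normal BMI, age-exponential cardiovascular rates, mid-life diabetes
incidence peak, low-incidence cancers whose remission complements case
fatality to an approximate five-year sojourn).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

SEXES = ("male", "female")
ETHNICITIES = ("maori", "non_maori")
MAX_AGE = 110
N_AGES = MAX_AGE + 1
BASE_YEAR = 2011
TREND_END_YEAR = 2026

AGES = np.arange(N_AGES)
#: midpoints of the 5-year bands on which rate templates are specified
BAND_MIDPOINTS = np.arange(2.5, 108.0, 5.0)

NONCANCERS = ("chd", "stroke", "diabetes", "osteoarthritis")
CANCERS = (
    "endometrial_ca",
    "kidney_ca",
    "liver_ca",
    "esophageal_ca",
    "pancreatic_ca",
    "thyroid_ca",
    "colorectal_ca",
    "breast_ca",
    "ovarian_ca",
    "gallbladder_ca",
)
DISEASES = NONCANCERS + CANCERS

#: diseases modelled as occurring in women only
FEMALE_ONLY = ("endometrial_ca", "breast_ca", "ovarian_ca")

N_STRATA = len(SEXES) * len(ETHNICITIES) * N_AGES  # 444


def strata_frame() -> pd.DataFrame:
    """Enumerate the 444 strata in canonical (sex, ethnicity, age) order."""
    rows = [
        (sex, eth, age)
        for sex in SEXES
        for eth in ETHNICITIES
        for age in AGES
    ]
    return pd.DataFrame(rows, columns=["sex", "ethnicity", "age"])


def expand_bands(band_values: np.ndarray) -> np.ndarray:
    """Expand a 5-year-band template to single years of age.

    Values are anchored at band midpoints and linearly interpolated;
    ends are held constant beyond the outermost midpoints.
    """
    band_values = np.asarray(band_values, dtype=float)
    if band_values.shape != BAND_MIDPOINTS.shape:
        raise ConfigurationError(
            f"band template needs {BAND_MIDPOINTS.size} values, "
            f"got {band_values.size}"
        )
    return np.interp(AGES, BAND_MIDPOINTS, band_values)


def _anchor_template(anchor_ages, anchor_values) -> np.ndarray:
    """Anchor points -> 5-year bands -> single years."""
    bands = np.interp(BAND_MIDPOINTS, anchor_ages, anchor_values)
    return expand_bands(bands)


@dataclass
class DiseaseSpec:
    """Rates, risks and stage costs for one disease.

    Rate arrays are indexed ``[sex, ethnicity, attained age]`` with shape
    ``(2, 2, 111)``; trends and stage costs are scalars, repeated per row
    in the CSV schema.
    """

    name: str
    group: str  # "noncancer" | "cancer"
    incidence: np.ndarray
    case_fatality: np.ndarray
    remission: np.ndarray
    dr: np.ndarray  # disability rate per prevalent case
    rr_per_unit: np.ndarray  # relative risk per BMI unit above TMREL
    trend_inc: float = 0.0
    trend_cf: float = 0.0
    trend_rem: float = 0.0
    cost_first_year: float = 0.0
    cost_prevalent: float = 0.0
    cost_last6m: float = 0.0

    @property
    def lag_window(self) -> tuple[int, int]:
        return (10, 30) if self.group == "cancer" else (0, 5)

    def steady_state_prevalence(self) -> np.ndarray:
        """Equilibrium prevalent proportion i / (i + f + r) per stratum-age."""
        denom = self.incidence + self.case_fatality + self.remission
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, self.incidence / denom, 0.0)
        return p

    def equals(self, other: "DiseaseSpec") -> bool:
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class BaselineDataset:
    """All business-as-usual inputs for one model run.

    Array layout:  ``population`` is indexed ``[sex, ethnicity, age in
    2011]``; mortality/morbidity/BMI arrays are indexed by *attained* age
    so a cohort reads down its own diagonal as it ages.
    """

    base_year: int
    population: np.ndarray          # (2, 2, 111) counts by age in base year
    acm_rate: np.ndarray            # (2, 2, 111) annual death probability
    pyld_rate: np.ndarray           # (2, 2, 111) prevalent YLD per capita
    base_cost: np.ndarray           # (2, 111) NZ$ / year, sex x age
    bmi_mean: np.ndarray            # (2, 2, 111)
    bmi_sd: np.ndarray              # (2, 2, 111)
    height_mean: np.ndarray         # (2, 2) metres
    height_sd: np.ndarray           # (2, 2) metres
    overweight_prop: np.ndarray     # (2, 2, 111) P[BMI >= 25]
    diseases: dict[str, DiseaseSpec]
    standard_population: np.ndarray  # (111,) age weights for standardization

    def __eq__(self, other) -> bool:  # round-trip identity support
        if not isinstance(other, BaselineDataset):
            return NotImplemented
        if self.base_year != other.base_year:
            return False
        arrays = (
            "population acm_rate pyld_rate base_cost bmi_mean bmi_sd "
            "height_mean height_sd overweight_prop standard_population"
        ).split()
        for name in arrays:
            if not np.array_equal(getattr(self, name), getattr(other, name)):
                return False
        if set(self.diseases) != set(other.diseases):
            return False
        return all(self.diseases[n].equals(other.diseases[n]) for n in self.diseases)

    def copy(self) -> "BaselineDataset":
        return BaselineDataset(
            base_year=self.base_year,
            population=self.population.copy(),
            acm_rate=self.acm_rate.copy(),
            pyld_rate=self.pyld_rate.copy(),
            base_cost=self.base_cost.copy(),
            bmi_mean=self.bmi_mean.copy(),
            bmi_sd=self.bmi_sd.copy(),
            height_mean=self.height_mean.copy(),
            height_sd=self.height_sd.copy(),
            overweight_prop=self.overweight_prop.copy(),
            diseases={n: dataclasses.replace(
                d,
                incidence=d.incidence.copy(),
                case_fatality=d.case_fatality.copy(),
                remission=d.remission.copy(),
                dr=d.dr.copy(),
                rr_per_unit=d.rr_per_unit.copy(),
            ) for n, d in self.diseases.items()},
            standard_population=self.standard_population.copy(),
        )


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generator; defaults are the study conditions."""

    total_population: float = 4.4e6
    maori_share: float = 0.15
    male_share: float = 0.49
    # Gompertz-Makeham hazard  h(a) = A + B exp(C a), plus an infant term
    makeham_a: float = 1.0e-3
    gompertz_b: float = 2.2e-5
    gompertz_c: float = 0.102
    infant_excess: float = 4.0e-3
    female_b_multiplier: float = 0.55
    maori_hazard_multiplier: float = 1.6
    maori_morbidity_multiplier: float = 1.25
    #: ceiling on the disease share of all-cause deaths per stratum
    disease_death_share_cap: float = 0.6
    rate_noise_sd: float = 0.02

    def validate(self) -> None:
        if self.total_population <= 0:
            raise ConfigurationError("total_population must be positive")
        if not 0.0 < self.maori_share < 1.0:
            raise ConfigurationError("maori_share must lie in (0, 1)")
        if not 0.0 < self.male_share < 1.0:
            raise ConfigurationError("male_share must lie in (0, 1)")


# ---------------------------------------------------------------------------
# disease rate templates
# ---------------------------------------------------------------------------

def _log_normal_params(mean: np.ndarray, sd: np.ndarray):
    """(mu, sigma) of a log-normal from arithmetic mean and sd."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _bmi_tables():
    """Mean/sd of BMI per sex x ethnicity x age, from banded templates."""
    anchor_ages = [0, 5, 12, 18, 25, 35, 45, 55, 65, 75, 85, 110]
    mean_m = [16.5, 16.0, 18.5, 23.5, 25.8, 27.2, 27.9, 28.2, 28.0, 27.2, 26.2, 25.2]
    mean_f = [16.2, 15.8, 18.8, 23.0, 25.0, 26.4, 27.2, 27.8, 27.6, 26.9, 26.0, 25.0]
    sd_m = [1.8, 2.0, 2.8, 3.6, 4.2, 4.5, 4.7, 4.7, 4.5, 4.3, 4.1, 4.0]
    sd_f = [1.8, 2.0, 3.0, 4.2, 4.9, 5.3, 5.5, 5.5, 5.3, 5.0, 4.7, 4.5]
    mean = np.zeros((2, 2, N_AGES))
    sd = np.zeros((2, 2, N_AGES))
    for si, sex in enumerate(SEXES):
        m = _anchor_template(anchor_ages, mean_m if sex == "male" else mean_f)
        s = _anchor_template(anchor_ages, sd_m if sex == "male" else sd_f)
        for ei, eth in enumerate(ETHNICITIES):
            # higher overweight/obesity prevalence in Maori adults
            bump = 1.8 if eth == "maori" else 0.0
            adult = np.clip((AGES - 15) / 10.0, 0.0, 1.0)
            mean[si, ei] = m + bump * adult
            sd[si, ei] = s * (1.08 if eth == "maori" else 1.0)
    return mean, sd


_DISEASE_TEMPLATES = {
    # name: (group, incidence fn, case-fatality fn, dr, rr, trends, costs)
    # incidence / cf given as callables of age returning annual probabilities.
    "chd": dict(
        group="noncancer",
        inc=lambda a: 6.0e-4 * np.exp(0.055 * (a - 40.0)) * (a >= 25),
        cf=lambda a: 0.030 * np.exp(0.030 * (a - 40.0)),
        dr=0.08, rr=1.045,
        trend_inc=-0.010, trend_cf=-0.015, trend_rem=0.0,
        cost_first_year=9000.0, cost_prevalent=2200.0, cost_last6m=25000.0,
        male_factor=1.5,
    ),
    "stroke": dict(
        group="noncancer",
        inc=lambda a: 3.0e-4 * np.exp(0.060 * (a - 45.0)) * (a >= 25),
        cf=lambda a: 0.050 * np.exp(0.025 * (a - 50.0)),
        dr=0.20, rr=1.035,
        trend_inc=-0.008, trend_cf=-0.012, trend_rem=0.0,
        cost_first_year=14000.0, cost_prevalent=4200.0, cost_last6m=22000.0,
        male_factor=1.15,
    ),
    "diabetes": dict(
        group="noncancer",
        inc=lambda a: 4.5e-3 * np.exp(-(((a - 58.0) / 20.0) ** 2)) * (a >= 25),
        cf=lambda a: 0.004 * np.exp(0.035 * (a - 50.0)),
        dr=0.07, rr=1.10,
        trend_inc=0.010, trend_cf=-0.010, trend_rem=0.0,
        cost_first_year=3200.0, cost_prevalent=1900.0, cost_last6m=15000.0,
        male_factor=1.1,
    ),
    "osteoarthritis": dict(
        group="noncancer",
        inc=lambda a: 2.5e-3 * np.exp(-(((a - 64.0) / 22.0) ** 2)) * (a >= 25),
        cf=lambda a: 0.004 * np.ones_like(a, dtype=float),
        dr=0.12, rr=1.03,
        trend_inc=0.0, trend_cf=0.0, trend_rem=0.0,
        cost_first_year=6500.0, cost_prevalent=1300.0, cost_last6m=8000.0,
        male_factor=0.8,
    ),
    "endometrial_ca": dict(
        group="cancer",
        inc=lambda a: 2.2e-4 * np.exp(-(((a - 67.0) / 16.0) ** 2)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.045, dtype=float),
        dr=0.12, rr=1.09,
        trend_inc=0.002, trend_cf=-0.008, trend_rem=0.004,
        cost_first_year=26000.0, cost_prevalent=3200.0, cost_last6m=34000.0,
        male_factor=0.0,
    ),
    "kidney_ca": dict(
        group="cancer",
        inc=lambda a: 9.0e-5 * np.exp(0.045 * (a - 50.0)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.085, dtype=float),
        dr=0.14, rr=1.05,
        trend_inc=0.003, trend_cf=-0.008, trend_rem=0.004,
        cost_first_year=28000.0, cost_prevalent=3300.0, cost_last6m=36000.0,
        male_factor=1.6,
    ),
    "liver_ca": dict(
        group="cancer",
        inc=lambda a: 4.0e-5 * np.exp(0.050 * (a - 50.0)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.175, dtype=float),
        dr=0.25, rr=1.045,
        trend_inc=0.004, trend_cf=-0.006, trend_rem=0.002,
        cost_first_year=30000.0, cost_prevalent=3600.0, cost_last6m=38000.0,
        male_factor=2.0,
    ),
    "esophageal_ca": dict(
        group="cancer",
        inc=lambda a: 5.0e-5 * np.exp(0.050 * (a - 50.0)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.170, dtype=float),
        dr=0.24, rr=1.055,
        trend_inc=0.001, trend_cf=-0.006, trend_rem=0.002,
        cost_first_year=31000.0, cost_prevalent=3600.0, cost_last6m=38000.0,
        male_factor=2.2,
    ),
    "pancreatic_ca": dict(
        group="cancer",
        inc=lambda a: 8.0e-5 * np.exp(0.055 * (a - 55.0)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.190, dtype=float),
        dr=0.30, rr=1.02,
        trend_inc=0.001, trend_cf=-0.004, trend_rem=0.001,
        cost_first_year=32000.0, cost_prevalent=3800.0, cost_last6m=40000.0,
        male_factor=1.1,
    ),
    "thyroid_ca": dict(
        group="cancer",
        inc=lambda a: 1.1e-4 * np.exp(-(((a - 50.0) / 22.0) ** 2)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.015, dtype=float),
        dr=0.08, rr=1.025,
        trend_inc=0.006, trend_cf=-0.010, trend_rem=0.005,
        cost_first_year=20000.0, cost_prevalent=2600.0, cost_last6m=30000.0,
        male_factor=0.4,
    ),
    "colorectal_ca": dict(
        group="cancer",
        inc=lambda a: 3.5e-4 * np.exp(0.055 * (a - 55.0)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.080, dtype=float),
        dr=0.16, rr=1.015,
        trend_inc=-0.003, trend_cf=-0.010, trend_rem=0.005,
        cost_first_year=29000.0, cost_prevalent=3400.0, cost_last6m=36000.0,
        male_factor=1.25,
    ),
    "breast_ca": dict(
        group="cancer",
        inc=lambda a: 1.3e-3 * np.exp(-(((a - 62.0) / 22.0) ** 2)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.030, dtype=float),
        dr=0.13, rr=1.01,
        trend_inc=0.002, trend_cf=-0.012, trend_rem=0.006,
        cost_first_year=27000.0, cost_prevalent=3100.0, cost_last6m=33000.0,
        male_factor=0.0,
    ),
    "ovarian_ca": dict(
        group="cancer",
        inc=lambda a: 1.3e-4 * np.exp(-(((a - 63.0) / 18.0) ** 2)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.110, dtype=float),
        dr=0.20, rr=1.01,
        trend_inc=-0.001, trend_cf=-0.006, trend_rem=0.003,
        cost_first_year=29000.0, cost_prevalent=3500.0, cost_last6m=36000.0,
        male_factor=0.0,
    ),
    "gallbladder_ca": dict(
        group="cancer",
        inc=lambda a: 2.5e-5 * np.exp(0.050 * (a - 55.0)) * (a >= 25),
        cf=lambda a: np.full_like(a, 0.160, dtype=float),
        dr=0.24, rr=1.055,
        trend_inc=-0.002, trend_cf=-0.004, trend_rem=0.002,
        cost_first_year=28000.0, cost_prevalent=3400.0, cost_last6m=36000.0,
        male_factor=0.65,
    ),
}

#: relative-risk attenuation with age (exponent on the log scale)
_RR_AGE_ANCHORS = ([0, 25, 45, 65, 80, 95, 110], [1.0, 1.0, 0.9, 0.7, 0.55, 0.4, 0.35])


def _build_disease(name: str, rng: np.random.Generator) -> DiseaseSpec:
    t = _DISEASE_TEMPLATES[name]
    ages = AGES.astype(float)
    inc1 = np.clip(t["inc"](ages), 0.0, 0.5)
    cf1 = np.clip(t["cf"](ages), 0.0, 0.2 if t["group"] == "cancer" else 0.5)

    inc = np.zeros((2, 2, N_AGES))
    cf = np.zeros((2, 2, N_AGES))
    for si, sex in enumerate(SEXES):
        sex_f = t["male_factor"] if sex == "male" else 1.0
        for ei, eth in enumerate(ETHNICITIES):
            if eth == "maori":
                eth_inc = 1.4 if t["group"] == "noncancer" else 1.2
                eth_cf = 1.3
            else:
                eth_inc = eth_cf = 1.0
            noise = np.exp(rng.normal(0.0, 0.02, size=2))
            inc[si, ei] = inc1 * sex_f * eth_inc * noise[0]
            cf[si, ei] = cf1 * eth_cf * noise[1]
    inc = np.clip(inc, 0.0, 0.95)
    cf = np.clip(cf, 0.0, 0.95)

    if t["group"] == "cancer":
        # annual remission complements case fatality so the prevalent
        # sojourn is ~5 years (five-year relative-survival convention)
        rem = np.clip(0.2 - cf, 0.0, 1.0)
    else:
        rem = np.zeros_like(cf)

    atten = np.interp(ages, *_RR_AGE_ANCHORS)
    rr = np.exp(np.log(t["rr"]) * atten)
    rr_arr = np.broadcast_to(rr, (2, 2, N_AGES)).copy()
    if name in FEMALE_ONLY:
        rr_arr[0] = 1.0  # male rates are zero anyway

    dr_arr = np.full((2, 2, N_AGES), float(t["dr"]))

    return DiseaseSpec(
        name=name,
        group=t["group"],
        incidence=inc,
        case_fatality=cf,
        remission=rem,
        dr=dr_arr,
        rr_per_unit=rr_arr,
        trend_inc=t["trend_inc"],
        trend_cf=t["trend_cf"],
        trend_rem=t["trend_rem"],
        cost_first_year=t["cost_first_year"],
        cost_prevalent=t["cost_prevalent"],
        cost_last6m=t["cost_last6m"],
    )


def _calibrate_disease_deaths(diseases: dict[str, DiseaseSpec],
                              acm: np.ndarray, cap: float) -> None:
    """Scale case fatality so disease deaths never exceed ``cap`` x all-cause.

    Disease deaths at the steady state are sum_d f_d * i_d / (i_d + f_d + r_d),
    monotone increasing in f, so iterated proportional shrinkage converges.
    """
    for _ in range(8):
        total = np.zeros_like(acm)
        for d in diseases.values():
            total += d.case_fatality * d.steady_state_prevalence()
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(total > cap * acm, cap * acm / np.maximum(total, 1e-300), 1.0)
        if np.all(factor >= 0.999):
            return
        for d in diseases.values():
            d.case_fatality = d.case_fatality * factor
            if d.group == "cancer":
                d.remission = np.clip(0.2 - d.case_fatality, 0.0, 1.0)


def generate_baseline(config: GeneratorConfig | None = None,
                      seed: int = 0) -> BaselineDataset:
    """Generate a coherent synthetic baseline dataset.

    Identical ``(config, seed)`` pairs produce identical datasets; the
    population total, Maori share and mortality structure come from the
    config defaults unless overridden.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    # --- population pyramid ------------------------------------------------
    ages = AGES.astype(float)
    w_nm = np.exp(-np.maximum(0.0, ages - 52.0) ** 2 / 1500.0)
    w_nm *= 1.0 - 0.15 * np.exp(-(((ages - 8.0) / 10.0) ** 2))
    w_ma = np.exp(-ages / 42.0)
    population = np.zeros((2, 2, N_AGES))
    male_share_age = np.clip(config.male_share + 0.02 - 0.0008 * ages, 0.0, 1.0)
    for ei, eth in enumerate(ETHNICITIES):
        share = config.maori_share if eth == "maori" else 1.0 - config.maori_share
        w = w_ma if eth == "maori" else w_nm
        counts = config.total_population * share * w / w.sum()
        population[0, ei] = counts * male_share_age
        population[1, ei] = counts * (1.0 - male_share_age)

    # --- all-cause mortality ----------------------------------------------
    acm = np.zeros((2, 2, N_AGES))
    for si, sex in enumerate(SEXES):
        b = config.gompertz_b * (config.female_b_multiplier if sex == "female" else 1.0)
        for ei, eth in enumerate(ETHNICITIES):
            mult = config.maori_hazard_multiplier if eth == "maori" else 1.0
            hazard = (config.makeham_a
                      + config.infant_excess * np.exp(-1.5 * ages)
                      + b * np.exp(config.gompertz_c * ages)) * mult
            prob = 1.0 - np.exp(-hazard)
            prob *= np.exp(rng.normal(0.0, config.rate_noise_sd, size=N_AGES))
            # monotone above 60 (generator guarantee) and closed at 110
            prob[60:] = np.maximum.accumulate(prob[60:])
            prob = np.clip(prob, 0.0, 1.0)
            prob[MAX_AGE] = 1.0
            acm[si, ei] = prob

    # --- morbidity (prevalent YLD per capita) ------------------------------
    pyld = np.zeros((2, 2, N_AGES))
    for si, sex in enumerate(SEXES):
        base = 0.045 + 0.11 * (ages / 100.0) ** 1.7
        if sex == "female":
            base *= 0.95
        for ei, eth in enumerate(ETHNICITIES):
            mult = config.maori_morbidity_multiplier if eth == "maori" else 1.0
            noise = np.exp(rng.normal(0.0, 0.03, size=N_AGES))
            pyld[si, ei] = np.clip(base * mult * noise, 0.0, 0.8)

    # --- baseline health-system cost (sex x age) ---------------------------
    base_cost = np.zeros((2, N_AGES))
    for si, sex in enumerate(SEXES):
        c = 1700.0 + 2600.0 * np.exp(-ages / 2.0) + 9500.0 * (ages / 100.0) ** 3
        if sex == "female":
            c *= 1.05
        base_cost[si] = c * np.exp(rng.normal(0.0, 0.02, size=N_AGES))

    # --- anthropometry -----------------------------------------------------
    bmi_mean, bmi_sd = _bmi_tables()
    height_mean = np.array([[1.751, 1.770],   # male: maori, non-maori
                            [1.622, 1.642]])  # female
    height_sd = np.array([[0.071, 0.069], [0.066, 0.064]])

    mu, sigma = _log_normal_params(bmi_mean, bmi_sd)
    from scipy.special import ndtr
    overweight = 1.0 - ndtr((np.log(25.0) - mu) / sigma)

    # --- diseases ----------------------------------------------------------
    diseases = {name: _build_disease(name, rng) for name in DISEASES}
    for name in FEMALE_ONLY:
        diseases[name].incidence[0] = 0.0
    _calibrate_disease_deaths(diseases, acm, config.disease_death_share_cap)

    standard = population.sum(axis=(0, 1))
    standard = standard / standard.sum()

    return BaselineDataset(
        base_year=BASE_YEAR,
        population=population,
        acm_rate=acm,
        pyld_rate=pyld,
        base_cost=base_cost,
        bmi_mean=bmi_mean,
        bmi_sd=bmi_sd,
        height_mean=height_mean,
        height_sd=height_sd,
        overweight_prop=overweight,
        diseases=diseases,
        standard_population=standard,
    )


# ---------------------------------------------------------------------------
# coherence checking
# ---------------------------------------------------------------------------

def coherence_check(ds: BaselineDataset,
                    prevalence: dict[str, np.ndarray] | None = None,
                    tol: float = 0.25) -> list[str]:
    """Report epidemiological incoherences; empty list means coherent.

    Checks: zero remission for noncancers; all rates/proportions within
    [0, 1]; disease deaths (case fatality x steady-state prevalence, summed
    over diseases) never exceeding all-cause mortality; and, when an
    explicit ``prevalence`` mapping is supplied, its consistency with the
    incidence / case-fatality / remission steady state within relative
    tolerance ``tol``.
    """
    violations: list[str] = []

    def _rate_in_range(name, arr):
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            violations.append(f"rate out of range: {name}")

    _rate_in_range("acm_rate", ds.acm_rate)
    _rate_in_range("pyld_rate", ds.pyld_rate)
    _rate_in_range("overweight_prop", ds.overweight_prop)
    if np.any(ds.population < 0):
        violations.append("negative population count")
    if np.any(ds.base_cost < 0):
        violations.append("negative base cost")
    if np.any(ds.bmi_sd <= 0):
        violations.append("bmi sd not positive")
    if np.any(ds.height_mean < 1.4) or np.any(ds.height_mean > 2.0):
        violations.append("height mean outside [1.4, 2.0] m")

    disease_deaths = np.zeros_like(ds.acm_rate)
    for name, d in ds.diseases.items():
        for rate_name in ("incidence", "case_fatality", "remission"):
            _rate_in_range(f"{name}.{rate_name}", getattr(d, rate_name))
        if d.group == "noncancer" and np.any(d.remission != 0.0):
            violations.append(f"noncancer remission nonzero: {name}")
        p = prevalence[name] if prevalence and name in prevalence else d.steady_state_prevalence()
        disease_deaths += d.case_fatality * p
        if prevalence and name in prevalence:
            expected = d.steady_state_prevalence()
            scale = np.maximum(expected, 1e-12)
            if np.any(np.abs(prevalence[name] - expected) > tol * scale + 1e-12):
                violations.append(f"prevalence inconsistent with steady state: {name}")
    if np.any(disease_deaths > ds.acm_rate + 1e-12):
        violations.append("disease deaths exceed all-cause mortality")
    return violations


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_DISEASE_COLUMNS = [
    "age", "sex", "ethnicity", "incidence", "case_fatality", "remission",
    "dr", "cost_first_year", "cost_prevalent", "cost_last6m", "rr_per_unit",
    "trend_inc", "trend_cf", "trend_rem",
]


def _long_frame(arr: np.ndarray, value: str) -> pd.DataFrame:
    df = strata_frame()
    df[value] = arr.reshape(-1)
    return df


def _pivot_back(df: pd.DataFrame, value: str) -> np.ndarray:
    out = np.zeros((2, 2, N_AGES))
    for si, sex in enumerate(SEXES):
        for ei, eth in enumerate(ETHNICITIES):
            sub = df[(df["sex"] == sex) & (df["ethnicity"] == eth)]
            sub = sub.set_index("age").reindex(AGES)
            if sub[value].isna().any():
                raise SchemaError(f"missing rows for {sex}/{eth} in column '{value}'")
            out[si, ei] = sub[value].to_numpy()
    return out


def _check_columns(df: pd.DataFrame, expected: list[str], fname: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        raise SchemaError(f"{fname}: missing column '{missing[0]}'")
    if extra:
        raise SchemaError(f"{fname}: unexpected column '{extra[0]}'")


def write_dataset(ds: BaselineDataset, directory: str | Path) -> list[Path]:
    """Write the dataset as the documented CSV file set; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(name: str, df: pd.DataFrame):
        path = directory / name
        df.to_csv(path, index=False)
        written.append(path)

    _save("population.csv", _long_frame(ds.population, "count"))
    _save("mortality.csv", _long_frame(ds.acm_rate, "rate"))
    _save("pyld.csv", _long_frame(ds.pyld_rate, "rate"))

    bc = pd.DataFrame(
        [(sex, age, ds.base_cost[si, age])
         for si, sex in enumerate(SEXES) for age in AGES],
        columns=["sex", "age", "cost"],
    )
    _save("base_costs.csv", bc)

    bmi = _long_frame(ds.bmi_mean, "mean")
    bmi["sd"] = ds.bmi_sd.reshape(-1)
    _save("bmi.csv", bmi)

    heights = pd.DataFrame(
        [(sex, eth, ds.height_mean[si, ei], ds.height_sd[si, ei])
         for si, sex in enumerate(SEXES) for ei, eth in enumerate(ETHNICITIES)],
        columns=["sex", "ethnicity", "mean", "sd"],
    )
    _save("heights.csv", heights)

    _save("overweight.csv", _long_frame(ds.overweight_prop, "prop"))

    std = pd.DataFrame({"age": AGES, "weight": ds.standard_population})
    _save("standard_population.csv", std)

    for name, d in ds.diseases.items():
        df = strata_frame()[["age", "sex", "ethnicity"]]
        df["incidence"] = d.incidence.reshape(-1)
        df["case_fatality"] = d.case_fatality.reshape(-1)
        df["remission"] = d.remission.reshape(-1)
        df["dr"] = d.dr.reshape(-1)
        df["cost_first_year"] = d.cost_first_year
        df["cost_prevalent"] = d.cost_prevalent
        df["cost_last6m"] = d.cost_last6m
        df["rr_per_unit"] = d.rr_per_unit.reshape(-1)
        df["trend_inc"] = d.trend_inc
        df["trend_cf"] = d.trend_cf
        df["trend_rem"] = d.trend_rem
        _save(f"disease_{name}.csv", df[_DISEASE_COLUMNS])
    return written


def read_dataset(directory: str | Path) -> BaselineDataset:
    """Read a dataset written by :func:`write_dataset`; validates schemas."""
    directory = Path(directory)

    def _load(name: str, columns: list[str]) -> pd.DataFrame:
        path = directory / name
        if not path.exists():
            raise SchemaError(f"missing dataset file: {name}")
        df = pd.read_csv(path, float_precision="round_trip")
        _check_columns(df, columns, name)
        return df

    population = _pivot_back(_load("population.csv",
                                   ["sex", "ethnicity", "age", "count"]), "count")
    acm = _pivot_back(_load("mortality.csv",
                            ["sex", "ethnicity", "age", "rate"]), "rate")
    pyld = _pivot_back(_load("pyld.csv",
                             ["sex", "ethnicity", "age", "rate"]), "rate")

    bc_df = _load("base_costs.csv", ["sex", "age", "cost"])
    base_cost = np.zeros((2, N_AGES))
    for si, sex in enumerate(SEXES):
        sub = bc_df[bc_df["sex"] == sex].set_index("age").reindex(AGES)
        if sub["cost"].isna().any():
            raise SchemaError(f"base_costs.csv: missing rows for sex '{sex}'")
        base_cost[si] = sub["cost"].to_numpy()

    bmi_df = _load("bmi.csv", ["sex", "ethnicity", "age", "mean", "sd"])
    bmi_mean = _pivot_back(bmi_df, "mean")
    bmi_sd = _pivot_back(bmi_df, "sd")

    h_df = _load("heights.csv", ["sex", "ethnicity", "mean", "sd"])
    height_mean = np.zeros((2, 2))
    height_sd = np.zeros((2, 2))
    for si, sex in enumerate(SEXES):
        for ei, eth in enumerate(ETHNICITIES):
            row = h_df[(h_df["sex"] == sex) & (h_df["ethnicity"] == eth)]
            if len(row) != 1:
                raise SchemaError(f"heights.csv: expected one row for {sex}/{eth}")
            height_mean[si, ei] = row["mean"].iloc[0]
            height_sd[si, ei] = row["sd"].iloc[0]

    overweight = _pivot_back(_load("overweight.csv",
                                   ["sex", "ethnicity", "age", "prop"]), "prop")

    std_df = _load("standard_population.csv", ["age", "weight"])
    standard = std_df.set_index("age").reindex(AGES)["weight"].to_numpy()
    if np.isnan(standard).any():
        raise SchemaError("standard_population.csv: missing ages")

    diseases: dict[str, DiseaseSpec] = {}
    for name in DISEASES:
        df = _load(f"disease_{name}.csv", _DISEASE_COLUMNS)
        group = "cancer" if name in CANCERS else "noncancer"
        diseases[name] = DiseaseSpec(
            name=name,
            group=group,
            incidence=_pivot_back(df, "incidence"),
            case_fatality=_pivot_back(df, "case_fatality"),
            remission=_pivot_back(df, "remission"),
            dr=_pivot_back(df, "dr"),
            rr_per_unit=_pivot_back(df, "rr_per_unit"),
            trend_inc=float(df["trend_inc"].iloc[0]),
            trend_cf=float(df["trend_cf"].iloc[0]),
            trend_rem=float(df["trend_rem"].iloc[0]),
            cost_first_year=float(df["cost_first_year"].iloc[0]),
            cost_prevalent=float(df["cost_prevalent"].iloc[0]),
            cost_last6m=float(df["cost_last6m"].iloc[0]),
        )

    return BaselineDataset(
        base_year=BASE_YEAR,
        population=population,
        acm_rate=acm,
        pyld_rate=pyld,
        base_cost=base_cost,
        bmi_mean=bmi_mean,
        bmi_sd=bmi_sd,
        height_mean=height_mean,
        height_sd=height_sd,
        overweight_prop=overweight,
        diseases=diseases,
        standard_population=standard,
    )
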