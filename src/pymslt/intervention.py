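"""Mass-media smartphone-app promotion intervention.

Covers the uptake cascade (smartphone access -> campaign exposure -> app
download -> regular use), conversion of the trial weight-loss effect into
per-stratum BMI changes, the per-stratum population-mean BMI-change
profile after decay, and the one-off intervention cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError
from .risk import DecayModel, decay_profile
from .synthpop import BaselineDataset, ETHNICITIES, N_AGES, SEXES

#: minimum age for receiving the intervention (adults) and for the
#: BMI-disease relative risks to act, respectively
MIN_INTERVENTION_AGE = 18
MIN_RISK_AGE = 25


@dataclass(frozen=True)
class UptakeCascade:
    """Sequential uptake proportions for the promotion campaign."""

    p_smartphone: float = 0.7442
    p_exposed: float = 0.7794
    p_download: float = 0.1346
    p_regular_use: float = 0.26
    download_multiplier: float = 1.0

    def __post_init__(self):
        for name in ("p_smartphone", "p_exposed", "p_download", "p_regular_use"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.download_multiplier < 0.0:
            raise ConfigurationError("download_multiplier must be non-negative")

    @property
    def effective_download(self) -> float:
        return min(1.0, self.p_download * self.download_multiplier)


@dataclass(frozen=True)
class EffectSize:
    """Incremental weight change among regular app users, kg."""

    delta_kg: float = -0.43
    ci_95: tuple[float, float] = (-0.61, -0.25)

    def __post_init__(self):
        if self.delta_kg > 0.0:
            raise ConfigurationError("base-case effect must be a weight loss (<= 0)")


@dataclass(frozen=True)
class CostComponents:
    """One-off intervention cost components, NZ$ (2011)."""

    web_promotion: float = 72_000.0
    mass_media: float = 2_791_000.0
    app_identification: float = 20_000.0

    def __post_init__(self):
        for name in ("web_promotion", "mass_media", "app_identification"):
            if getattr(self, name) < 0.0:
                raise ConfigurationError(f"{name} must be non-negative")


class BMIEffectProfile:
    """Per-stratum, per-year population-mean BMI change from the intervention.

    ``delta[t, sex, ethnicity, age0]`` is the change in the stratum's mean
    BMI in simulation year ``t`` (year 0 = intervention year).
    """

    def __init__(self, delta: np.ndarray):
        self.delta = delta

    @property
    def horizon(self) -> int:
        return self.delta.shape[0]


def uptake_fraction(c: UptakeCascade) -> float:
    """Proportion of overweight/obese adults receiving the effective
    intervention: the product of the four cascade stages (download stage
    scaled by the scenario multiplier, capped at 1)."""
    return c.p_smartphone * c.p_exposed * c.effective_download * c.p_regular_use


def kg_to_bmi(delta_kg: float, height_m: float) -> float:
    """Convert a weight change to BMI units using a mean height."""
    if height_m <= 0.0:
        raise DomainError("height must be positive")
    return delta_kg / height_m ** 2


def intervention_cost(cc: CostComponents) -> float:
    """Total one-off intervention cost (exact sum of the components)."""
    return cc.web_promotion + cc.mass_media + cc.app_identification


def effect_profile(ds: BaselineDataset, c: UptakeCascade, e: EffectSize,
                   decay: DecayModel, horizon: int = N_AGES) -> BMIEffectProfile:
    """Build the per-stratum population-mean BMI-change series.

    Each stratum's series is ``uptake x overweight_prop x decayed BMI
    change`` where the BMI change uses the stratum's mean height; strata
    younger than 18 at the intervention year are untouched (the campaign
    targets adults).  The relative-risk age floor (25 years) is applied
    downstream by the life-table engine, not here.
    """
    if horizon < 1:
        raise ConfigurationError("horizon must be at least 1 year")
    uptake = uptake_fraction(c)
    delta = np.zeros((horizon, 2, 2, N_AGES))
    for si in range(len(SEXES)):
        for ei in range(len(ETHNICITIES)):
            d0 = kg_to_bmi(e.delta_kg, ds.height_mean[si, ei])
            series = decay_profile(d0, decay, horizon)  # (horizon,)
            ow = ds.overweight_prop[si, ei].copy()
            ow[:MIN_INTERVENTION_AGE] = 0.0
            delta[:, si, ei, :] = uptake * series[:, None] * ow[None, :]
    return BMIEffectProfile(delta)


def population_reach(ds: BaselineDataset, c: UptakeCascade,
                     min_age: int = MIN_INTERVENTION_AGE) -> float:
    """Population-weighted proportion of adults effectively intervened on
    (uptake x overweight proportion averaged over the adult population)."""
    uptake = uptake_fraction(c)
    pop = ds.population[:, :, min_age:]
    ow = ds.overweight_prop[:, :, min_age:]
    return float(uptake * (pop * ow).sum() / pop.sum())


# ---------------------------------------------------------------------------
# packaged configuration (central values and uncertainty bounds)
# ---------------------------------------------------------------------------

def load_intervention_config() -> dict:
    """Load the packaged intervention parameter file (central values,
    uncertainty bounds, cost components, PPP factor)."""
    text = resources.files("pymslt.data").joinpath("intervention.yaml").read_text()
    return yaml.safe_load(text)


def defaults_from_config(cfg: dict | None = None):
    """(UptakeCascade, EffectSize, DecayModel, CostComponents) at central values."""
    cfg = cfg or load_intervention_config()
    up = cfg["uptake"]
    cascade = UptakeCascade(
        p_smartphone=up["p_smartphone"],
        p_exposed=up["p_exposed"],
        p_download=up["p_download"],
        p_regular_use=up["p_regular_use"],
    )
    effect = EffectSize(delta_kg=cfg["effect"]["delta_kg"],
                        ci_95=tuple(cfg["effect"]["ci_95"]))
    decay = DecayModel(rate=cfg["decay"]["rate_per_month"])
    costs = CostComponents(
        web_promotion=cfg["costs"]["web_promotion"],
        mass_media=cfg["costs"]["mass_media"],
        app_identification=cfg["costs"]["app_identification"],
    )
    return cascade, effect, decay, costs
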