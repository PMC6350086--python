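"""Scenario wiring: intervention -> risk -> life table -> economics."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import econ, engine, intervention as iv
from .errors import ConfigurationError
from .risk import DecayModel, LagWindow
from .synthpop import BaselineDataset


@dataclass(frozen=True)
class Scenario:
    """One cell of the scenario grid."""

    download_multiplier: float = 1.0
    discount_rate: float = 0.03
    decay_enabled: bool = True
    equity_swap: bool = False
    name: str = "base"

    def __post_init__(self):
        if self.download_multiplier <= 0:
            raise ConfigurationError("download_multiplier must be positive")
        if self.discount_rate < 0:
            raise ConfigurationError("discount rate must be non-negative")


@dataclass
class ModelInputs:
    """Everything a single model evaluation needs besides the scenario.

    The PSA perturbs a copy of this bundle per draw; the defaults are the
    packaged central values.
    """

    ds: BaselineDataset
    cascade: iv.UptakeCascade = field(default_factory=iv.UptakeCascade)
    effect: iv.EffectSize = field(default_factory=iv.EffectSize)
    decay: DecayModel = field(default_factory=DecayModel)
    costs: iv.CostComponents = field(default_factory=iv.CostComponents)
    tmrel: float = 21.0
    lag_noncancer: LagWindow = engine.LAG_NONCANCER
    lag_cancer: LagWindow = engine.LAG_CANCER
    intervention_cost_override: float | None = None

    @property
    def intervention_cost(self) -> float:
        if self.intervention_cost_override is not None:
            return self.intervention_cost_override
        return iv.intervention_cost(self.costs)


def run_scenario(inputs: ModelInputs, scenario: Scenario) -> econ.ScenarioResult:
    """Evaluate one scenario at the given inputs (no uncertainty)."""
    ds = engine.equity_swap(inputs.ds) if scenario.equity_swap else inputs.ds
    cascade = replace(inputs.cascade,
                      download_multiplier=scenario.download_multiplier)
    decay = replace(inputs.decay, enabled=scenario.decay_enabled)
    profile = iv.effect_profile(ds, cascade, inputs.effect, decay,
                                horizon=engine.N_YEARS)
    run = engine.run_mslt(ds, profile, tmrel=inputs.tmrel,
                          lag_noncancer=inputs.lag_noncancer,
                          lag_cancer=inputs.lag_cancer)
    return econ.summarize(run, ds, discount_rate=scenario.discount_rate,
                          intervention_cost_total=inputs.intervention_cost)


def scenario_grid(download_multipliers=(1.0, 1.5, 2.0),
                  discount_rates=(0.0, 0.03, 0.06)) -> list[Scenario]:
    """The reporting grid: download multipliers x discount rates, plus the
    permanent-weight-loss and equity counterfactuals at base settings."""
    grid = [
        Scenario(download_multiplier=m, discount_rate=r,
                 name=f"dl{m:g}_disc{int(round(r * 100))}")
        for m in download_multipliers for r in discount_rates
    ]
    grid.append(Scenario(decay_enabled=False, name="no_decay"))
    grid.append(Scenario(equity_swap=True, name="equity"))
    return grid
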