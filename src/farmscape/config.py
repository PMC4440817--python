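"""Configuration: behavioural parameters, market assumptions, scenario grid.

Everything the simulation can be told is collected here as plain
dataclasses with the model's default parametrisation, loadable from a
single YAML file.  Defaults follow the study design the package
implements: 10 five-year steps, 2 %/yr real commodity price growth, a
75 % succession success rate, base conversion likelihood 0.2,
endorsement/imitation adjustments of ±0.1/±0.05, a 5-step (25-year)
forestry lock-in, a 75 % penalty on proposed Dairy conversions, and a
scenario grid of carbon prices $0-$60/tCO2e crossed with a
network-effects toggle over 50 seeds (700 runs).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml


@dataclass
class BehaviourConfig:
    """Decision-rule parameters for farmer agents."""

    #: base likelihood of land-use conversion, reset after every decision
    initial_likelihood: float = 0.2
    #: endorsement adjustment from the social network (±)
    endorsement_delta: float = 0.1
    #: imitation adjustment from the geographic network (±)
    imitation_delta: float = 0.05
    #: size of the social network (closest same-enterprise farmers)
    k_social: int = 10
    #: proposed-Dairy conversions keep this fraction of their likelihood
    #: (a 75 % reduction: up-front conversion cost and lifestyle change)
    dairy_penalty: float = 0.75
    #: steps a new forest is locked in (25 years at 5 yr/step)
    forest_lock_steps: int = 5
    network_effects_enabled: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.initial_likelihood <= 1.0:
            raise ValueError("initial_likelihood must be in [0, 1]")
        if not 0.0 <= self.dairy_penalty <= 1.0:
            raise ValueError("dairy_penalty must be in [0, 1]")
        if self.k_social < 1:
            raise ValueError("k_social must be >= 1")
        if self.forest_lock_steps < 0:
            raise ValueError("forest_lock_steps must be >= 0")


@dataclass
class DemographyConfig:
    """Generational life-cycle parameters."""

    #: probability a successor is found at the Stage-1 assessment
    succession_rate: float = 0.75
    #: model steps spent in each of the five life-cycle stages
    steps_per_stage: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.succession_rate <= 1.0:
            raise ValueError("succession_rate must be in [0, 1]")
        if self.steps_per_stage < 1:
            raise ValueError("steps_per_stage must be >= 1")


@dataclass
class MarketConfig:
    """Commodity and carbon price assumptions."""

    #: real annual growth of farm commodity prices (milk, meat, timber)
    annual_price_growth: float = 0.02
    years_per_step: int = 5
    #: carbon price in NZD/tCO2e, constant over the horizon
    ghg_price: float = 0.0

    def validate(self) -> None:
        if self.years_per_step < 1:
            raise ValueError("years_per_step must be >= 1")
        if self.ghg_price < 0:
            raise ValueError("ghg_price must be >= 0")


@dataclass
class GeneratorConfig:
    """Synthetic-catchment generator settings.

    The default catchment is a 50 x 80 grid of 25-ha cells (100,000 ha)
    split into Plains/Foothills/Hills bands, partitioned into farms with
    a log-normal size distribution (mean ~10 cells = 250 ha, truncated
    at 4 cells), with initial land use dominated by Sheep & Beef plus
    minor Dairy on the Plains and Forestry in the Hills.
    """

    n_rows: int = 50
    n_cols: int = 80
    cell_size_ha: float = 25.0
    zone_band_fractions: dict[str, float] = field(
        default_factory=lambda: {"Plains": 0.3, "Foothills": 0.3, "Hills": 0.4}
    )
    initial_shares: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Plains": {"Dairy": 0.15, "SheepBeef": 0.80, "Forestry": 0.05},
            "Foothills": {"Dairy": 0.05, "SheepBeef": 0.90, "Forestry": 0.05},
            "Hills": {"SheepBeef": 0.85, "Forestry": 0.15},
        }
    )
    #: log-normal parcel-size distribution, in cells
    mean_cells: float = 10.0
    sigma_cells: float = 0.6
    #: smallest parcel the region-growing will emit (4 cells = 100 ha)
    min_cells: int = 4

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.min_cells < 4:
            raise ValueError("min_cells below 4 would create sub-100-ha farms")
        band_total = sum(self.zone_band_fractions.values())
        if abs(band_total - 1.0) > 1e-9:
            raise ValueError(f"zone band fractions must sum to 1, got {band_total}")
        for zone, shares in self.initial_shares.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{zone} initial shares must sum to 1, got {total}")
            if any(s < 0 for s in shares.values()):
                raise ValueError(f"{zone} initial shares must be non-negative")


@dataclass
class LandscapeConfig:
    """Where the landscape comes from: a file, or the generator."""

    source: str | None = None
    min_area_ha: float = 100.0
    #: seed for synthetic-landscape generation.  The catchment is part of
    #: the study setup, so by default it is fixed across an ensemble and
    #: run seeds only vary initial stages, decisions and demography; set
    #: to None to derive the landscape from the run seed instead.
    landscape_seed: int | None = 101
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if self.min_area_ha <= 0:
            raise ValueError("min_area_ha must be positive")
        self.generator.validate()


@dataclass
class ModelConfig:
    """Full configuration for a single simulation run."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    behaviour: BehaviourConfig = field(default_factory=BehaviourConfig)
    demography: DemographyConfig = field(default_factory=DemographyConfig)
    market: MarketConfig = field(default_factory=MarketConfig)
    #: CSV path of enterprise x zone coefficients; None uses the defaults
    coefficients: str | None = None
    n_steps: int = 10

    def validate(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        self.landscape.validate()
        self.behaviour.validate()
        self.demography.validate()
        self.market.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class ScenarioGrid:
    """The experiment design: carbon prices x network toggle x seeds."""

    ghg_prices: list[float] = field(
        default_factory=lambda: [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
    )
    network_effects: list[bool] = field(default_factory=lambda: [True, False])
    seeds: list[int] = field(default_factory=lambda: list(range(1, 51)))
    model: ModelConfig = field(default_factory=ModelConfig)

    @property
    def n_runs(self) -> int:
        return len(self.ghg_prices) * len(self.network_effects) * len(self.seeds)

    def validate(self) -> None:
        if not self.ghg_prices or not self.network_effects or not self.seeds:
            raise ValueError("scenario grid has an empty axis")
        if any(p < 0 for p in self.ghg_prices):
            raise ValueError("ghg_prices must be >= 0")
        self.model.validate()


# ---------------------------------------------------------------------------
# Default enterprise x zone coefficient table
# ---------------------------------------------------------------------------

#: Default per-hectare enterprise budgets and environmental coefficients.
#:
#: Magnitudes are an uncalibrated but qualitatively ordered stand-in for
#: catchment-specific farm budgets: Dairy is the most profitable use on
#: Plains and Foothills but infeasible in the Hills; Forestry out-earns
#: Sheep & Beef in the Hills; Carbon Forestry has no commodity revenue
#: and only pays through the carbon price.  Livestock carry gross GHG
#: emissions and the higher nutrient losses; forests sequester
#: (plantation forestry is carbon-neutral under the price: it neither
#: pays nor is paid).
DEFAULT_COEFFICIENTS: list[dict[str, Any]] = [
    # enterprise, zone, revenue, cost, emissions, sequestration, N, P, feasible
    dict(enterprise="Dairy", zone="Plains", revenue_per_ha=5800.0, cost_per_ha=3400.0,
         emissions_per_ha=9.0, sequestration_per_ha=0.0, n_leach_per_ha=42.0,
         p_loss_per_ha=1.3, feasible=True),
    dict(enterprise="Dairy", zone="Foothills", revenue_per_ha=4600.0, cost_per_ha=3000.0,
         emissions_per_ha=7.5, sequestration_per_ha=0.0, n_leach_per_ha=32.0,
         p_loss_per_ha=1.0, feasible=True),
    dict(enterprise="Dairy", zone="Hills", revenue_per_ha=0.0, cost_per_ha=0.0,
         emissions_per_ha=0.0, sequestration_per_ha=0.0, n_leach_per_ha=0.0,
         p_loss_per_ha=0.0, feasible=False),
    dict(enterprise="SheepBeef", zone="Plains", revenue_per_ha=1450.0, cost_per_ha=950.0,
         emissions_per_ha=3.6, sequestration_per_ha=0.0, n_leach_per_ha=14.0,
         p_loss_per_ha=0.6, feasible=True),
    dict(enterprise="SheepBeef", zone="Foothills", revenue_per_ha=1200.0, cost_per_ha=820.0,
         emissions_per_ha=3.0, sequestration_per_ha=0.0, n_leach_per_ha=11.0,
         p_loss_per_ha=0.5, feasible=True),
    dict(enterprise="SheepBeef", zone="Hills", revenue_per_ha=700.0, cost_per_ha=560.0,
         emissions_per_ha=2.2, sequestration_per_ha=0.0, n_leach_per_ha=8.0,
         p_loss_per_ha=0.4, feasible=True),
    dict(enterprise="Forestry", zone="Plains", revenue_per_ha=1350.0, cost_per_ha=900.0,
         emissions_per_ha=0.0, sequestration_per_ha=0.0, n_leach_per_ha=3.0,
         p_loss_per_ha=0.1, feasible=True),
    dict(enterprise="Forestry", zone="Foothills", revenue_per_ha=1150.0, cost_per_ha=820.0,
         emissions_per_ha=0.0, sequestration_per_ha=0.0, n_leach_per_ha=2.5,
         p_loss_per_ha=0.1, feasible=True),
    dict(enterprise="Forestry", zone="Hills", revenue_per_ha=760.0, cost_per_ha=580.0,
         emissions_per_ha=0.0, sequestration_per_ha=0.0, n_leach_per_ha=2.0,
         p_loss_per_ha=0.1, feasible=True),
    dict(enterprise="CarbonForestry", zone="Plains", revenue_per_ha=0.0, cost_per_ha=150.0,
         emissions_per_ha=0.0, sequestration_per_ha=8.0, n_leach_per_ha=2.0,
         p_loss_per_ha=0.1, feasible=True),
    dict(enterprise="CarbonForestry", zone="Foothills", revenue_per_ha=0.0, cost_per_ha=140.0,
         emissions_per_ha=0.0, sequestration_per_ha=7.0, n_leach_per_ha=2.0,
         p_loss_per_ha=0.1, feasible=True),
    dict(enterprise="CarbonForestry", zone="Hills", revenue_per_ha=0.0, cost_per_ha=100.0,
         emissions_per_ha=0.0, sequestration_per_ha=8.0, n_leach_per_ha=2.0,
         p_loss_per_ha=0.1, feasible=True),
]


def default_coefficient_frame() -> pd.DataFrame:
    return pd.DataFrame(DEFAULT_COEFFICIENTS)


# ---------------------------------------------------------------------------
# YAML (de)serialisation
# ---------------------------------------------------------------------------


_NESTED = {
    "landscape": LandscapeConfig,
    "behaviour": BehaviourConfig,
    "demography": DemographyConfig,
    "market": MarketConfig,
    "generator": GeneratorConfig,
    "model": ModelConfig,
}


def _from_dict(cls, data: dict[str, Any] | None):
    if data is None:
        return cls()
    kwargs: dict[str, Any] = {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _from_dict(_NESTED[key], value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_model_config(path: str | Path) -> ModelConfig:
    """Read a ModelConfig from a YAML file and validate it."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(ModelConfig, data)
    cfg.validate()
    return cfg


def load_scenario_grid(path: str | Path) -> ScenarioGrid:
    """Read a ScenarioGrid (with nested model config) from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    grid = _from_dict(ScenarioGrid, data)
    grid.validate()
    return grid
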