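"""Farmer demography: the five-stage generational life-cycle.

Farmers move through five life-cycle stages (entry, consolidation,
maturity, wind-down, exit).  Entering Stage 1 triggers a succession
assessment — a successor is found with probability ``succession_rate``
(default 0.75).  A farmer who completes Stage 5 with a successor hands
the farm over and the cycle restarts at Stage 1; without one, the farm
is sold at the end of the step and a new operator (a fresh agent)
takes over, immediately reconsidering the land use once at the base
conversion likelihood.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .landscape import Landscape, Parcel


class FarmerIdFactory:
    """Per-run counter so farmer ids are unique yet reproducible."""

    def __init__(self) -> None:
        self._next = 0

    def __call__(self) -> str:
        fid = f"f{self._next:06d}"
        self._next += 1
        return fid


@dataclass
class Farmer:
    """Decision-maker operating exactly one farm."""

    farmer_id: str
    farm_id: str
    life_stage: int = 1
    steps_in_stage: int = 0
    has_successor: bool = False
    #: conversion likelihood; reset to the base value after every decision
    likelihood: float = 0.2
    #: realised net revenue per hectare from the previous step (NZD/ha/yr)
    profitability_per_ha: float = 0.0
    #: realised net revenue from the previous step (NZD/yr)
    net_revenue: float = 0.0
    flagged_for_sale: bool = False
    #: Stage-1 succession assessment still owed (new operators)
    pending_succession_draw: bool = False

    def __post_init__(self) -> None:
        if self.life_stage not in range(1, 6):
            raise ValueError(f"life_stage must be in 1..5, got {self.life_stage}")
        if not 0.0 <= self.likelihood <= 1.0:
            raise ValueError("likelihood must be in [0, 1]")


def advance_life_cycle(
    farmer: Farmer,
    rng: np.random.Generator,
    succession_rate: float,
    steps_per_stage: int = 1,
) -> Farmer:
    """Advance one farmer's stage clock by one model step (in place).

    A pending Stage-1 assessment (new operators) is resolved first.
    Completing a stage moves to the next; completing Stage 5 either
    resets to Stage 1 (successor takes over, triggering a fresh
    succession draw) or flags the farm for sale.
    """
    if not 0.0 <= succession_rate <= 1.0:
        raise ValueError("succession_rate must be in [0, 1]")
    if farmer.pending_succession_draw:
        farmer.has_successor = bool(rng.random() < succession_rate)
        farmer.pending_succession_draw = False
    farmer.steps_in_stage += 1
    if farmer.steps_in_stage < steps_per_stage:
        return farmer
    if farmer.life_stage < 5:
        farmer.life_stage += 1
        farmer.steps_in_stage = 0
    elif farmer.has_successor:
        # takeover: the groomed successor restarts the cycle on the same farm
        farmer.life_stage = 1
        farmer.steps_in_stage = 0
        farmer.has_successor = bool(rng.random() < succession_rate)
    else:
        farmer.flagged_for_sale = True
    return farmer


def make_initial_population(
    landscape: Landscape,
    rng: np.random.Generator,
    succession_rate: float,
    initial_likelihood: float,
    id_factory: FarmerIdFactory | None = None,
) -> dict[str, Farmer]:
    """Create one farmer per parcel with uniform initial life stages.

    Stages are drawn uniformly over 1..5 (avoiding synchronised sale
    waves) and every farmer receives an initial succession draw.
    Returns a dict keyed by farm (parcel) id; parcel ``owner_id`` fields
    are set.
    """
    new_id = id_factory or FarmerIdFactory()
    population: dict[str, Farmer] = {}
    for parcel in landscape.parcels:
        farmer = Farmer(
            farmer_id=new_id(),
            farm_id=parcel.parcel_id,
            life_stage=int(rng.integers(1, 6)),
            has_successor=bool(rng.random() < succession_rate),
            likelihood=initial_likelihood,
        )
        parcel.owner_id = farmer.farmer_id
        population[parcel.parcel_id] = farmer
    return population


def resolve_sales(
    population: dict[str, Farmer],
    landscape: Landscape,
    rng: np.random.Generator,
    config,
    new_owner_decision: Callable[[Farmer, Parcel, np.random.Generator], None] | None = None,
    id_factory: FarmerIdFactory | None = None,
) -> dict[str, Farmer]:
    """Sell every flagged farm to a fresh operator (in place).

    Runs after all conversion decisions, concluding the step.  The sale
    itself leaves the enterprise unchanged, but the new owner — created
    at Stage 1 with base likelihood and the farm's current realised
    profitability, their succession assessment owed at their first
    life-cycle advance — immediately reconsiders the land use once via
    ``new_owner_decision`` (the engine supplies an evaluation at base
    likelihood with constraints applied and network effects omitted).
    """
    new_id = id_factory or FarmerIdFactory()
    for parcel in landscape.parcels:
        old = population[parcel.parcel_id]
        if not old.flagged_for_sale:
            continue
        buyer = Farmer(
            farmer_id=new_id(),
            farm_id=parcel.parcel_id,
            life_stage=1,
            has_successor=False,
            pending_succession_draw=True,
            likelihood=config.behaviour.initial_likelihood,
            profitability_per_ha=old.profitability_per_ha,
            net_revenue=old.net_revenue,
        )
        population[parcel.parcel_id] = buyer
        parcel.owner_id = buyer.farmer_id
        if new_owner_decision is not None:
            new_owner_decision(buyer, parcel, rng)
    return population
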