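"""Simulation engine: the per-step loop tying all components together.

Each 5-year step runs ordered phases:

1. market update — commodity price index and carbon price;
2. forestry lock-in counters tick down;
3. every farmer, in a fresh seeded random order, receives the
   revenue-maximising proposal for their farm; a proposal differing
   from the current enterprise triggers a stochastic conversion
   decision: base likelihood 0.2, adjusted by endorsement (±0.1) and
   imitation (±0.05) when network effects are on, then constrained
   (forest lock forces 0; proposed Dairy is cut by 75 %), clamped to
   [0, 1] and compared against a uniform draw.  New forests are locked
   for 5 steps.  Network comparisons read enterprises and
   profitabilities as of the start of the step (synchronous read,
   asynchronous write);
4. demography — life-cycle advance, then successor-less exiting
   farmers sell: the new owner re-evaluates once at base likelihood
   with constraints but without network input;
5. the ledger records areas by enterprise and zone, net revenue,
   gross/net GHG, sequestration, N leaching, P loss and all decisions.

Runs are reproducible: a run is a pure function of (config, seed), with
separate named substreams for landscape generation, initialisation,
decisions and demography.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import ModelConfig
from .demography import (
    Farmer,
    FarmerIdFactory,
    advance_life_cycle,
    make_initial_population,
    resolve_sales,
)
from .economics import (
    CoefficientTable,
    MarketState,
    _argmax_with_ties,
    environmental_outputs,
    optimize_farm,
    price_index,
)
from .landscape import (
    ENTERPRISE_ORDER,
    FOREST_ENTERPRISES,
    ZONE_ORDER,
    Enterprise,
    Landscape,
    Parcel,
    build_adjacency,
    filter_parcels,
    generate_synthetic_landscape,
    load_landscape,
)

_ENT_CODE = {e: i for i, e in enumerate(ENTERPRISE_ORDER)}
_ZONE_CODE = {z: i for i, z in enumerate(ZONE_ORDER)}


@dataclass(frozen=True)
class DecisionRecord:
    """One stochastic conversion evaluation."""

    farmer_id: str
    step: int
    current: Enterprise
    proposed: Enterprise
    likelihood_final: float
    uniform_draw: float | None
    converted: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.likelihood_final <= 1.0:
            raise ValueError("likelihood_final must be in [0, 1]")
        if self.uniform_draw is not None and self.converted != (
            self.uniform_draw < self.likelihood_final
        ):
            raise ValueError("converted must equal (draw < likelihood_final)")


def apply_constraints(
    likelihood: float,
    current: Enterprise,
    proposed: Enterprise,
    forest_lock_steps: int,
    dairy_penalty: float = 0.75,
) -> float:
    """Apply the two enterprise-level behavioural constraints.

    A forest inside its lock-in window cannot convert (likelihood 0);
    a proposed conversion to Dairy keeps only ``1 - dairy_penalty`` of
    its likelihood (up-front capital and lifestyle costs).  The result
    is clamped to [0, 1].
    """
    if current in FOREST_ENTERPRISES and forest_lock_steps > 0:
        return 0.0
    if proposed is Enterprise.DAIRY:
        likelihood = likelihood * (1.0 - dairy_penalty)
    return float(min(1.0, max(0.0, likelihood)))


def evaluate_decision(
    farmer: Farmer,
    parcel: Parcel,
    market: MarketState,
    coeffs: CoefficientTable,
    networks_enabled: bool,
    rng: np.random.Generator,
    *,
    endorsement_delta: float = 0.0,
    imitation_delta: float = 0.0,
    initial_likelihood: float = 0.2,
    dairy_penalty: float = 0.75,
    forest_lock_steps: int = 5,
    proposal: tuple[Enterprise, dict[Enterprise, float]] | None = None,
) -> DecisionRecord:
    """Run one farmer's land-use decision (mutating farmer and parcel).

    When the proposal matches the current enterprise no random draw is
    consumed — the farmer just books the updated net revenue.
    Otherwise likelihood = base + endorsement + imitation (deltas are
    ignored when networks are disabled), constraints apply, and a
    uniform draw decides.  A conversion into a forest enterprise starts
    the lock-in; the likelihood is reset to base afterwards either way.
    """
    proposed, nr_map = proposal if proposal is not None else optimize_farm(
        parcel, market, coeffs
    )
    current = parcel.enterprise
    if proposed == current:
        farmer.net_revenue = nr_map[current]
        farmer.profitability_per_ha = nr_map[current] / parcel.area_ha
        farmer.likelihood = initial_likelihood
        return DecisionRecord(
            farmer_id=farmer.farmer_id,
            step=market.step,
            current=current,
            proposed=proposed,
            likelihood_final=0.0,
            uniform_draw=None,
            converted=False,
        )
    likelihood = initial_likelihood
    if networks_enabled:
        likelihood += endorsement_delta + imitation_delta
    likelihood = apply_constraints(
        likelihood, current, proposed, parcel.forest_lock_steps, dairy_penalty
    )
    draw = float(rng.random())
    converted = draw < likelihood
    if converted:
        parcel.enterprise = proposed
        parcel.forest_lock_steps = (
            forest_lock_steps if proposed in FOREST_ENTERPRISES else 0
        )
    operated = parcel.enterprise
    farmer.net_revenue = nr_map[operated]
    farmer.profitability_per_ha = nr_map[operated] / parcel.area_ha
    farmer.likelihood = initial_likelihood
    return DecisionRecord(
        farmer_id=farmer.farmer_id,
        step=market.step,
        current=current,
        proposed=proposed,
        likelihood_final=likelihood,
        uniform_draw=draw,
        converted=converted,
    )


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------


class SimulationState:
    """Mutable state of one run plus cached spatial arrays."""

    def __init__(
        self,
        config: ModelConfig,
        landscape: Landscape,
        population: dict[str, Farmer],
        coeffs: CoefficientTable,
        rng_decisions: np.random.Generator,
        rng_demography: np.random.Generator,
        id_factory: FarmerIdFactory,
    ):
        self.config = config
        self.landscape = landscape
        self.population = population
        self.coeffs = coeffs
        self.rng_decisions = rng_decisions
        self.rng_demography = rng_demography
        self.id_factory = id_factory
        self.step_index = 0
        self.market = MarketState(
            step=0, price_index=1.0, ghg_price=self._ghg_price_at(0)
        )
        self.index_of = {p.parcel_id: i for i, p in enumerate(landscape.parcels)}

        parcels = landscape.parcels  # sorted by id
        self.n = len(parcels)
        self.areas = np.array([p.area_ha for p in parcels])
        self.zone_codes = np.array([_ZONE_CODE[p.zone] for p in parcels])
        self.ent_codes = np.array(
            [_ENT_CODE[p.enterprise] for p in parcels], dtype=np.int8
        )
        coords = np.array([p.centroid for p in parcels])
        self.dist = cdist(coords, coords)
        self.adj_idx = [
            np.array(
                sorted(self.index_of[q] for q in landscape.neighbours(p.parcel_id)),
                dtype=np.int64,
            )
            for p in parcels
        ]
        # realised profitability of the previous step, index-aligned
        self.profit = np.zeros(self.n)
        self.ledger_rows: list[dict[str, Any]] = []
        self.decision_rows: list[DecisionRecord] = []
        self.enterprise_path: list[np.ndarray] = []
        self.n_sales_this_step = 0

    # -- helpers ----------------------------------------------------------
    def _ghg_price_at(self, step: int) -> float:
        """Carbon price schedule hook; the default is a constant price."""
        sched = self.config.market.ghg_price
        if isinstance(sched, (list, tuple)):
            return float(sched[min(step, len(sched) - 1)])
        return float(sched)

    def _net_revenue_rows(self) -> np.ndarray:
        """(n, n_enterprises) expected NZD/yr per farm; -inf infeasible."""
        per_ha = self.coeffs.net_revenue_per_ha(self.market)  # (E, Z)
        return self.areas[:, None] * per_ha[:, self.zone_codes].T

    def _refresh_realised(self) -> None:
        """Book realised net revenue for the enterprise each farm runs."""
        nr = self._net_revenue_rows()
        realised = nr[np.arange(self.n), self.ent_codes]
        self.profit = realised / self.areas
        for i, parcel in enumerate(self.landscape.parcels):
            farmer = self.population[parcel.parcel_id]
            farmer.net_revenue = float(realised[i])
            farmer.profitability_per_ha = float(self.profit[i])

    def record_ledger(self) -> None:
        step = self.step_index
        area_by = np.zeros((len(ZONE_ORDER), len(ENTERPRISE_ORDER)))
        np.add.at(area_by, (self.zone_codes, self.ent_codes), self.areas)
        nr = self._net_revenue_rows()
        realised = nr[np.arange(self.n), self.ent_codes]
        rows = self.ledger_rows
        rows.append(
            dict(step=step, variable="price_index", enterprise="", zone="",
                 value=self.market.price_index)
        )
        rows.append(
            dict(step=step, variable="ghg_price", enterprise="", zone="",
                 value=self.market.ghg_price)
        )
        for zi, zone in enumerate(ZONE_ORDER):
            for ei, ent in enumerate(ENTERPRISE_ORDER):
                rows.append(
                    dict(step=step, variable="area_ha", enterprise=ent.value,
                         zone=zone.value, value=float(area_by[zi, ei]))
                )
        for ei, ent in enumerate(ENTERPRISE_ORDER):
            rows.append(
                dict(step=step, variable="net_revenue", enterprise=ent.value,
                     zone="", value=float(realised[self.ent_codes == ei].sum()))
            )
        env = environmental_outputs(self.landscape, self.coeffs)
        for name in ("gross_ghg", "sequestration", "net_ghg", "n_leach", "p_loss"):
            rows.append(
                dict(step=step, variable=name, enterprise="", zone="", value=env[name])
            )
        converted = sum(
            1 for d in self.decision_rows if d.step == step and d.converted
        )
        rows.append(
            dict(step=step, variable="n_conversions", enterprise="", zone="",
                 value=float(converted))
        )
        rows.append(
            dict(step=step, variable="n_sales", enterprise="", zone="",
                 value=float(self.n_sales_this_step))
        )
        self.enterprise_path.append(self.ent_codes.copy())


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one 5-year step (in place)."""
    cfg = state.config
    beh = cfg.behaviour
    state.step_index += 1
    t = state.step_index

    # 1. market update
    state.market = MarketState(
        step=t,
        price_index=price_index(
            t, cfg.market.annual_price_growth, cfg.market.years_per_step
        ),
        ghg_price=state._ghg_price_at(t),
    )

    # 2. forest locks tick down
    for parcel in state.landscape.parcels:
        if parcel.forest_lock_steps > 0:
            parcel.forest_lock_steps -= 1

    # 3. decisions, seeded random order, synchronous network reads
    ent_prev = state.ent_codes.copy()
    profit_prev = state.profit.copy()
    nr_rows = state._net_revenue_rows()
    parcels = state.landscape.parcels
    order = state.rng_decisions.permutation(state.n)
    for i in order:
        parcel = parcels[i]
        farmer = state.population[parcel.parcel_id]
        nr_row = nr_rows[i]
        proposed = _argmax_with_ties(nr_row, parcel.enterprise)
        nr_map = {
            e: float(nr_row[ci])
            for ci, e in enumerate(ENTERPRISE_ORDER)
            if np.isfinite(nr_row[ci])
        }
        if proposed == parcel.enterprise:
            evaluate_decision(
                farmer, parcel, state.market, state.coeffs, False,
                state.rng_decisions,
                initial_likelihood=beh.initial_likelihood,
                proposal=(proposed, nr_map),
            )
            continue
        e_delta = i_delta = 0.0
        if beh.network_effects_enabled:
            e_delta = _endorsement_delta_fast(state, i, ent_prev, profit_prev)
            i_delta = _imitation_delta_fast(
                state, i, _ENT_CODE[proposed], ent_prev, profit_prev
            )
        record = evaluate_decision(
            farmer, parcel, state.market, state.coeffs,
            beh.network_effects_enabled, state.rng_decisions,
            endorsement_delta=e_delta,
            imitation_delta=i_delta,
            initial_likelihood=beh.initial_likelihood,
            dairy_penalty=beh.dairy_penalty,
            forest_lock_steps=beh.forest_lock_steps,
            proposal=(proposed, nr_map),
        )
        state.decision_rows.append(record)
        if record.converted:
            state.ent_codes[i] = _ENT_CODE[parcel.enterprise]

    # 4. demography: life-cycle advance, then sales
    for parcel in parcels:
        advance_life_cycle(
            state.population[parcel.parcel_id],
            state.rng_demography,
            cfg.demography.succession_rate,
            cfg.demography.steps_per_stage,
        )
    flagged = sum(
        1 for p in parcels if state.population[p.parcel_id].flagged_for_sale
    )
    state.n_sales_this_step = flagged

    def _new_owner_decision(buyer: Farmer, parcel: Parcel, rng) -> None:
        i = state.index_of[parcel.parcel_id]
        nr_row = nr_rows[i]
        proposed = _argmax_with_ties(nr_row, parcel.enterprise)
        nr_map = {
            e: float(nr_row[ci])
            for ci, e in enumerate(ENTERPRISE_ORDER)
            if np.isfinite(nr_row[ci])
        }
        record = evaluate_decision(
            buyer, parcel, state.market, state.coeffs, False, rng,
            initial_likelihood=beh.initial_likelihood,
            dairy_penalty=beh.dairy_penalty,
            forest_lock_steps=beh.forest_lock_steps,
            proposal=(proposed, nr_map),
        )
        if record.uniform_draw is not None:
            state.decision_rows.append(record)
        if record.converted:
            state.ent_codes[i] = _ENT_CODE[parcel.enterprise]

    resolve_sales(
        state.population,
        state.landscape,
        state.rng_demography,
        cfg,
        new_owner_decision=_new_owner_decision,
        id_factory=state.id_factory,
    )

    # 5. book realised revenue and append the ledger row
    state._refresh_realised()
    state.record_ledger()
    return state


def _endorsement_delta_fast(
    state: SimulationState, i: int, ent_prev: np.ndarray, profit_prev: np.ndarray
) -> float:
    from .networks import k_nearest_same_enterprise

    members = k_nearest_same_enterprise(
        state.dist[i], ent_prev, i, state.config.behaviour.k_social
    )
    if members.size == 0:
        return 0.0
    mean = float(profit_prev[members].mean())
    own = float(profit_prev[i])
    mag = state.config.behaviour.endorsement_delta
    return -mag if own > mean else (+mag if own < mean else 0.0)


def _imitation_delta_fast(
    state: SimulationState,
    i: int,
    proposed_code: int,
    ent_prev: np.ndarray,
    profit_prev: np.ndarray,
) -> float:
    nbrs = state.adj_idx[i]
    if nbrs.size == 0:
        return 0.0
    members = nbrs[ent_prev[nbrs] == proposed_code]
    if members.size == 0:
        return 0.0
    mean = float(profit_prev[members].mean())
    own = float(profit_prev[i])
    mag = state.config.behaviour.imitation_delta
    return -mag if own > mean else (+mag if own < mean else 0.0)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Complete record of one run."""

    meta: dict[str, Any]
    parcel_ids: list[str]
    zones: list[str]
    areas: np.ndarray
    #: (n_steps + 1, n_parcels) enterprise codes, step 0 first
    enterprise_path: np.ndarray
    ledger: pd.DataFrame
    decisions: pd.DataFrame
    final_landscape: Landscape

    def ledger_csv_bytes(self) -> bytes:
        return self.ledger.to_csv(index=False).encode()

    def series(self, variable: str) -> pd.Series:
        """Per-step values of a scalar ledger variable."""
        sub = self.ledger[self.ledger["variable"] == variable]
        return sub.groupby("step")["value"].sum()


def initialise(config: ModelConfig, seed: int) -> SimulationState:
    """Build the initial state: landscape, adjacency, farmers, market."""
    config = copy.deepcopy(config)
    config.validate()
    ss = np.random.SeedSequence(seed)
    rng_land, rng_init, rng_dec, rng_dem = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    if config.landscape.landscape_seed is not None:
        rng_land = np.random.default_rng(config.landscape.landscape_seed)
    if config.landscape.source is not None:
        raw = load_landscape(config.landscape.source, config)
    else:
        raw = generate_synthetic_landscape(config.landscape.generator, rng_land)
    landscape = filter_parcels(raw, config.landscape.min_area_ha)
    if landscape.adjacency is None:
        landscape.adjacency = build_adjacency(landscape)

    coeffs = (
        CoefficientTable.from_csv(config.coefficients)
        if config.coefficients
        else CoefficientTable.default()
    )

    id_factory = FarmerIdFactory()
    population = make_initial_population(
        landscape,
        rng_init,
        config.demography.succession_rate,
        config.behaviour.initial_likelihood,
        id_factory=id_factory,
    )
    state = SimulationState(
        config, landscape, population, coeffs, rng_dec, rng_dem, id_factory
    )
    state._refresh_realised()
    state.record_ledger()
    return state


def run(config: ModelConfig, seed: int) -> Trajectory:
    """Run a full simulation (default 10 steps = 50 years)."""
    state = initialise(config, seed)
    for _ in range(config.n_steps):
        step(state)
    decisions = pd.DataFrame(
        [
            dict(
                farmer_id=d.farmer_id,
                step=d.step,
                current=d.current.value,
                proposed=d.proposed.value,
                likelihood_final=d.likelihood_final,
                uniform_draw=d.uniform_draw,
                converted=d.converted,
            )
            for d in state.decision_rows
        ],
        columns=[
            "farmer_id", "step", "current", "proposed",
            "likelihood_final", "uniform_draw", "converted",
        ],
    )
    beh = state.config.behaviour
    meta = dict(
        seed=seed,
        ghg_price=state.config.market.ghg_price,
        networks_enabled=beh.network_effects_enabled,
        n_steps=state.config.n_steps,
    )
    return Trajectory(
        meta=meta,
        parcel_ids=state.landscape.parcel_ids,
        zones=[p.zone.value for p in state.landscape.parcels],
        areas=state.areas.copy(),
        enterprise_path=np.stack(state.enterprise_path),
        ledger=pd.DataFrame(state.ledger_rows),
        decisions=decisions,
        final_landscape=state.landscape,
    )
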