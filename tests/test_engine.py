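"""The decision rule, behavioural constraints and the step loop."""
from __future__ import annotations

import copy

import numpy as np
import pandas as pd
import pytest

from farmscape import (
    ENTERPRISE_ORDER,
    BehaviourConfig,
    DemographyConfig,
    GeneratorConfig,
    LandscapeConfig,
    MarketConfig,
    MarketState,
    ModelConfig,
    apply_constraints,
    enterprise_net_revenue,
    evaluate_decision,
    run,
)
from farmscape.demography import Farmer
from helpers import E, Z, flat_table, make_parcel

FOREST_CODES = {ENTERPRISE_ORDER.index(E.FORESTRY),
                ENTERPRISE_ORDER.index(E.CARBON_FORESTRY)}


def tiny_config(**kw) -> ModelConfig:
    cfg = ModelConfig(
        landscape=LandscapeConfig(
            generator=GeneratorConfig(n_rows=16, n_cols=16, mean_cells=6.0)
        )
    )
    for key, value in kw.items():
        obj, attr = cfg, key
        while "." in attr:
            head, attr = attr.split(".", 1)
            obj = getattr(obj, head)
        setattr(obj, attr, value)
    return cfg


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "likelihood, current, proposed, lock, expected",
    [
        (0.35, E.FORESTRY, E.SHEEP_BEEF, 3, 0.0),       # locked forest
        (0.35, E.CARBON_FORESTRY, E.FORESTRY, 1, 0.0),  # locked carbon forest
        (0.2, E.SHEEP_BEEF, E.DAIRY, 0, 0.05),          # 75 % Dairy reduction
        (0.35, E.SHEEP_BEEF, E.DAIRY, 0, 0.0875),
        (0.3, E.SHEEP_BEEF, E.FORESTRY, 0, 0.3),        # unchanged
        (0.3, E.FORESTRY, E.SHEEP_BEEF, 0, 0.3),        # lock expired
        (1.5, E.SHEEP_BEEF, E.FORESTRY, 0, 1.0),        # clamped
        (-0.2, E.SHEEP_BEEF, E.FORESTRY, 0, 0.0),
    ],
)
def test_apply_constraints_algebra(likelihood, current, proposed, lock, expected):
    assert apply_constraints(likelihood, current, proposed, lock) == pytest.approx(expected)


def test_constraint_outcomes_without_networks_are_three_valued():
    """With networks off the final likelihood can only be the base value,
    the Dairy-penalised value, or zero (locked)."""
    outcomes = set()
    for current in (E.DAIRY, E.SHEEP_BEEF, E.FORESTRY, E.CARBON_FORESTRY):
        for proposed in (E.DAIRY, E.SHEEP_BEEF, E.FORESTRY, E.CARBON_FORESTRY):
            for lock in (0, 1, 5):
                if lock > 0 and current not in (E.FORESTRY, E.CARBON_FORESTRY):
                    continue
                outcomes.add(round(apply_constraints(0.2, current, proposed, lock), 10))
    assert outcomes == {0.0, 0.05, 0.2}


# ---------------------------------------------------------------------------
# Single decisions
# ---------------------------------------------------------------------------


def test_matching_proposal_updates_revenue_without_a_draw(rng):
    table = flat_table(dairy=0.0, sheepbeef=5000.0)  # SheepBeef dominant
    parcel = make_parcel("p", enterprise=E.SHEEP_BEEF, area=100.0)
    farmer = Farmer(farmer_id="f", farm_id="p")
    market = MarketState(step=1, price_index=1.0, ghg_price=0.0)
    state_before = copy.deepcopy(rng.bit_generator.state)
    record = evaluate_decision(farmer, parcel, market, table, True, rng)
    assert rng.bit_generator.state == state_before  # no rng consumed
    assert not record.converted and record.uniform_draw is None
    assert farmer.net_revenue == pytest.approx(500_000.0)
    assert farmer.profitability_per_ha == pytest.approx(5000.0)


def test_zero_likelihood_never_converts(rng):
    table = flat_table(dairy=0.0, sheepbeef=5000.0)
    market = MarketState(step=1, price_index=1.0, ghg_price=0.0)
    for _ in range(10_000):
        parcel = make_parcel("p", enterprise=E.FORESTRY, lock=3)
        farmer = Farmer(farmer_id="f", farm_id="p")
        record = evaluate_decision(farmer, parcel, market, table, False, rng)
        assert record.likelihood_final == 0.0
        assert not record.converted
        assert parcel.enterprise is E.FORESTRY


def test_conversion_frequency_tracks_likelihood(rng):
    """Empirical conversion frequency over 10,000 draws sits within
    ±0.01 of the final likelihood (0.3 = base 0.2 + endorsement 0.1)."""
    table = flat_table(dairy=0.0, sheepbeef=5000.0)
    market = MarketState(step=1, price_index=1.0, ghg_price=0.0)
    n, hits = 10_000, 0
    for _ in range(n):
        parcel = make_parcel("p", enterprise=E.FORESTRY)
        farmer = Farmer(farmer_id="f", farm_id="p")
        record = evaluate_decision(
            farmer, parcel, market, table, True, rng, endorsement_delta=0.1
        )
        assert record.likelihood_final == pytest.approx(0.3)
        hits += record.converted
    assert hits / n == pytest.approx(0.3, abs=0.01)


def test_conversion_to_forest_starts_lock():
    rng = np.random.default_rng(0)
    table = flat_table(dairy=0.0, sheepbeef=1.0, forestry=5000.0)
    market = MarketState(step=1, price_index=1.0, ghg_price=0.0)
    converted = False
    while not converted:
        parcel = make_parcel("p", enterprise=E.SHEEP_BEEF)
        farmer = Farmer(farmer_id="f", farm_id="p")
        record = evaluate_decision(farmer, parcel, market, table, False, rng)
        converted = record.converted
    assert parcel.enterprise is E.FORESTRY
    assert parcel.forest_lock_steps == 5


def test_network_deltas_ignored_when_disabled(rng):
    table = flat_table(dairy=0.0, sheepbeef=5000.0)
    market = MarketState(step=1, price_index=1.0, ghg_price=0.0)
    parcel = make_parcel("p", enterprise=E.FORESTRY)
    farmer = Farmer(farmer_id="f", farm_id="p")
    record = evaluate_decision(
        farmer, parcel, market, table, False, rng,
        endorsement_delta=0.1, imitation_delta=0.05,
    )
    assert record.likelihood_final == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# Step and run
# ---------------------------------------------------------------------------


def test_zero_base_likelihood_freezes_the_landscape():
    cfg = tiny_config(**{"behaviour.initial_likelihood": 0.0,
                         "behaviour.network_effects_enabled": False})
    traj = run(cfg, seed=5)
    path = traj.enterprise_path
    assert (path == path[0]).all()
    areas = traj.ledger[traj.ledger.variable == "area_ha"]
    by_step = areas.groupby("step").value.sum()
    assert np.allclose(by_step.values, by_step.values[0])


def test_same_seed_same_config_byte_identical_ledgers():
    for seed in (1, 7, 13):
        for tau in (0.0, 40.0):
            for nets in (True, False):
                cfg = tiny_config(**{"market.ghg_price": tau,
                                     "behaviour.network_effects_enabled": nets})
                a, b = run(cfg, seed), run(copy.deepcopy(cfg), seed)
                assert a.ledger_csv_bytes() == b.ledger_csv_bytes()
                assert a.decisions.equals(b.decisions)
                assert (a.enterprise_path == b.enterprise_path).all()


def test_total_area_constant_across_steps():
    traj = run(tiny_config(), seed=3)
    areas = traj.ledger[traj.ledger.variable == "area_ha"]
    totals = areas.groupby("step").value.sum().values
    assert np.allclose(totals, totals[0])


def test_converted_iff_draw_below_likelihood():
    traj = run(tiny_config(**{"market.ghg_price": 60.0}), seed=4)
    dec = traj.decisions.dropna(subset=["uniform_draw"])
    assert len(dec) > 50
    assert (dec.converted == (dec.uniform_draw < dec.likelihood_final)).all()


def test_forest_lock_holds_for_five_steps():
    """Every conversion into a forest enterprise freezes the parcel's
    enterprise for the following four steps."""
    traj = run(tiny_config(**{"market.ghg_price": 60.0}), seed=8)
    path = traj.enterprise_path  # (steps+1, n)
    n_steps = path.shape[0] - 1
    checked = 0
    for t in range(1, n_steps + 1):
        changed = np.nonzero(path[t] != path[t - 1])[0]
        for i in changed:
            if int(path[t, i]) in FOREST_CODES:
                horizon = min(t + 5, n_steps + 1)
                assert (path[t:horizon, i] == path[t, i]).all()
                checked += 1
    assert checked > 0


def test_network_off_final_likelihoods_three_valued():
    traj = run(tiny_config(**{"behaviour.network_effects_enabled": False,
                              "market.ghg_price": 60.0}), seed=2)
    dec = traj.decisions.dropna(subset=["uniform_draw"])
    allowed = np.array([0.0, 0.05, 0.2])
    assert np.isclose(dec.likelihood_final.values[:, None], allowed).any(axis=1).all()


def test_run_zero_steps_records_initial_state_only():
    traj = run(tiny_config(n_steps=0), seed=1)
    assert traj.ledger.step.max() == 0
    assert traj.enterprise_path.shape[0] == 1
    assert traj.decisions.empty


def test_run_default_has_ten_post_initial_steps():
    traj = run(tiny_config(), seed=1)
    assert sorted(traj.ledger.step.unique()) == list(range(11))
    assert traj.enterprise_path.shape[0] == 11


def test_forced_conversion_reaches_argmax_fixed_point():
    """With certain conversion (likelihood 1, no Dairy penalty, no lock),
    static prices and no sales, every farm sits at its revenue-maximising
    enterprise after step 1 and the allocation is absorbing."""
    cfg = tiny_config(**{
        "behaviour.initial_likelihood": 1.0,
        "behaviour.dairy_penalty": 0.0,
        "behaviour.forest_lock_steps": 0,
        "behaviour.network_effects_enabled": False,
        "demography.succession_rate": 1.0,
        "market.annual_price_growth": 0.0,
        "market.ghg_price": 0.0,
    })
    traj = run(cfg, seed=6)
    path = traj.enterprise_path
    # absorbing from step 1 on
    assert (path[1:] == path[1]).all()
    # step-1 allocation is the brute-force argmax per parcel
    from farmscape import CoefficientTable, optimize_farm

    table = CoefficientTable.default()
    final = traj.final_landscape
    market = MarketState(step=1, price_index=1.0, ghg_price=0.0)
    for parcel in final.parcels:
        nrs = {
            e: enterprise_net_revenue(parcel, e, market, table)
            for e in ENTERPRISE_ORDER
            if table.feasible(e, parcel.zone)
        }
        assert nrs[parcel.enterprise] == max(nrs.values())


def test_sales_occur_and_farmer_count_is_conserved():
    traj = run(tiny_config(**{"demography.succession_rate": 0.0}), seed=9)
    sales = traj.ledger[traj.ledger.variable == "n_sales"].value
    assert sales.sum() > 0
    assert len(traj.final_landscape.parcels) == len(traj.parcel_ids)
    owners = [p.owner_id for p in traj.final_landscape.parcels]
    assert len(set(owners)) == len(owners)
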