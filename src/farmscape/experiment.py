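"""Scenario ensembles: the carbon-price x network-toggle x seed grid.

The experiment design crosses a set of carbon prices (default $0-$60 in
$10 increments) with the network-effects toggle and an ensemble of
seeds (default 50), i.e. 700 runs.  Aggregation produces: per-step
means with normal-approximation 95 % confidence intervals for every
ledger output; land-use shares by productivity zone with the
network-on minus network-off delta; and per-parcel probabilities of
ending in each enterprise across the ensemble.
"""
from __future__ import annotations

import copy
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, ScenarioGrid
from .engine import Trajectory, run
from .landscape import ENTERPRISE_ORDER, ZONE_ORDER

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95 % normal quantile


def _scenario_config(model: ModelConfig, ghg_price: float, networks: bool) -> ModelConfig:
    cfg = copy.deepcopy(model)
    cfg.market.ghg_price = float(ghg_price)
    cfg.behaviour.network_effects_enabled = bool(networks)
    return cfg


def run_experiment(grid: ScenarioGrid, jobs: int = 1) -> list[Trajectory]:
    """Run every (price, network setting, seed) triple.

    Runs are independent, so results do not depend on execution order;
    ``jobs > 1`` parallelises over scenarios with joblib.
    """
    grid.validate()
    tasks = [
        (price, networks, seed)
        for price in grid.ghg_prices
        for networks in grid.network_effects
        for seed in grid.seeds
    ]

    def _one(price: float, networks: bool, seed: int) -> Trajectory:
        try:
            return run(_scenario_config(grid.model, price, networks), seed)
        except Exception as exc:  # surface the scenario identity
            raise RuntimeError(
                f"run failed for ghg_price={price}, networks={networks}, "
                f"seed={seed}: {exc}"
            ) from exc

    if jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=jobs)(delayed(_one)(*t) for t in tasks)
    else:
        results = [_one(*t) for t in tasks]
    logger.info("experiment complete: %d runs", len(results))
    return list(results)


def summarize(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Ensemble means and 95 % CIs per scenario, step and output.

    CI bounds are mean ± 1.96 sd / sqrt(n) over seeds.  Scenarios with
    a single run report the mean with NaN CI bounds.
    """
    if not trajectories:
        raise ValueError("no trajectories to summarize")
    frames = []
    for traj in trajectories:
        led = traj.ledger.copy()
        led["ghg_price"] = traj.meta["ghg_price"]
        led["networks"] = traj.meta["networks_enabled"]
        led["seed"] = traj.meta["seed"]
        frames.append(led)
    long = pd.concat(frames, ignore_index=True)
    # fix the within-group order so float accumulation is independent of
    # the order trajectories were supplied in
    long = long.sort_values(
        ["ghg_price", "networks", "step", "variable", "enterprise", "zone", "seed"],
        kind="mergesort",
    ).reset_index(drop=True)
    grouped = long.groupby(
        ["ghg_price", "networks", "step", "variable", "enterprise", "zone"],
        dropna=False,
        sort=True,
    )["value"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    half = _Z95 * out["sd"] / np.sqrt(out["n"])
    out["ci_lower"] = out["mean"] - half
    out["ci_upper"] = out["mean"] + half
    single = out["n"] < 2
    out.loc[single, ["sd", "ci_lower", "ci_upper"]] = np.nan
    return out


def _area_by_zone_enterprise(traj: Trajectory, step: int) -> np.ndarray:
    """(zones, enterprises) hectares at a step of one run."""
    codes = traj.enterprise_path[step]
    zone_code = {z.value: i for i, z in enumerate(ZONE_ORDER)}
    zi = np.array([zone_code[z] for z in traj.zones])
    out = np.zeros((len(ZONE_ORDER), len(ENTERPRISE_ORDER)))
    np.add.at(out, (zi, codes), traj.areas)
    return out


def land_use_share_table(
    trajectories: Sequence[Trajectory], step: int = -1
) -> pd.DataFrame:
    """Zone x enterprise land-use shares and the network-effect delta.

    Shares are percentages of total catchment area, averaged over seeds
    within each (price, network arm); ``delta`` is the network-on minus
    network-off share.  Both arms must be present for every price.
    """
    rows = []
    for traj in trajectories:
        s = step if step >= 0 else traj.enterprise_path.shape[0] + step
        area = _area_by_zone_enterprise(traj, s)
        total = traj.areas.sum()
        for zi, zone in enumerate(ZONE_ORDER):
            for ei, ent in enumerate(ENTERPRISE_ORDER):
                rows.append(
                    dict(
                        ghg_price=traj.meta["ghg_price"],
                        networks=traj.meta["networks_enabled"],
                        zone=zone.value,
                        enterprise=ent.value,
                        share_pct=100.0 * area[zi, ei] / total,
                    )
                )
    frame = pd.DataFrame(rows)
    mean = (
        frame.groupby(["ghg_price", "networks", "zone", "enterprise"], sort=True)[
            "share_pct"
        ]
        .mean()
        .reset_index()
    )
    wide = mean.pivot_table(
        index=["ghg_price", "zone", "enterprise"],
        columns="networks",
        values="share_pct",
    )
    wide = wide.rename(columns={True: "share_on_pct", False: "share_off_pct"})
    wide.columns.name = None
    wide = wide.reset_index()
    for arm in ("share_on_pct", "share_off_pct"):
        missing = (
            set(wide["ghg_price"].unique())
            if arm not in wide.columns
            else set(wide.loc[wide[arm].isna(), "ghg_price"].unique())
        )
        if missing:
            raise ValueError(
                f"missing network arm for ghg_price={sorted(missing)}"
            )
    wide["delta_pct"] = wide["share_on_pct"] - wide["share_off_pct"]
    return wide


def parcel_enterprise_probability(
    trajectories: Sequence[Trajectory], step: int = -1
) -> pd.DataFrame:
    """Per-parcel probability of each enterprise across the ensemble.

    The probability is the fraction of runs in which the parcel is at
    that enterprise at ``step`` (default: final); per-parcel
    probabilities sum to 1.  Pass a pre-filtered collection to scope
    this to one scenario.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    ids = trajectories[0].parcel_ids
    counts = np.zeros((len(ids), len(ENTERPRISE_ORDER)))
    for traj in trajectories:
        if traj.parcel_ids != ids:
            raise ValueError("trajectories cover different landscapes")
        s = step if step >= 0 else traj.enterprise_path.shape[0] + step
        codes = traj.enterprise_path[s]
        counts[np.arange(len(ids)), codes] += 1.0
    probs = counts / len(trajectories)
    out = pd.DataFrame(probs, columns=[e.value for e in ENTERPRISE_ORDER])
    out.insert(0, "parcel_id", ids)
    out.insert(1, "zone", trajectories[0].zones)
    return out
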