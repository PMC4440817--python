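"""Farm economics: enterprise budgets, the per-farm optimiser, accounting.

Each (enterprise, zone) pair carries an annualised per-hectare budget —
commodity revenue, operating cost, gross GHG emissions, carbon
sequestration, nitrogen leaching and phosphorus loss — plus a
feasibility flag.  Expected net revenue of running enterprise *e* on a
farm of area *A* in zone *z* at step *t* under carbon price ``tau`` is

    A * [ revenue(e,z) * index(t) - cost(e,z)
          - tau * emissions(e,z) + tau * sequestration(e,z) ]

mirroring the Emissions Trading Scheme's incidence: livestock pays the
carbon price on its emissions, Carbon Forestry (permanent, unharvested)
is paid for sequestration, and rotational plantation Forestry neither
pays nor is paid.  Commodity revenue grows with a real price index;
costs are held in real terms.

The per-farm optimiser is a direct argmax over feasible enterprise
budgets — the farm-level result an external partial-equilibrium model
would hand back to each agent.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .landscape import (
    ENTERPRISE_ORDER,
    ZONE_ORDER,
    Enterprise,
    Landscape,
    Parcel,
    ProductivityZone,
)

_ENT_INDEX = {e: i for i, e in enumerate(ENTERPRISE_ORDER)}
_ZONE_INDEX = {z: i for i, z in enumerate(ZONE_ORDER)}

_RATE_COLUMNS = (
    "revenue_per_ha",
    "cost_per_ha",
    "emissions_per_ha",
    "sequestration_per_ha",
    "n_leach_per_ha",
    "p_loss_per_ha",
)


@dataclass(frozen=True)
class MarketState:
    """Prices as seen by every farm at one model step."""

    step: int
    price_index: float
    ghg_price: float

    def __post_init__(self) -> None:
        if self.step < 0:
            raise ValueError("step must be >= 0")
        if self.price_index < 0 or self.ghg_price < 0:
            raise ValueError("price_index and ghg_price must be >= 0")


def price_index(step: int, annual_growth: float, years_per_step: int) -> float:
    """Real commodity price index after ``step`` model steps.

    ``(1 + annual_growth) ** (years_per_step * step)``; equals 1 at
    step 0 and is strictly increasing for positive growth.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    return float((1.0 + annual_growth) ** (years_per_step * step))


class CoefficientTable:
    """Enterprise x zone budget and environmental coefficients.

    Stored internally as dense (enterprise, zone) arrays over the four
    modelled enterprises and three zones, for vectorised evaluation
    across a whole landscape.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"enterprise", "zone", "feasible", *_RATE_COLUMNS}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"coefficient table missing columns: {sorted(missing)}")
        n_e, n_z = len(ENTERPRISE_ORDER), len(ZONE_ORDER)
        self._rates = {col: np.zeros((n_e, n_z)) for col in _RATE_COLUMNS}
        self._feasible = np.zeros((n_e, n_z), dtype=bool)
        seen = np.zeros((n_e, n_z), dtype=bool)
        for _, row in frame.iterrows():
            e = Enterprise(row["enterprise"])
            z = ProductivityZone(row["zone"])
            if e not in _ENT_INDEX:
                raise ValueError(f"coefficients given for non-modelled enterprise {e}")
            ei, zi = _ENT_INDEX[e], _ZONE_INDEX[z]
            if seen[ei, zi]:
                raise ValueError(f"duplicate coefficient row for ({e.value}, {z.value})")
            seen[ei, zi] = True
            for col in _RATE_COLUMNS:
                value = float(row[col])
                if value < 0:
                    raise ValueError(f"negative {col} for ({e.value}, {z.value})")
                self._rates[col][ei, zi] = value
            self._feasible[ei, zi] = bool(row["feasible"])
        if not seen.all():
            holes = [
                (ENTERPRISE_ORDER[i].value, ZONE_ORDER[j].value)
                for i, j in zip(*np.nonzero(~seen))
            ]
            raise ValueError(f"coefficient table incomplete; missing {holes}")
        if not self._feasible.any(axis=0).all():
            raise ValueError("every zone needs at least one feasible enterprise")
        self._frame = frame.reset_index(drop=True)

    # -- constructors -----------------------------------------------------
    @classmethod
    def default(cls) -> "CoefficientTable":
        from .config import default_coefficient_frame

        return cls(default_coefficient_frame())

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        return cls(pd.read_csv(path))

    # -- lookups ----------------------------------------------------------
    def rate(self, column: str, enterprise: Enterprise, zone: ProductivityZone) -> float:
        return float(self._rates[column][_ENT_INDEX[enterprise], _ZONE_INDEX[zone]])

    def feasible(self, enterprise: Enterprise, zone: ProductivityZone) -> bool:
        return bool(self._feasible[_ENT_INDEX[enterprise], _ZONE_INDEX[zone]])

    def feasible_enterprises(self, zone: ProductivityZone) -> list[Enterprise]:
        zi = _ZONE_INDEX[zone]
        return [e for e in ENTERPRISE_ORDER if self._feasible[_ENT_INDEX[e], zi]]

    def rates_array(self, column: str) -> np.ndarray:
        """(n_enterprises, n_zones) array of a per-ha rate."""
        return self._rates[column].copy()

    @property
    def feasible_mask(self) -> np.ndarray:
        return self._feasible.copy()

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    # -- vectorised net revenue -------------------------------------------
    def net_revenue_per_ha(self, market: MarketState) -> np.ndarray:
        """(n_enterprises, n_zones) NZD/ha/yr; -inf where infeasible."""
        nr = (
            self._rates["revenue_per_ha"] * market.price_index
            - self._rates["cost_per_ha"]
            - market.ghg_price * self._rates["emissions_per_ha"]
            + market.ghg_price * self._rates["sequestration_per_ha"]
        )
        return np.where(self._feasible, nr, -np.inf)


def enterprise_net_revenue(
    parcel: Parcel,
    enterprise: Enterprise,
    market: MarketState,
    coeffs: CoefficientTable,
) -> float:
    """Expected annual net revenue (NZD/yr) of running ``enterprise`` on
    ``parcel`` under the current market.

    Raises ``ValueError`` for an infeasible (enterprise, zone) pair:
    callers must mask feasibility first.
    """
    if not coeffs.feasible(enterprise, parcel.zone):
        raise ValueError(
            f"{enterprise.value} is not feasible in {parcel.zone.value} "
            f"(parcel {parcel.parcel_id})"
        )
    per_ha = coeffs.net_revenue_per_ha(market)[
        _ENT_INDEX[enterprise], _ZONE_INDEX[parcel.zone]
    ]
    return float(parcel.area_ha * per_ha)


def _argmax_with_ties(
    nr_row: np.ndarray, current: Enterprise | None
) -> Enterprise:
    """Argmax over the enterprise axis with the deterministic tie rule:
    the current enterprise wins if among the maxima, else the first
    enterprise in the fixed order."""
    best = nr_row.max()
    if not np.isfinite(best):
        raise ValueError("no feasible enterprise")
    winners = np.nonzero(nr_row == best)[0]
    if current is not None and _ENT_INDEX.get(current) in winners:
        return current
    return ENTERPRISE_ORDER[int(winners[0])]


def optimize_farm(
    parcel: Parcel, market: MarketState, coeffs: CoefficientTable
) -> tuple[Enterprise, dict[Enterprise, float]]:
    """Revenue-maximising enterprise for one farm.

    Returns the proposal and the expected net revenue (NZD/yr) of every
    feasible enterprise.  Exact ties go to the current enterprise if it
    is among the maxima, otherwise to the first enterprise in the fixed
    order.
    """
    per_ha = coeffs.net_revenue_per_ha(market)[:, _ZONE_INDEX[parcel.zone]]
    nr_row = parcel.area_ha * per_ha
    current = parcel.enterprise if parcel.enterprise in _ENT_INDEX else None
    proposed = _argmax_with_ties(nr_row, current)
    nr_map = {
        e: float(nr_row[_ENT_INDEX[e]])
        for e in ENTERPRISE_ORDER
        if np.isfinite(nr_row[_ENT_INDEX[e]])
    }
    return proposed, nr_map


def environmental_outputs(
    landscape: Landscape, coeffs: CoefficientTable
) -> dict[str, float]:
    """Catchment-level annual environmental accounts.

    Sums area x per-ha coefficient over parcels; ``net_ghg`` is exactly
    ``gross_ghg - sequestration`` (livestock emissions less forest
    carbon uptake).
    """
    areas = np.array([p.area_ha for p in landscape.parcels])
    ei = np.array([_ENT_INDEX[p.enterprise] for p in landscape.parcels])
    zi = np.array([_ZONE_INDEX[p.zone] for p in landscape.parcels])
    totals = {
        name: float((areas * coeffs.rates_array(col)[ei, zi]).sum())
        for name, col in (
            ("gross_ghg", "emissions_per_ha"),
            ("sequestration", "sequestration_per_ha"),
            ("n_leach", "n_leach_per_ha"),
            ("p_loss", "p_loss_per_ha"),
        )
    }
    totals["net_ghg"] = totals["gross_ghg"] - totals["sequestration"]
    return totals
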