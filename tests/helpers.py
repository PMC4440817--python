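"""Shared builders for toy landscapes and coefficient tables."""
from __future__ import annotations

import pandas as pd

from farmscape import (
    CoefficientTable,
    Enterprise,
    Landscape,
    Parcel,
    ProductivityZone,
    build_adjacency,
)

E = Enterprise
Z = ProductivityZone


def make_parcel(
    pid: str,
    enterprise: Enterprise = E.SHEEP_BEEF,
    zone: ProductivityZone = Z.PLAINS,
    area: float = 200.0,
    centroid: tuple[float, float] = (0.0, 0.0),
    cells=None,
    lock: int = 0,
) -> Parcel:
    return Parcel(
        parcel_id=pid,
        area_ha=area,
        centroid=centroid,
        zone=zone,
        enterprise=enterprise,
        forest_lock_steps=lock,
        cells=tuple(cells) if cells is not None else None,
    )


def grid_landscape(parcels: list[Parcel], with_adjacency: bool = True) -> Landscape:
    ls = Landscape(parcels=parcels)
    if with_adjacency:
        ls.adjacency = build_adjacency(ls)
    return ls


def flat_table(
    dairy: float = 2000.0,
    sheepbeef: float = 500.0,
    forestry: float = 400.0,
    carbon: float = 0.0,
    emissions_dairy: float = 9.0,
    emissions_sb: float = 3.0,
    sequestration: float = 8.0,
    dairy_on_hills: bool = False,
) -> CoefficientTable:
    """A coefficient table with the same budget in every zone.

    Net revenue at base prices and zero carbon price equals the
    headline numbers (cost = 0, revenue = net), which keeps hand
    arithmetic in tests trivial.
    """
    rows = []
    for zone in Z:
        rows += [
            dict(enterprise="Dairy", zone=zone.value, revenue_per_ha=dairy,
                 cost_per_ha=0.0, emissions_per_ha=emissions_dairy,
                 sequestration_per_ha=0.0, n_leach_per_ha=40.0, p_loss_per_ha=1.0,
                 feasible=dairy_on_hills or zone is not Z.HILLS),
            dict(enterprise="SheepBeef", zone=zone.value, revenue_per_ha=sheepbeef,
                 cost_per_ha=0.0, emissions_per_ha=emissions_sb,
                 sequestration_per_ha=0.0, n_leach_per_ha=12.0, p_loss_per_ha=0.5,
                 feasible=True),
            dict(enterprise="Forestry", zone=zone.value, revenue_per_ha=forestry,
                 cost_per_ha=0.0, emissions_per_ha=0.0, sequestration_per_ha=0.0,
                 n_leach_per_ha=3.0, p_loss_per_ha=0.1, feasible=True),
            dict(enterprise="CarbonForestry", zone=zone.value, revenue_per_ha=carbon,
                 cost_per_ha=0.0, emissions_per_ha=0.0,
                 sequestration_per_ha=sequestration, n_leach_per_ha=2.0,
                 p_loss_per_ha=0.1, feasible=True),
        ]
    return CoefficientTable(pd.DataFrame(rows))
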