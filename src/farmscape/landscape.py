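"""Spatial substrate: parcels, productivity zones, adjacency.

The landscape is a set of cadastral parcels, each operated as a single
enterprise (Dairy, Sheep & Beef, plantation Forestry or Carbon Forestry).
Parcels live on a 25-ha raster: a parcel is a contiguous block of cells,
its area a multiple of the cell size and its centroid the mean of its
cell centres.  Productivity zones (Plains / Foothills / Hills) map from
New Zealand Land Use Capability classes 1-4 / 5-6 / 7-8.

Real cadastres can be loaded from GeoJSON or a flat CSV; a seeded
region-growing generator provides synthetic catchments with the same
structure (three zone bands, farms above the 100-ha commercial
threshold, area dominated by Sheep & Beef).
"""
from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Enterprise(str, Enum):
    """Single land use operated on a farm."""

    DAIRY = "Dairy"
    SHEEP_BEEF = "SheepBeef"
    FORESTRY = "Forestry"
    CARBON_FORESTRY = "CarbonForestry"
    NON_MODELLED = "NonModelled"


#: Fixed enterprise order used for deterministic tie-breaking.
ENTERPRISE_ORDER: tuple[Enterprise, ...] = (
    Enterprise.DAIRY,
    Enterprise.SHEEP_BEEF,
    Enterprise.FORESTRY,
    Enterprise.CARBON_FORESTRY,
)

#: Enterprises a farm may carry at initialisation (Carbon Forestry only
#: ever arises through conversion during a simulation).
INITIAL_ENTERPRISES: frozenset[Enterprise] = frozenset(
    {Enterprise.DAIRY, Enterprise.SHEEP_BEEF, Enterprise.FORESTRY}
)

FOREST_ENTERPRISES: frozenset[Enterprise] = frozenset(
    {Enterprise.FORESTRY, Enterprise.CARBON_FORESTRY}
)


class ProductivityZone(str, Enum):
    PLAINS = "Plains"
    FOOTHILLS = "Foothills"
    HILLS = "Hills"


ZONE_ORDER: tuple[ProductivityZone, ...] = (
    ProductivityZone.PLAINS,
    ProductivityZone.FOOTHILLS,
    ProductivityZone.HILLS,
)


def assign_zone(luc_class: int, parcel_id: object | None = None) -> ProductivityZone:
    """Map a Land Use Capability class (1-8) to a productivity zone.

    Classes 1-4 are Plains, 5-6 Foothills, 7-8 Hills.

    Raises
    ------
    ValueError
        If ``luc_class`` is outside 1-8; the message names the parcel
        when ``parcel_id`` is given.
    """
    if luc_class not in range(1, 9):
        where = f" for parcel {parcel_id!r}" if parcel_id is not None else ""
        raise ValueError(f"LUC class must be in 1..8, got {luc_class!r}{where}")
    if luc_class <= 4:
        return ProductivityZone.PLAINS
    if luc_class <= 6:
        return ProductivityZone.FOOTHILLS
    return ProductivityZone.HILLS


@dataclass
class Parcel:
    """A farm: one parcel, one enterprise, one (eventual) operator."""

    parcel_id: str
    area_ha: float
    centroid: tuple[float, float]
    zone: ProductivityZone
    enterprise: Enterprise
    forest_lock_steps: int = 0
    owner_id: str | None = None
    #: (row, col) cells of the 25-ha raster this parcel occupies, when known.
    cells: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"parcel {self.parcel_id}: area must be positive")
        if self.forest_lock_steps < 0:
            raise ValueError(f"parcel {self.parcel_id}: negative forest lock")
        if self.forest_lock_steps > 0 and self.enterprise not in FOREST_ENTERPRISES:
            raise ValueError(
                f"parcel {self.parcel_id}: forest lock on non-forest enterprise"
            )


@dataclass
class Landscape:
    """Collection of parcels plus the rook-contiguity adjacency relation."""

    parcels: list[Parcel]
    adjacency: dict[str, frozenset[str]] | None = None
    cell_size_ha: float = 25.0
    #: side length of one raster cell in metres (sqrt(25 ha) = 500 m)
    cell_size_m: float = field(init=False)

    def __post_init__(self) -> None:
        self.cell_size_m = math.sqrt(self.cell_size_ha * 1e4)
        ids = [p.parcel_id for p in self.parcels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate parcel ids")
        self.parcels = sorted(self.parcels, key=lambda p: p.parcel_id)

    def __len__(self) -> int:
        return len(self.parcels)

    @property
    def parcel_ids(self) -> list[str]:
        return [p.parcel_id for p in self.parcels]

    def parcel(self, parcel_id: str) -> Parcel:
        i = self._index()[parcel_id]
        return self.parcels[i]

    def _index(self) -> dict[str, int]:
        return {p.parcel_id: i for i, p in enumerate(self.parcels)}

    @property
    def total_area_ha(self) -> float:
        return float(sum(p.area_ha for p in self.parcels))

    def neighbours(self, parcel_id: str) -> frozenset[str]:
        if self.adjacency is None:
            raise ValueError("adjacency not built; call build_adjacency first")
        return self.adjacency.get(parcel_id, frozenset())

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per parcel), round-trippable through CSV."""
        return pd.DataFrame(
            {
                "parcel_id": [p.parcel_id for p in self.parcels],
                "landuse": [p.enterprise.value for p in self.parcels],
                "zone": [p.zone.value for p in self.parcels],
                "area_ha": [p.area_ha for p in self.parcels],
                "centroid_x": [p.centroid[0] for p in self.parcels],
                "centroid_y": [p.centroid[1] for p in self.parcels],
            }
        )


# ---------------------------------------------------------------------------
# Loading real landscapes
# ---------------------------------------------------------------------------

_CROWN_LABELS = {"crown", "crown_land", "doc", "conservation"}


def _parse_enterprise(label: object, parcel_id: str) -> Enterprise:
    try:
        return Enterprise(str(label))
    except ValueError:
        logger.warning(
            "parcel %s: unknown land-use label %r mapped to NonModelled",
            parcel_id,
            label,
        )
        return Enterprise.NON_MODELLED


def _resolve_zone(row: Mapping, parcel_id: str) -> ProductivityZone:
    zone = row.get("zone")
    if zone is not None and not (isinstance(zone, float) and math.isnan(zone)):
        return ProductivityZone(str(zone))
    luc = row.get("luc_class")
    if luc is None or (isinstance(luc, float) and math.isnan(luc)):
        raise ValueError(f"parcel {parcel_id}: neither zone nor luc_class given")
    return assign_zone(int(luc), parcel_id)


def _majority(labels: Sequence, weights: Sequence[float], order: Sequence) -> object:
    """Label with the largest summed weight; ties go to the earliest in *order*."""
    totals: dict = {}
    for lab, w in zip(labels, weights):
        totals[lab] = totals.get(lab, 0.0) + float(w)
    best = max(totals.values())
    ranked = {lab: i for i, lab in enumerate(order)}
    winners = sorted(
        (lab for lab, tot in totals.items() if tot == best),
        key=lambda lab: ranked.get(lab, len(ranked)),
    )
    return winners[0]


def load_landscape(parcel_source: str | Path | pd.DataFrame, config=None) -> Landscape:
    """Load and validate a parcel landscape.

    Accepts a GeoJSON file (polygon features with ``parcel_id``,
    ``landuse``, ``luc_class`` or ``zone``, optional ``tenure``
    properties), a CSV with the same attributes plus ``area_ha`` and
    centroid coordinates, or an equivalent DataFrame.  A CSV/DataFrame
    may also be cell-level (repeated ``parcel_id`` rows, one per raster
    cell): the parcel then takes the majority-area land use and zone,
    the summed area and the area-weighted centroid.

    Crown-tenure parcels are dropped (no farmer agents on non-productive
    Crown land); unrecognised land-use labels become ``NonModelled``
    with a logged warning.
    """
    geoms: dict[str, object] = {}
    if isinstance(parcel_source, pd.DataFrame):
        frame = parcel_source.copy()
    else:
        path = Path(parcel_source)
        if path.suffix.lower() in {".geojson", ".json"}:
            frame, geoms = _geojson_to_frame(path)
        else:
            frame = pd.read_csv(path)

    required = {"parcel_id", "landuse"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"parcel source missing columns: {sorted(missing_cols)}")
    if "zone" not in frame.columns and "luc_class" not in frame.columns:
        raise ValueError("parcel source needs a 'zone' or 'luc_class' column")

    frame["parcel_id"] = frame["parcel_id"].astype(str)

    bad = [
        pid
        for pid, grp in frame.groupby("parcel_id", sort=True)
        if grp["landuse"].isna().any()
        or ("area_ha" in frame.columns and grp["area_ha"].isna().any() and pid not in geoms)
    ]
    if bad:
        raise ValueError(f"parcels with missing attributes: {bad}")

    parcels: list[Parcel] = []
    for pid, grp in frame.groupby("parcel_id", sort=True):
        tenure = grp.get("tenure")
        if tenure is not None and any(
            str(t).strip().lower() in _CROWN_LABELS for t in tenure.dropna()
        ):
            logger.info("parcel %s: Crown tenure, excluded", pid)
            continue

        if pid in geoms:
            geom = geoms[pid]
            area = geom.area / 1e4
            centroid = (geom.centroid.x, geom.centroid.y)
        else:
            if "area_ha" not in grp.columns:
                raise ValueError(f"parcel {pid}: no geometry and no area_ha")
            areas = grp["area_ha"].astype(float)
            area = float(areas.sum())
            if {"centroid_x", "centroid_y"} <= set(grp.columns):
                w = areas / area
                centroid = (
                    float((grp["centroid_x"].astype(float) * w).sum()),
                    float((grp["centroid_y"].astype(float) * w).sum()),
                )
            else:
                raise ValueError(f"parcel {pid}: centroid_x/centroid_y required")

        weights = (
            grp["area_ha"].astype(float).tolist()
            if "area_ha" in grp.columns
            else [1.0] * len(grp)
        )
        enterprises = [_parse_enterprise(v, pid) for v in grp["landuse"]]
        enterprise = _majority(
            enterprises, weights, list(ENTERPRISE_ORDER) + [Enterprise.NON_MODELLED]
        )
        zones = [_resolve_zone(row, pid) for _, row in grp.iterrows()]
        zone = _majority(zones, weights, ZONE_ORDER)

        parcels.append(
            Parcel(
                parcel_id=pid,
                area_ha=area,
                centroid=centroid,
                zone=zone,
                enterprise=enterprise,
            )
        )

    landscape = Landscape(parcels=parcels)
    if geoms:
        landscape.adjacency = _polygon_adjacency(
            {p.parcel_id: geoms[p.parcel_id] for p in parcels}
        )
    return landscape


def _geojson_to_frame(path: Path) -> tuple[pd.DataFrame, dict[str, object]]:
    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    rows, geoms = [], {}
    for feat in doc.get("features", []):
        props = dict(feat.get("properties") or {})
        pid = str(props.get("parcel_id"))
        rows.append({"parcel_id": pid, **props})
        if feat.get("geometry"):
            geoms[pid] = shape(feat["geometry"])
    return pd.DataFrame(rows), geoms


def _polygon_adjacency(geoms: Mapping[str, object]) -> dict[str, frozenset[str]]:
    """Adjacency from polygon geometry: shared boundary of positive length.

    Corner-only contact (point intersection) does not count.
    """
    ids = sorted(geoms)
    neigh: dict[str, set[str]] = {pid: set() for pid in ids}
    for i, a in enumerate(ids):
        ga = geoms[a]
        for b in ids[i + 1 :]:
            gb = geoms[b]
            if not ga.intersects(gb):
                continue
            if ga.intersection(gb).length > 0:
                neigh[a].add(b)
                neigh[b].add(a)
    return {pid: frozenset(s) for pid, s in neigh.items()}


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_parcels(landscape: Landscape, min_area_ha: float = 100.0) -> Landscape:
    """Keep commercially-modelled farms only.

    Retains parcels strictly larger than ``min_area_ha`` (a 100.0-ha
    parcel is excluded) whose enterprise is one of the three initial
    enterprises; everything else — lifestyle blocks, non-modelled land
    uses — is discarded.
    """
    if min_area_ha <= 0:
        raise ValueError("min_area_ha must be positive")
    kept = [
        p
        for p in landscape.parcels
        if p.area_ha > min_area_ha and p.enterprise in INITIAL_ENTERPRISES
    ]
    removed = len(landscape.parcels) - len(kept)
    if not kept:
        raise ValueError(
            f"no parcels remain after the {min_area_ha} ha / enterprise filter"
        )
    logger.info("filter_parcels: removed %d of %d parcels", removed, len(landscape.parcels))
    out = Landscape(parcels=[replace(p) for p in kept], cell_size_ha=landscape.cell_size_ha)
    if landscape.adjacency is not None:
        keep_ids = {p.parcel_id for p in kept}
        out.adjacency = {
            pid: frozenset(n & keep_ids)
            for pid, n in landscape.adjacency.items()
            if pid in keep_ids
        }
    return out


# ---------------------------------------------------------------------------
# Synthetic landscapes
# ---------------------------------------------------------------------------


def generate_synthetic_landscape(gen_config, seed: int | np.random.Generator) -> Landscape:
    """Generate a synthetic catchment on a 25-ha cell grid.

    The grid is split into three horizontal zone bands (Plains nearest
    the origin, then Foothills, then Hills) and partitioned into
    contiguous parcels by seeded region growing with log-normal target
    sizes truncated below at ``min_cells``.  Each parcel takes the
    majority zone of its cells and an initial enterprise drawn from the
    zone's target shares.  Deterministic for a fixed seed.

    Parameters
    ----------
    gen_config
        A :class:`farmscape.config.GeneratorConfig` (or any object with
        the same attributes).
    seed
        Integer seed or a ``numpy.random.Generator``.
    """
    cfg = gen_config
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_rows, n_cols = cfg.n_rows, cfg.n_cols
    cell_m = math.sqrt(cfg.cell_size_ha * 1e4)

    # zone band per row
    fracs = [cfg.zone_band_fractions[z.value] for z in ZONE_ORDER]
    bounds = np.floor(np.cumsum(fracs) * n_rows).astype(int)
    row_zone = np.empty(n_rows, dtype=np.int8)
    row_zone[: bounds[0]] = 0
    row_zone[bounds[0] : bounds[1]] = 1
    row_zone[bounds[1] :] = 2

    assignment = _region_grow(n_rows, n_cols, cfg, rng)

    n_parcels = assignment.max() + 1
    width = len(str(n_parcels))
    parcels: list[Parcel] = []
    rows_idx, cols_idx = np.divmod(np.arange(n_rows * n_cols), n_cols)
    for k in range(n_parcels):
        mask = assignment.ravel() == k
        rr, cc = rows_idx[mask], cols_idx[mask]
        zone_counts = np.bincount(row_zone[rr], minlength=3)
        zone = ZONE_ORDER[int(np.argmax(zone_counts))]  # ties: most productive wins
        shares = cfg.initial_shares[zone.value]
        labels = sorted(shares, key=lambda lab: ENTERPRISE_ORDER.index(Enterprise(lab)))
        probs = np.array([shares[lab] for lab in labels])
        enterprise = Enterprise(labels[rng.choice(len(labels), p=probs / probs.sum())])
        cx = float((cc.mean() + 0.5) * cell_m)
        cy = float((rr.mean() + 0.5) * cell_m)
        parcels.append(
            Parcel(
                parcel_id=f"p{k:0{width}d}",
                area_ha=float(mask.sum() * cfg.cell_size_ha),
                centroid=(cx, cy),
                zone=zone,
                enterprise=enterprise,
                cells=tuple(zip(rr.tolist(), cc.tolist())),
            )
        )
    landscape = Landscape(parcels=parcels, cell_size_ha=cfg.cell_size_ha)
    landscape.adjacency = build_adjacency(landscape)
    return landscape


def _region_grow(n_rows: int, n_cols: int, cfg, rng: np.random.Generator) -> np.ndarray:
    """Partition the grid into contiguous parcels; returns a cell->parcel map."""
    assignment = np.full((n_rows, n_cols), -1, dtype=np.int64)
    order = rng.permutation(n_rows * n_cols)
    next_id = 0
    for flat in order:
        r, c = divmod(int(flat), n_cols)
        if assignment[r, c] != -1:
            continue
        target = max(
            cfg.min_cells,
            int(round(rng.lognormal(math.log(cfg.mean_cells), cfg.sigma_cells))),
        )
        # BFS over unassigned cells, frontier shuffled for irregular shapes
        assignment[r, c] = next_id
        frontier = deque([(r, c)])
        size = 1
        while frontier and size < target:
            fr, fc = frontier.popleft()
            nbrs = [
                (fr + dr, fc + dc)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= fr + dr < n_rows and 0 <= fc + dc < n_cols
            ]
            rng.shuffle(nbrs)
            for nr, nc in nbrs:
                if size >= target:
                    break
                if assignment[nr, nc] == -1:
                    assignment[nr, nc] = next_id
                    frontier.append((nr, nc))
                    size += 1
        next_id += 1

    # Merge fragments below min_cells into an adjacent parcel (smallest id).
    sizes = np.bincount(assignment.ravel(), minlength=next_id)
    for k in np.where(sizes < cfg.min_cells)[0]:
        cells = np.argwhere(assignment == k)
        neighbours = set()
        for r, c in cells:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < n_rows and 0 <= nc < n_cols and assignment[nr, nc] != k:
                    neighbours.add(int(assignment[nr, nc]))
        if neighbours:
            assignment[assignment == k] = min(neighbours)

    # compact ids
    _, compact = np.unique(assignment, return_inverse=True)
    return compact.reshape(n_rows, n_cols)


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------


def build_adjacency(landscape: Landscape) -> dict[str, frozenset[str]]:
    """Rook-contiguity adjacency: parcels sharing at least one cell edge.

    Corner-only contact does not make neighbours.  Requires parcels to
    carry raster cell memberships (synthetic or cell-level-loaded
    landscapes); polygon inputs get their adjacency at load time.
    """
    if all(p.cells is None for p in landscape.parcels):
        raise ValueError(
            "parcels carry neither cells nor polygons; adjacency unavailable"
        )
    cell_owner: dict[tuple[int, int], str] = {}
    for p in landscape.parcels:
        for cell in p.cells or ():
            cell_owner[cell] = p.parcel_id
    neigh: dict[str, set[str]] = {p.parcel_id: set() for p in landscape.parcels}
    for (r, c), pid in cell_owner.items():
        for dr, dc in ((1, 0), (0, 1)):
            other = cell_owner.get((r + dr, c + dc))
            if other is not None and other != pid:
                neigh[pid].add(other)
                neigh[other].add(pid)
    return {pid: frozenset(s) for pid, s in neigh.items()}
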