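"""Information networks: endorsement and imitation.

Two networks feed each conversion decision.  The *social* network is
the ten closest farmers (centroid Euclidean distance) running the same
enterprise: if the focal farmer's profitability/ha beats the network
mean, conversion likelihood falls by 0.1 (peer endorsement of the
status quo); if it trails, likelihood rises by 0.1.  The *geographic*
network is the adjacent farms currently running the proposed
enterprise: the analogous comparison moves likelihood by ±0.05 —
imitation deliberately carries half the weight of endorsement.  Equal
profitabilities, or an empty network, leave the likelihood untouched,
and both adjustments return 0 when network effects are disabled.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .demography import Farmer
from .landscape import Enterprise, Landscape


def social_network(
    farmer: Farmer,
    population: Mapping[str, Farmer],
    landscape: Landscape,
    k: int = 10,
) -> list[str]:
    """The k closest same-enterprise farmers (farmer ids).

    Distance is Euclidean between parcel centroids; ties break on the
    lower parcel id.  Returns fewer than k when fewer same-enterprise
    farmers exist, possibly none.  Recomputed every step since
    enterprises change.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    focal_parcel = landscape.parcel(farmer.farm_id)
    fx, fy = focal_parcel.centroid
    candidates: list[tuple[float, str, str]] = []
    for parcel in landscape.parcels:
        if parcel.parcel_id == farmer.farm_id:
            continue
        if parcel.enterprise != focal_parcel.enterprise:
            continue
        other = population.get(parcel.parcel_id)
        if other is None:
            continue
        d = math.hypot(parcel.centroid[0] - fx, parcel.centroid[1] - fy)
        candidates.append((d, parcel.parcel_id, other.farmer_id))
    candidates.sort(key=lambda t: (t[0], t[1]))
    return [fid for _, _, fid in candidates[:k]]


def geographic_network(
    farmer: Farmer,
    landscape: Landscape,
    proposed: Enterprise,
    population: Mapping[str, Farmer],
) -> list[str]:
    """Adjacent farms currently running the proposed enterprise.

    Imitation only fires on a proposed change, so the caller passes the
    proposal; the neighbour set may be empty.
    """
    members = []
    for neighbour_id in sorted(landscape.neighbours(farmer.farm_id)):
        if landscape.parcel(neighbour_id).enterprise == proposed:
            other = population.get(neighbour_id)
            if other is not None:
                members.append(other.farmer_id)
    return members


def _comparison_delta(
    own: float, member_profitabilities: Sequence[float], magnitude: float
) -> float:
    if len(member_profitabilities) == 0:
        return 0.0
    mean = float(np.mean(member_profitabilities))
    if own > mean:
        return -magnitude
    if own < mean:
        return +magnitude
    return 0.0


def endorsement_adjustment(
    farmer: Farmer,
    network_members: Iterable[Farmer],
    magnitude: float = 0.1,
    enabled: bool = True,
) -> float:
    """Endorsement delta from the social network: -0.1, 0 or +0.1.

    Members are equally weighted (no stature).  Profitability above the
    network mean endorses the status quo (likelihood down); below it,
    the network signals better practice elsewhere (likelihood up).
    """
    if not enabled:
        return 0.0
    profits = [m.profitability_per_ha for m in network_members]
    return _comparison_delta(farmer.profitability_per_ha, profits, magnitude)


def imitation_adjustment(
    farmer: Farmer,
    members: Iterable[Farmer],
    magnitude: float = 0.05,
    enabled: bool = True,
) -> float:
    """Imitation delta from the geographic network: -0.05, 0 or +0.05.

    Half the endorsement magnitude: passive observation of neighbours
    carries less weight than an active peer network.
    """
    if not enabled:
        return 0.0
    profits = [m.profitability_per_ha for m in members]
    return _comparison_delta(farmer.profitability_per_ha, profits, magnitude)


# ---------------------------------------------------------------------------
# Vectorised helpers used by the engine's step loop
# ---------------------------------------------------------------------------


def k_nearest_same_enterprise(
    dist_row: np.ndarray,
    enterprise_codes: np.ndarray,
    focal: int,
    k: int,
) -> np.ndarray:
    """Indices of the k nearest parcels sharing the focal parcel's
    enterprise code, ties broken on the lower index.

    ``dist_row`` is the focal parcel's row of the pairwise distance
    matrix; parcels are index-ordered by parcel id, so index order is
    id order.
    """
    mask = enterprise_codes == enterprise_codes[focal]
    mask[focal] = False
    cand = np.nonzero(mask)[0]
    if cand.size == 0:
        return cand
    order = np.lexsort((cand, dist_row[cand]))
    return cand[order[:k]]
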