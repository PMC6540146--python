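"""Built-environment exposures: dwelling density, street connectivity, NDAI.

All three attributes are computed for one polygon (a neighbourhood
delineation) at a time:

* dwelling density — occupied dwellings per hectare of residentially
  zoned land, with area-weighted interpolation of meshblock counts for
  polygons that cross meshblock boundaries and exact member sums for
  administrative definitions (whose boundaries align with meshblocks);
* street connectivity — intersections (three or more ways) per km^2;
* NDAI — the neighbourhood destination accessibility index, a weighted
  sum of 8 domain scores over 31 destination types, in [0, 31]: most
  domains score the presence of each destination type, while the
  transport and recreation domains score a saturating density per type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from neighscale.delineation import NeighbourhoodDelineation
from neighscale.synthetic_city import (
    DEFAULT_DOMAIN_TYPES,
    DOMAINS,
    AdminUnitSet,
    DestinationSet,
    StreetNetwork,
    ZoningSet,
)

logger = logging.getLogger(__name__)

DEFAULT_DENSITY_DOMAINS = frozenset({"transport", "recreation"})


@dataclass
class ExposureRecord:
    participant_id: int
    definition: str
    dwelling_density: float  # dwellings per hectare (NaN when undefined)
    connectivity: float  # intersections per km^2
    ndai: float  # score in [0, 31]


@dataclass
class NdaiConfig:
    """Configuration of the destination accessibility index.

    ``domain_types`` allocates the 31 destination types to the 8 domains;
    ``density_domains`` use a per-type saturating density score
    min(1, rate / rho_ref) instead of presence; ``weights`` scale each
    domain's score.  Under unit weights the maximal total is the number of
    types, 31.
    """

    domain_types: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_TYPES)
    )
    density_domains: frozenset[str] = DEFAULT_DENSITY_DOMAINS
    rho_ref: float = 1.0  # reference density, destinations per km^2 per type
    weights: Mapping[str, float] = field(
        default_factory=lambda: {d: 1.0 for d in DOMAINS}
    )
    max_score: float = 31.0

    def __post_init__(self) -> None:
        types = [t for ts in self.domain_types.values() for t in ts]
        if len(types) != len(set(types)):
            raise ValueError("destination types must partition across domains")
        if len(types) != 31:
            raise ValueError(f"expected 31 destination types, got {len(types)}")
        if self.rho_ref <= 0:
            raise ValueError("rho_ref must be positive")
        unknown = self.density_domains - set(self.domain_types)
        if unknown:
            raise ValueError(f"density domains not in domain map: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# dwellings
# ---------------------------------------------------------------------------


def interpolate_dwellings(polygon: Polygon, admin: AdminUnitSet) -> float:
    """Area-weighted dwelling count for an arbitrary polygon.

    Each meshblock contributes its count times the fraction of its area
    intersected by the polygon (uniform-density areal weighting).
    """
    tree, mbs = admin.meshblock_tree()
    idx = tree.query(polygon, predicate="intersects")
    if len(idx) == 0:
        logger.warning("polygon intersects no meshblock; dwelling count 0")
        return 0.0
    total = 0.0
    for i in idx:
        mb = mbs[i]
        inter = polygon.intersection(mb.polygon).area
        if inter > 0 and mb.occupied_dwellings:
            total += mb.occupied_dwellings * inter / mb.polygon.area
    return total


def admin_dwelling_count(unit_id: int, admin: AdminUnitSet) -> float:
    """Exact dwelling count of an administrative unit as a member-meshblock sum."""
    unit = admin.get(unit_id)
    if unit.level == "meshblock":
        return float(unit.occupied_dwellings or 0)
    if unit.level == "study_neighbourhood":
        members = [
            mb for mb in admin.meshblocks() if mb.study_neighbourhood_id == unit_id
        ]
    else:
        members = [mb for mb in admin.meshblocks() if _has_ancestor(mb, unit_id, admin)]
    return float(sum(mb.occupied_dwellings or 0 for mb in members))


def _has_ancestor(mb, unit_id: int, admin: AdminUnitSet) -> bool:
    u = mb
    while u.parent_id is not None:
        if u.parent_id == unit_id:
            return True
        u = admin.get(u.parent_id)
    return False


def dwelling_density(
    polygon: Polygon,
    admin: AdminUnitSet,
    zoning: ZoningSet,
    exact_count: float | None = None,
) -> float:
    """Dwellings per hectare of residential land within ``polygon``.

    ``exact_count`` short-circuits the areal interpolation for
    administrative definitions whose boundaries align with meshblocks.
    Returns NaN (undefined, to be excluded from modelling) when the
    polygon contains no residential land.
    """
    count = exact_count if exact_count is not None else interpolate_dwellings(polygon, admin)
    res_ha = zoning.residential_area_m2(polygon) / 1e4
    if res_ha <= 0:
        logger.warning("polygon has no residential land; dwelling density undefined")
        return float("nan")
    return count / res_ha


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------


def count_intersections(polygon: Polygon, network: StreetNetwork) -> int:
    """Number of >=3-way intersections inside or on the boundary of ``polygon``."""
    import shapely
    from shapely.strtree import STRtree

    nodes = network.intersection_nodes()
    if not nodes:
        return 0
    pts = shapely.points([network.node_xy(n) for n in nodes])
    tree = STRtree(pts)
    return int(len(tree.query(polygon, predicate="covers")))


def _count_intersections_tree(polygon: Polygon, tree) -> int:
    return int(len(tree.query(polygon, predicate="covers")))


def street_connectivity(polygon: Polygon, network: StreetNetwork) -> float:
    """Intersections per square kilometre of the polygon."""
    area_km2 = polygon.area / 1e6
    if area_km2 <= 0:
        raise ValueError("polygon area must be positive")
    return count_intersections(polygon, network) / area_km2


# ---------------------------------------------------------------------------
# NDAI
# ---------------------------------------------------------------------------


def ndai(
    polygon: Polygon,
    destinations: DestinationSet,
    config: NdaiConfig | None = None,
) -> float:
    """Neighbourhood destination accessibility index for a polygon.

    Presence domains contribute one point per destination type present;
    density domains contribute min(1, rate/rho_ref) per type, where rate
    is the type's point density in the polygon.  Domain scores are
    weighted and summed, clipped to [0, max_score].
    """
    config = config or NdaiConfig()
    if len(destinations) == 0:
        return 0.0
    idx = destinations.indices_in(polygon)
    types_in = destinations.dest_type[idx]
    area_km2 = polygon.area / 1e6
    total = 0.0
    for domain, types in config.domain_types.items():
        if domain in config.density_domains and area_km2 > 0:
            score = sum(
                min(1.0, (np.sum(types_in == t) / area_km2) / config.rho_ref)
                for t in types
            )
        else:
            score = sum(1.0 for t in types if np.any(types_in == t))
        total += config.weights.get(domain, 1.0) * score
    return float(np.clip(total, 0.0, config.max_score))


# ---------------------------------------------------------------------------
# batch table
# ---------------------------------------------------------------------------


def exposure_table(
    delineations: Sequence[NeighbourhoodDelineation],
    admin: AdminUnitSet,
    zoning: ZoningSet,
    network: StreetNetwork,
    destinations: DestinationSet,
    config: NdaiConfig | None = None,
) -> pd.DataFrame:
    """One ExposureRecord per delineation, as a DataFrame.

    Administrative definitions (MB/UN/CA) use exact member-meshblock
    dwelling sums; buffers use areal interpolation.  Undefined densities
    (no residential land) are NaN and logged.
    """
    import shapely
    from shapely.strtree import STRtree

    config = config or NdaiConfig()
    nodes = network.intersection_nodes()
    node_tree = STRtree(shapely.points([network.node_xy(n) for n in nodes])) if nodes else None

    # id lookup for exact admin counts: meshblock id by (rounded) polygon
    rows = []
    for rec in delineations:
        if rec.definition in ("MB", "UN", "CA"):
            count = _exact_count_for(rec, admin)
        else:
            count = None
        dens = dwelling_density(rec.polygon, admin, zoning, exact_count=count)
        conn = (
            _count_intersections_tree(rec.polygon, node_tree) / rec.area_km2
            if node_tree is not None
            else 0.0
        )
        score = ndai(rec.polygon, destinations, config)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "definition": rec.definition,
                "dwelling_density": dens,
                "connectivity": conn,
                "ndai": score,
            }
        )
    df = pd.DataFrame(rows)
    n_missing = int(df["dwelling_density"].isna().sum()) if len(df) else 0
    if n_missing:
        logger.warning("%d exposure records with undefined dwelling density", n_missing)
    return df


def _exact_count_for(rec: NeighbourhoodDelineation, admin: AdminUnitSet) -> float | None:
    """Exact member-sum dwelling count for an admin delineation polygon.

    The polygon of an administrative delineation is exactly the unit
    polygon, so the member meshblocks are those fully inside it.
    """
    tree, mbs = admin.meshblock_tree()
    idx = tree.query(rec.polygon, predicate="intersects")
    total = 0.0
    for i in idx:
        mb = mbs[i]
        inter = rec.polygon.intersection(mb.polygon).area
        if inter >= mb.polygon.area * (1 - 1e-9):
            total += float(mb.occupied_dwellings or 0)
    return total


def exposure_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median / range / IQR of each exposure per neighbourhood definition."""
    out = []
    for definition, grp in table.groupby("definition"):
        row: dict[str, object] = {"definition": definition}
        for col in ("dwelling_density", "connectivity", "ndai"):
            vals = grp[col].dropna()
            row[f"{col}_median"] = vals.median()
            row[f"{col}_min"] = vals.min()
            row[f"{col}_max"] = vals.max()
            row[f"{col}_iqr_low"] = vals.quantile(0.25)
            row[f"{col}_iqr_high"] = vals.quantile(0.75)
        out.append(row)
    order = {d: i for i, d in enumerate(("MB", "UN", "CA", "B0500", "B0800", "B1000", "B1500"))}
    df = pd.DataFrame(out)
    return df.sort_values("definition", key=lambda s: s.map(order)).reset_index(drop=True)
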