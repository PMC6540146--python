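"""Synthetic study region and cohort generator.

Emulates the data substrate of an observational built-environment /
physical-activity study set in New Zealand-style suburban cities:

* a grid-like street network with cul-de-sacs and a small motorway share,
* a 4-level administrative hierarchy (meshblock -> census area unit ->
  city, with study neighbourhoods overlaid as unions of meshblocks),
* residential zoning and Poisson dwelling counts,
* destination points in 8 domains / 31 types concentrated in
  high-walkability areas,
* a participant cohort with covariates, and
* outcomes drawn from a known log-linear multilevel model (random
  intercepts for city and for neighbourhood nested in city) so that every
  downstream stage can be validated by parameter recovery.

All coordinates are planar metres; areas are computed directly from the
geometry (no geographic CRS is ever involved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union
from shapely.strtree import STRtree

ROAD_CLASSES = ("street", "motorway", "ramp")
WALKABILITY_CLASSES = ("low", "high", "excluded")

#: destination domains and the default allocation of the 31 destination
#: types across them (types are 1-based; the allocation sums to 31 and is
#: fully overridable through NdaiConfig in the exposures module).
DOMAINS = (
    "education",
    "transport",
    "recreation",
    "social_cultural",
    "food_retail",
    "financial",
    "health",
    "other_retail",
)

DEFAULT_DOMAIN_TYPES: dict[str, tuple[int, ...]] = {
    "education": (1, 2, 3, 4),
    "transport": (5, 6),
    "recreation": (7, 8, 9, 10),
    "social_cultural": (11, 12, 13, 14),
    "food_retail": (15, 16, 17, 18, 19, 20),
    "financial": (21, 22, 23),
    "health": (24, 25, 26, 27),
    "other_retail": (28, 29, 30, 31),
}

TYPE_TO_DOMAIN: dict[int, str] = {
    t: d for d, types in DEFAULT_DOMAIN_TYPES.items() for t in types
}

OUTCOME_NAMES = (
    "walk_transport_min",
    "walk_recreation_min",
    "walk_total_min",
    "mean_counts_per_hour",
    "pct_mvpa",
)

# unit-id blocks per administrative level
_AU_ID0 = 10_000
_UN_ID0 = 20_000
_CITY_ID0 = 30_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class StreetNetwork:
    """Undirected planar street graph with geometric edges.

    Nodes carry ``x``/``y`` coordinates (metres); edges carry ``length``,
    ``road_class`` and a shapely ``geometry`` (a LineString oriented from
    the lower to the higher node id).
    """

    def __init__(self, graph: nx.Graph, extent: tuple[float, float] | None = None):
        self.graph = graph
        if extent is None and graph.number_of_nodes():
            xs = [d["x"] for _, d in graph.nodes(data=True)]
            ys = [d["y"] for _, d in graph.nodes(data=True)]
            extent = (max(xs), max(ys))
        self.extent = extent
        self._edge_tree: STRtree | None = None
        self._edge_keys: list[tuple[int, int]] | None = None

    # -- basic accessors ----------------------------------------------------

    def node_xy(self, node: int) -> tuple[float, float]:
        d = self.graph.nodes[node]
        return (d["x"], d["y"])

    def edge_keys(self) -> list[tuple[int, int]]:
        """Edges as sorted (u, v) tuples in deterministic ascending order."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def edge_geometry(self, key: tuple[int, int]) -> LineString:
        return self.graph.edges[key]["geometry"]

    def edge_length(self, key: tuple[int, int]) -> float:
        return self.graph.edges[key]["length"]

    def intersection_nodes(self) -> list[int]:
        """Nodes with three or more distinct incident edges (true intersections)."""
        return [n for n, deg in self.graph.degree if deg >= 3]

    def edge_tree(self) -> tuple[STRtree, list[tuple[int, int]]]:
        """STRtree over edge geometries (cached), with parallel key list."""
        if self._edge_tree is None:
            self._edge_keys = self.edge_keys()
            geoms = [self.edge_geometry(k) for k in self._edge_keys]
            self._edge_tree = STRtree(geoms)
        return self._edge_tree, self._edge_keys  # type: ignore[return-value]

    def copy(self) -> "StreetNetwork":
        return StreetNetwork(self.graph.copy(), self.extent)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StreetNetwork(nodes={self.graph.number_of_nodes()}, "
            f"edges={self.graph.number_of_edges()})"
        )


@dataclass
class AdminUnit:
    """One administrative polygon at some level of the nesting."""

    unit_id: int
    level: str  # meshblock | area_unit | study_neighbourhood | city
    polygon: Polygon
    parent_id: int | None = None
    # meshblock-level attributes
    occupied_dwellings: int | None = None
    deprivation: int | None = None
    walkability_class: str | None = None
    study_neighbourhood_id: int | None = None
    residential_ha: float | None = None

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6


class AdminUnitSet:
    """Nested administrative units with id-indexed lookup."""

    def __init__(self, units: Iterable[AdminUnit]):
        self.units: list[AdminUnit] = sorted(units, key=lambda u: u.unit_id)
        self._by_id = {u.unit_id: u for u in self.units}
        if len(self._by_id) != len(self.units):
            raise ValueError("duplicate unit_id in AdminUnitSet")
        self._mb_tree: STRtree | None = None
        self._mb_list: list[AdminUnit] | None = None

    def get(self, unit_id: int) -> AdminUnit:
        return self._by_id[unit_id]

    def __contains__(self, unit_id: int) -> bool:
        return unit_id in self._by_id

    def by_level(self, level: str) -> list[AdminUnit]:
        return [u for u in self.units if u.level == level]

    def meshblocks(self) -> list[AdminUnit]:
        return self.by_level("meshblock")

    def cities(self) -> list[AdminUnit]:
        return self.by_level("city")

    def city_of(self, unit: AdminUnit) -> AdminUnit:
        u = unit
        while u.level != "city":
            if u.parent_id is None:
                raise ValueError(f"unit {u.unit_id} has no city ancestor")
            u = self.get(u.parent_id)
        return u

    def add_units(self, units: Iterable[AdminUnit]) -> None:
        for u in units:
            if u.unit_id in self._by_id:
                raise ValueError(f"duplicate unit_id {u.unit_id}")
            self._by_id[u.unit_id] = u
            self.units.append(u)
        self.units.sort(key=lambda u: u.unit_id)

    def meshblock_tree(self) -> tuple[STRtree, list[AdminUnit]]:
        """STRtree over meshblock polygons, cached; parallel unit list."""
        if self._mb_tree is None:
            self._mb_list = self.meshblocks()
            self._mb_tree = STRtree([u.polygon for u in self._mb_list])
        return self._mb_tree, self._mb_list  # type: ignore[return-value]

    def invalidate_caches(self) -> None:
        self._mb_tree = None
        self._mb_list = None


@dataclass
class ZoningSet:
    """Land-use polygons tagged residential / non_residential."""

    polygons: list[tuple[Polygon, str]]

    def __post_init__(self) -> None:
        self._res_tree: STRtree | None = None
        self._res_geoms: list[Polygon] | None = None

    def residential_polygons(self) -> list[Polygon]:
        return [p for p, kind in self.polygons if kind == "residential"]

    def residential_tree(self) -> tuple[STRtree, list[Polygon]]:
        if self._res_tree is None:
            self._res_geoms = self.residential_polygons()
            self._res_tree = STRtree(self._res_geoms)
        return self._res_tree, self._res_geoms  # type: ignore[return-value]

    def residential_area_m2(self, polygon: Polygon) -> float:
        """Area of ``polygon`` ∩ residential zoning, in square metres."""
        tree, geoms = self.residential_tree()
        idx = tree.query(polygon, predicate="intersects")
        total = 0.0
        for i in idx:
            total += polygon.intersection(geoms[i]).area
        return total


class DestinationSet:
    """Typed destination points (31 types across 8 domains)."""

    def __init__(
        self,
        xy: np.ndarray,
        dest_type: np.ndarray,
        type_to_domain: Mapping[int, str] | None = None,
    ):
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        dest_type = np.asarray(dest_type, dtype=int)
        if len(xy) != len(dest_type):
            raise ValueError("xy and dest_type length mismatch")
        self.xy = xy
        self.dest_type = dest_type
        self.type_to_domain = dict(type_to_domain or TYPE_TO_DOMAIN)
        domains = set(self.type_to_domain.values())
        if not domains <= set(DOMAINS):
            raise ValueError(f"unknown domains {domains - set(DOMAINS)}")
        bad = set(np.unique(dest_type)) - set(self.type_to_domain)
        if bad:
            raise ValueError(f"dest_type values with no domain mapping: {sorted(bad)}")
        self.dest_id = np.arange(len(dest_type))
        self._points: np.ndarray | None = None
        self._tree: STRtree | None = None

    def __len__(self) -> int:
        return len(self.dest_type)

    @property
    def domain(self) -> np.ndarray:
        return np.array([self.type_to_domain[t] for t in self.dest_type])

    def points(self) -> np.ndarray:
        if self._points is None:
            self._points = shapely.points(self.xy)
        return self._points

    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree(self.points())
        return self._tree

    def indices_in(self, polygon: Polygon) -> np.ndarray:
        """Indices of destinations inside or on the boundary of ``polygon``."""
        if len(self) == 0:
            return np.empty(0, dtype=int)
        idx = self.tree().query(polygon, predicate="covers")
        return np.sort(idx)


@dataclass
class Participant:
    participant_id: int
    home: Point
    sex: str
    age: float
    ethnicity: str
    income: str
    marital: str
    education: str
    employment: str
    car_access: bool
    preference: int  # 1 (strongly prefer walkable) .. 5 (strongly prefer less walkable)
    city_id: int
    study_neighbourhood_id: int


@dataclass
class TrueModelParams:
    """Ground-truth parameters of the outcome-generating multilevel model.

    The model on the log scale is

        log(y + 1) = alpha + beta * x + gamma' z + u_city + u_nbhd + eps

    with independent Gaussian random intercepts u_city ~ N(0, sigma2_city),
    u_nbhd ~ N(0, sigma2_nbhd) and residual eps ~ N(0, sigma2_resid);
    y = exp(.) - 1 truncated at zero.  ``alpha`` may be a single intercept
    or a per-outcome mapping; ``gamma`` maps covariate design columns
    (see :func:`covariate_design`) to coefficients.
    """

    alpha: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALPHAS)
    )
    beta: float = 0.05
    gamma: Mapping[str, float] = field(
        default_factory=lambda: {"age_c": -0.05, "female": -0.08, "car_access": 0.10}
    )
    sigma2_city: float = 0.02
    sigma2_nbhd: float = 0.05
    sigma2_resid: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_city", "sigma2_nbhd", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def alpha_for(self, outcome: str) -> float:
        if isinstance(self.alpha, Mapping):
            return float(self.alpha[outcome])
        return float(self.alpha)


#: default per-outcome intercepts on the log(y+1) scale, placed so that the
#: implied outcome medians resemble a suburban adult cohort (about 40 min/wk
#: transport walking, 30 min/wk recreation walking, 8000 counts/h, 12% MVPA).
DEFAULT_ALPHAS: dict[str, float] = {
    "walk_transport_min": 3.7,
    "walk_recreation_min": 3.4,
    "walk_total_min": 4.6,  # used only when totals are simulated directly
    "mean_counts_per_hour": 9.0,
    "pct_mvpa": 2.5,
}


@dataclass
class OutcomeRecord:
    participant_id: int
    walk_transport_min: float
    walk_recreation_min: float
    walk_total_min: float
    mean_counts_per_hour: float
    pct_mvpa: float

    def __post_init__(self) -> None:
        vals = [
            self.walk_transport_min,
            self.walk_recreation_min,
            self.walk_total_min,
            self.mean_counts_per_hour,
            self.pct_mvpa,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError("outcome values must be finite")
        if self.walk_total_min < max(self.walk_transport_min, self.walk_recreation_min) - 1e-9:
            raise ValueError("walk_total_min below a component walk outcome")


# ---------------------------------------------------------------------------
# street network generation
# ---------------------------------------------------------------------------


def generate_street_network(
    extent: tuple[float, float],
    spacing: float,
    culdesac_rate: float = 0.0,
    motorway_fraction: float = 0.0,
    seed: int = 0,
) -> StreetNetwork:
    """Generate a grid street network with cul-de-sacs and motorway edges.

    A regular grid with the given node ``spacing`` is laid over ``extent``;
    ``culdesac_rate`` of the interior edges are then removed (never
    disconnecting the graph), which produces dead ends, and
    ``motorway_fraction`` of the remaining edges are tagged as motorway
    (again guarded so the pedestrian subgraph stays connected).
    """
    width, height = extent
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not (0 <= culdesac_rate <= 1 and 0 <= motorway_fraction <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if width < 2 * spacing or height < 2 * spacing:
        raise ValueError("degenerate network: extent smaller than 2x spacing")

    ncols = int(math.floor(width / spacing + 1e-9)) + 1
    nrows = int(math.floor(height / spacing + 1e-9)) + 1
    rng = np.random.default_rng(seed)

    g = nx.Graph()
    for r in range(nrows):
        for c in range(ncols):
            g.add_node(r * ncols + c, x=c * spacing, y=r * spacing)

    def _add_edge(u: int, v: int) -> None:
        u, v = min(u, v), max(u, v)
        geom = LineString([(g.nodes[u]["x"], g.nodes[u]["y"]), (g.nodes[v]["x"], g.nodes[v]["y"])])
        g.add_edge(u, v, length=geom.length, road_class="street", geometry=geom)

    for r in range(nrows):
        for c in range(ncols):
            n = r * ncols + c
            if c + 1 < ncols:
                _add_edge(n, n + 1)
            if r + 1 < nrows:
                _add_edge(n, n + ncols)

    def _interior(n: int) -> bool:
        r, c = divmod(n, ncols)
        return 0 < r < nrows - 1 and 0 < c < ncols - 1

    interior_edges = sorted(
        (min(u, v), max(u, v)) for u, v in g.edges if _interior(u) and _interior(v)
    )
    n_remove = int(round(culdesac_rate * len(interior_edges)))
    # spatially clustered removal: a smooth random field biases which edges
    # go, so cul-de-sac-rich (low-connectivity) pockets emerge, as in real
    # suburbs, rather than uniformly sprinkled dead ends
    bias = ndimage.gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=3.0, mode="nearest")
    bias = (bias - bias.mean()) / (bias.std() or 1.0)

    def _edge_weight(e: tuple[int, int]) -> float:
        r1, c1 = divmod(e[0], ncols)
        r2, c2 = divmod(e[1], ncols)
        return math.exp(1.5 * (bias[r1, c1] + bias[r2, c2]) / 2.0)

    keys = rng.random(len(interior_edges))
    order = np.argsort(
        [-(k ** (1.0 / _edge_weight(e))) for k, e in zip(keys, interior_edges)]
    )
    removed = 0
    for i in order:
        if removed >= n_remove:
            break
        u, v = interior_edges[i]
        data = g.edges[u, v]
        g.remove_edge(u, v)
        if nx.has_path(g, u, v):
            removed += 1
        else:
            g.add_edge(u, v, **data)

    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges)
    n_mw = int(round(motorway_fraction * len(edges)))
    order = rng.permutation(len(edges))
    tagged = 0
    pedestrian = g.copy()
    for i in order:
        if tagged >= n_mw:
            break
        u, v = edges[i]
        data = pedestrian.edges[u, v]
        pedestrian.remove_edge(u, v)
        # keep the walking network connected on its non-isolated nodes
        ok = (pedestrian.degree(u) == 0 or pedestrian.degree(v) == 0) or nx.has_path(
            pedestrian, u, v
        )
        if ok:
            g.edges[u, v]["road_class"] = "motorway"
            tagged += 1
        else:
            pedestrian.add_edge(u, v, **data)

    return StreetNetwork(g, extent=(width, height))


# ---------------------------------------------------------------------------
# administrative units, zoning, dwellings
# ---------------------------------------------------------------------------


def generate_admin_units(
    network: StreetNetwork,
    mb_cell: float,
    seed: int = 0,
    target_density: float = 10.0,
    density_field_sd: float = 0.35,
    density_local_sd: float = 0.5,
    res_frac_range: tuple[float, float] = (0.5, 0.9),
    au_cells: int = 5,
) -> tuple[AdminUnitSet, ZoningSet]:
    """Tile the network extent into meshblocks, area units and cities.

    Meshblocks are ``mb_cell`` x ``mb_cell`` squares (0.050 km^2 at the
    default cell of 224 m, matching a typical urban meshblock).  They are
    aggregated into area units of roughly ``au_cells``^2 meshblocks and the
    area-unit grid is split into quadrant cities (4 where the grid allows,
    2 otherwise).  Each meshblock receives a residential zoning rectangle
    covering 50-90% of its area and a Poisson dwelling count with mean
    equal to a spatially smooth target density (dwellings/ha, lognormal
    around ``target_density``) times its residential hectares.
    """
    if network.extent is None:
        raise ValueError("network has no extent")
    width, height = network.extent
    ncx = width / mb_cell
    ncy = height / mb_cell
    if abs(ncx - round(ncx)) > 1e-9 or abs(ncy - round(ncy)) > 1e-9:
        raise ValueError("mb_cell must divide the network extent")
    ncx, ncy = int(round(ncx)), int(round(ncy))
    rng = np.random.default_rng(seed)

    # area-unit grid and quadrant cities
    nax = max(1, math.ceil(ncx / au_cells))
    nay = max(1, math.ceil(ncy / au_cells))
    if nax < 2 and nay < 2:
        raise ValueError("extent too small to form at least two cities")
    split_x = nax // 2 if nax >= 2 else 1
    split_y = nay // 2 if nay >= 2 else 1

    def _city_index(ac: int, ar: int) -> int:
        cx = int(ac >= split_x) if nax >= 2 else 0
        cy = int(ar >= split_y) if nay >= 2 else 0
        return cy * (2 if nax >= 2 else 1) + cx

    # spatially smooth log-density and deprivation fields over the cell grid
    dens_field = ndimage.gaussian_filter(rng.standard_normal((ncy, ncx)), sigma=2.0, mode="nearest")
    dens_field = (dens_field - dens_field.mean()) / (dens_field.std() or 1.0)
    # smooth field (walkable pockets) plus meshblock-level idiosyncrasy:
    # adjacent meshblocks differ substantially in realized density, as in
    # census data, while the neighbourhood-scale mean varies smoothly
    local = rng.standard_normal((ncy, ncx))
    cell_density = np.exp(
        np.log(target_density) + density_field_sd * dens_field + density_local_sd * local
    )

    depr_field = ndimage.gaussian_filter(rng.standard_normal((ncy, ncx)), sigma=2.0, mode="nearest")
    ranks = depr_field.flatten().argsort().argsort()
    deprivation = 1 + (ranks * 10) // ranks.size  # deciles 1..10
    deprivation = deprivation.reshape(ncy, ncx)

    res_frac = rng.uniform(*res_frac_range, size=(ncy, ncx))

    units: list[AdminUnit] = []
    zoning: list[tuple[Polygon, str]] = []
    au_ids_used: dict[int, int] = {}
    city_members: dict[int, list[int]] = {}

    for r in range(ncy):
        for c in range(ncx):
            mb_id = r * ncx + c
            x0, y0 = c * mb_cell, r * mb_cell
            cell = box(x0, y0, x0 + mb_cell, y0 + mb_cell)
            ac, ar = c // au_cells, r // au_cells
            au_id = _AU_ID0 + ar * nax + ac
            city_id = _CITY_ID0 + _city_index(ac, ar)
            au_ids_used[au_id] = city_id
            city_members.setdefault(city_id, []).append(mb_id)

            frac = res_frac[r, c]
            side_x = mb_cell * math.sqrt(frac)
            side_y = side_x
            cx0 = x0 + (mb_cell - side_x) / 2
            cy0 = y0 + (mb_cell - side_y) / 2
            res_poly = box(cx0, cy0, cx0 + side_x, cy0 + side_y)
            res_ha = res_poly.area / 1e4
            dwellings = int(rng.poisson(cell_density[r, c] * res_ha))

            units.append(
                AdminUnit(
                    unit_id=mb_id,
                    level="meshblock",
                    polygon=cell,
                    parent_id=au_id,
                    occupied_dwellings=dwellings,
                    deprivation=int(deprivation[r, c]),
                    residential_ha=res_ha,
                )
            )
            zoning.append((res_poly, "residential"))
            nonres = cell.difference(res_poly)
            if not nonres.is_empty:
                zoning.append((nonres, "non_residential"))

    for au_id, city_id in sorted(au_ids_used.items()):
        k = au_id - _AU_ID0
        ar, ac = divmod(k, nax)
        x0 = ac * au_cells * mb_cell
        y0 = ar * au_cells * mb_cell
        poly = box(x0, y0, min(x0 + au_cells * mb_cell, width), min(y0 + au_cells * mb_cell, height))
        units.append(AdminUnit(unit_id=au_id, level="area_unit", polygon=poly, parent_id=city_id))

    for city_id, members in sorted(city_members.items()):
        poly = unary_union([units[m].polygon for m in members])
        units.append(AdminUnit(unit_id=city_id, level="city", polygon=poly, parent_id=None))

    return AdminUnitSet(units), ZoningSet(zoning)


# ---------------------------------------------------------------------------
# walkability classification and study-neighbourhood selection
# ---------------------------------------------------------------------------


def meshblock_intersection_density(
    admin: AdminUnitSet, network: StreetNetwork
) -> dict[int, float]:
    """Intersections (>= 3 ways) per km^2 for every meshblock (inclusive boundary)."""
    nodes = network.intersection_nodes()
    pts = shapely.points([network.node_xy(n) for n in nodes]) if nodes else []
    tree = STRtree(pts) if nodes else None
    out: dict[int, float] = {}
    for mb in admin.meshblocks():
        count = len(tree.query(mb.polygon, predicate="covers")) if tree is not None else 0
        out[mb.unit_id] = count / mb.area_km2
    return out


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def assign_walkability_and_select(
    admin: AdminUnitSet,
    network: StreetNetwork,
    n_neigh_per_class: int = 6,
    min_contiguous: int = 5,
) -> AdminUnitSet:
    """Classify meshblocks into walkability tertiles and select study neighbourhoods.

    The surrogate walkability score is the mean of the z-scored dwelling
    density and z-scored intersection density of each meshblock, computed
    within its city.  Meshblocks in the top/bottom tertile are classed
    high/low; the middle tertile is excluded.  Study neighbourhoods are the
    largest connected components (shared-boundary adjacency) of at least
    ``min_contiguous`` same-class meshblocks, up to ``n_neigh_per_class``
    per class per city.  Ties are broken by unit_id for determinism.
    """
    int_dens = meshblock_intersection_density(admin, network)
    new_neigh: list[AdminUnit] = []
    un_counter = _UN_ID0

    for city in admin.cities():
        mbs = [
            mb
            for mb in admin.meshblocks()
            if admin.city_of(mb).unit_id == city.unit_id
        ]
        if len(mbs) < 3:
            raise ValueError("need at least 3 meshblocks per city")
        ids = np.array([mb.unit_id for mb in mbs])
        dens = np.array(
            [
                (mb.occupied_dwellings or 0) / mb.residential_ha if mb.residential_ha else 0.0
                for mb in mbs
            ]
        )
        score = (_zscore(dens) + _zscore(np.array([int_dens[i] for i in ids]))) / 2.0
        order = np.lexsort((ids, score))  # ascending score, ties by unit_id
        n = len(mbs)
        t1, t2 = n // 3, n - n // 3
        classes = {}
        for pos, idx in enumerate(order):
            if pos < t1:
                classes[ids[idx]] = "low"
            elif pos < t2:
                classes[ids[idx]] = "excluded"
            else:
                classes[ids[idx]] = "high"
        for mb in mbs:
            mb.walkability_class = classes[mb.unit_id]

        # contiguity graph (rook adjacency via shared boundaries)
        polys = [mb.polygon for mb in mbs]
        tree = STRtree(polys)
        for klass in ("low", "high"):
            sub = nx.Graph()
            members = [mb for mb in mbs if mb.walkability_class == klass]
            sub.add_nodes_from(mb.unit_id for mb in members)
            member_idx = {mb.unit_id for mb in members}
            for mb in members:
                for j in tree.query(mb.polygon, predicate="intersects"):
                    other = mbs[j]
                    if other.unit_id <= mb.unit_id or other.unit_id not in member_idx:
                        continue
                    inter = mb.polygon.intersection(other.polygon)
                    if inter.length > 0:  # shared edge, not a corner touch
                        sub.add_edge(mb.unit_id, other.unit_id)
            comps = [sorted(c) for c in nx.connected_components(sub) if len(c) >= min_contiguous]
            if not comps:
                raise ValueError(
                    f"selection infeasible: no contiguous {klass}-walkability "
                    f"component of >= {min_contiguous} meshblocks in city {city.unit_id}"
                )
            comps.sort(key=lambda c: (-len(c), c[0]))
            for comp in comps[:n_neigh_per_class]:
                poly = unary_union([admin.get(i).polygon for i in comp])
                new_neigh.append(
                    AdminUnit(
                        unit_id=un_counter,
                        level="study_neighbourhood",
                        polygon=poly,
                        parent_id=city.unit_id,
                        walkability_class=klass,
                    )
                )
                for i in comp:
                    admin.get(i).study_neighbourhood_id = un_counter
                un_counter += 1

    admin.add_units(new_neigh)
    admin.invalidate_caches()
    return admin


# ---------------------------------------------------------------------------
# destinations
# ---------------------------------------------------------------------------

DEFAULT_INTENSITY_BY_CLASS: dict[str | None, float] = {
    "high": 14.0,  # destinations per km^2 in high-walkability meshblocks
    "low": 4.0,
    "excluded": 7.0,
    None: 7.0,
}


def generate_destinations(
    admin: AdminUnitSet,
    intensity_by_class: Mapping[str | None, float] | None = None,
    seed: int = 0,
    type_probs: Sequence[float] | None = None,
) -> DestinationSet:
    """Marked Poisson destination process over meshblocks.

    Each meshblock receives Poisson(intensity * area_km2) points placed
    uniformly within it, with intensity depending on its walkability class;
    destination types 1..31 are drawn from ``type_probs`` (uniform by
    default) and mapped to domains through the default allocation.
    """
    rates = dict(DEFAULT_INTENSITY_BY_CLASS)
    if intensity_by_class is not None:
        rates.update(intensity_by_class)
    if any(v < 0 for v in rates.values()):
        raise ValueError("intensities must be non-negative")
    if type_probs is None:
        probs = np.full(31, 1 / 31)
    else:
        probs = np.asarray(type_probs, dtype=float)
        if probs.shape != (31,) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("type_probs must be 31 probabilities summing to 1")

    rng = np.random.default_rng(seed)
    xs: list[np.ndarray] = []
    types: list[np.ndarray] = []
    for mb in admin.meshblocks():
        lam = rates.get(mb.walkability_class, rates[None]) * mb.area_km2
        k = int(rng.poisson(lam))
        if k == 0:
            continue
        pts = _uniform_points_in(mb.polygon, k, rng)
        xs.append(pts)
        types.append(rng.choice(np.arange(1, 32), size=k, p=probs))
    if xs:
        xy = np.vstack(xs)
        dest_type = np.concatenate(types)
    else:
        xy = np.empty((0, 2))
        dest_type = np.empty(0, dtype=int)
    return DestinationSet(xy, dest_type)


def _uniform_points_in(polygon: Polygon, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection sampling in its bbox."""
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((k, 2))
    got = 0
    while got < k:
        m = max(4 * (k - got), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        mask = shapely.contains_xy(polygon, cand[:, 0], cand[:, 1])
        take = cand[mask][: k - got]
        out[got : got + len(take)] = take
        got += len(take)
    return out


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

_COVARIATE_LEVELS = {
    "sex": (("female", "male"), (0.55, 0.45)),
    "ethnicity": (
        ("nz_european", "maori", "pacific", "asian", "other"),
        (0.60, 0.14, 0.08, 0.12, 0.06),
    ),
    "income": (("low", "medium", "high", "not_stated"), (0.25, 0.40, 0.25, 0.10)),
    "marital": (("partnered", "single", "other"), (0.60, 0.30, 0.10)),
    "education": (("secondary", "trade", "degree"), (0.40, 0.30, 0.30)),
    "employment": (("fulltime", "parttime", "not_employed"), (0.55, 0.20, 0.25)),
}


def generate_participants(
    admin: AdminUnitSet, n: int, seed: int = 0
) -> list[Participant]:
    """Draw a participant cohort residing in the selected study neighbourhoods.

    Residence is dwelling-weighted: a study neighbourhood is sampled in
    proportion to its occupied dwellings, then a member meshblock again by
    dwellings, then a uniform point within that meshblock.  This emulates
    household-based recruitment (participants live where dwellings are),
    which places the cohort's local dwelling density above the regional
    average, as observed in household surveys.  Ages are uniform on
    [20, 65]; categorical covariates follow fixed marginal distributions
    typical of an urban adult cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    neigh = admin.by_level("study_neighbourhood")
    if not neigh:
        raise ValueError("no selected study neighbourhoods; run walkability selection first")
    rng = np.random.default_rng(seed)
    members = {
        u.unit_id: [
            m for m in admin.meshblocks() if m.study_neighbourhood_id == u.unit_id
        ]
        for u in neigh
    }
    weights = np.array(
        [sum(m.occupied_dwellings or 0 for m in members[u.unit_id]) for u in neigh],
        dtype=float,
    )
    if weights.sum() <= 0:
        weights = np.array([u.polygon.area for u in neigh])
    probs = weights / weights.sum()
    choice = rng.choice(len(neigh), size=n, p=probs)

    participants: list[Participant] = []
    for pid in range(n):
        nb = neigh[choice[pid]]
        mbs = members[nb.unit_id]
        w = np.array([m.occupied_dwellings or 0 for m in mbs], dtype=float)
        if w.sum() <= 0:
            w = np.array([m.polygon.area for m in mbs])
        mb = mbs[rng.choice(len(mbs), p=w / w.sum())]
        xy = _uniform_points_in(mb.polygon, 1, rng)[0]
        draws = {
            name: levels[rng.choice(len(levels), p=np.array(p))]
            for name, (levels, p) in _COVARIATE_LEVELS.items()
        }
        participants.append(
            Participant(
                participant_id=pid,
                home=Point(xy),
                sex=draws["sex"],
                age=float(np.round(rng.uniform(20, 65), 1)),
                ethnicity=draws["ethnicity"],
                income=draws["income"],
                marital=draws["marital"],
                education=draws["education"],
                employment=draws["employment"],
                car_access=bool(rng.random() < 0.85),
                preference=int(rng.choice([1, 2, 3, 4, 5], p=[0.2, 0.3, 0.25, 0.15, 0.1])),
                city_id=nb.parent_id,
                study_neighbourhood_id=nb.unit_id,
            )
        )
    return participants


def participants_frame(
    participants: Sequence[Participant], admin: AdminUnitSet | None = None
) -> "pd.DataFrame":
    """Participant covariate table; adds meshblock deprivation if admin given."""
    import pandas as pd

    rows = []
    for p in participants:
        rows.append(
            {
                "participant_id": p.participant_id,
                "home_x": p.home.x,
                "home_y": p.home.y,
                "sex": p.sex,
                "age": p.age,
                "ethnicity": p.ethnicity,
                "income": p.income,
                "marital": p.marital,
                "education": p.education,
                "employment": p.employment,
                "car_access": p.car_access,
                "preference": p.preference,
                "city_id": p.city_id,
                "study_neighbourhood_id": p.study_neighbourhood_id,
            }
        )
    df = pd.DataFrame(rows)
    if admin is not None and len(df):
        tree, mbs = admin.meshblock_tree()
        depr = np.full(len(df), np.nan)
        pts = shapely.points(df[["home_x", "home_y"]].to_numpy())
        for i, pt in enumerate(pts):
            idx = tree.query(pt, predicate="within")
            if len(idx) == 0:
                idx = tree.query(pt, predicate="intersects")
            if len(idx):
                mb = min((mbs[j] for j in idx), key=lambda m: m.unit_id)
                depr[i] = mb.deprivation
        df["deprivation"] = depr
    return df


# ---------------------------------------------------------------------------
# outcome simulation
# ---------------------------------------------------------------------------


def covariate_design(participants: Sequence[Participant]) -> "pd.DataFrame":
    """Numeric covariate encoding used by the true outcome model.

    Columns: ``age_c`` (age in decades centred at 42.5), ``female`` and
    ``car_access`` indicators.  The fitted models adjust for the full
    categorical covariate set; covariates absent here simply have zero
    true effect.
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "age_c": [(p.age - 42.5) / 10 for p in participants],
            "female": [1.0 if p.sex == "female" else 0.0 for p in participants],
            "car_access": [1.0 if p.car_access else 0.0 for p in participants],
        },
        index=[p.participant_id for p in participants],
    )


def simulate_outcomes(
    participants: Sequence[Participant],
    exposures: Mapping[int, float],
    params: TrueModelParams,
) -> list[OutcomeRecord]:
    """Simulate the five physical-activity outcomes from the true model.

    Each outcome is drawn independently from
    ``log(y+1) = alpha_o + beta x + gamma' z + u_city + u_nbhd + eps`` with
    fresh random intercepts per outcome; ``y = exp(.) - 1`` truncated at 0
    and percent MVPA clipped to 100.  Total walking is rebuilt as
    transport + recreation + non-negative noise so the component ordering
    invariant holds by construction.
    """
    rng = np.random.default_rng(params.seed)
    n = len(participants)
    x = np.array([float(exposures[p.participant_id]) for p in participants])
    z = covariate_design(participants)
    gz = np.zeros(n)
    for name, coef in params.gamma.items():
        gz += coef * z[name].to_numpy()

    cities = sorted({p.city_id for p in participants})
    neighs = sorted({p.study_neighbourhood_id for p in participants})
    ci = np.array([cities.index(p.city_id) for p in participants])
    ni = np.array([neighs.index(p.study_neighbourhood_id) for p in participants])

    sims: dict[str, np.ndarray] = {}
    for outcome in OUTCOME_NAMES:
        if outcome == "walk_total_min":
            continue
        u_city = rng.normal(0, math.sqrt(params.sigma2_city), len(cities))
        u_nb = rng.normal(0, math.sqrt(params.sigma2_nbhd), len(neighs))
        eps = rng.normal(0, math.sqrt(params.sigma2_resid), n)
        eta = params.alpha_for(outcome) + params.beta * x + gz + u_city[ci] + u_nb[ni] + eps
        y = np.maximum(np.exp(eta) - 1.0, 0.0)
        if outcome == "pct_mvpa":
            y = np.minimum(y, 100.0)
        sims[outcome] = y

    total = (
        sims["walk_transport_min"]
        + sims["walk_recreation_min"]
        + np.abs(rng.normal(0, 5.0, n))
    )
    sims["walk_total_min"] = total

    return [
        OutcomeRecord(
            participant_id=p.participant_id,
            walk_transport_min=float(sims["walk_transport_min"][i]),
            walk_recreation_min=float(sims["walk_recreation_min"][i]),
            walk_total_min=float(sims["walk_total_min"][i]),
            mean_counts_per_hour=float(sims["mean_counts_per_hour"][i]),
            pct_mvpa=float(sims["pct_mvpa"][i]),
        )
        for i, p in enumerate(participants)
    ]


def outcomes_frame(records: Sequence[OutcomeRecord]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# accelerometer epoch profiles
# ---------------------------------------------------------------------------

EPOCHS_PER_HOUR = 120  # 30-s epochs

#: counts per 30-s epoch for the two anchor activity profiles: light
#: housework (~10 counts/min) and continuous vigorous sport (~4700/min).
PROFILE_COUNTS = {"dishwashing": 5, "basketball": 2350}


def generate_epoch_series(
    profile: str, duration_hours: float, seed: int = 0
) -> np.ndarray:
    """Generate a 30-s epoch count series for a named activity profile.

    ``dishwashing`` and ``basketball`` emit constant counts (5 and 2350 per
    epoch); ``nonwear_block`` emits zeros; ``mixed`` concatenates seeded
    random segments of the three.
    """
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_hours * EPOCHS_PER_HOUR))
    if profile in PROFILE_COUNTS:
        return np.full(n, PROFILE_COUNTS[profile], dtype=int)
    if profile == "nonwear_block":
        return np.zeros(n, dtype=int)
    if profile == "mixed":
        rng = np.random.default_rng(seed)
        out = np.empty(0, dtype=int)
        kinds = ("dishwashing", "basketball", "nonwear_block")
        while len(out) < n:
            kind = kinds[rng.integers(0, 3)]
            seg_len = int(rng.integers(10, 240))
            if kind == "nonwear_block":
                seg = np.zeros(seg_len, dtype=int)
            else:
                seg = np.full(seg_len, PROFILE_COUNTS[kind], dtype=int)
            out = np.concatenate([out, seg])
        return out[:n]
    raise ValueError(f"unknown profile {profile!r}")
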