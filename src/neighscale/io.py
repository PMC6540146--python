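"""Readers and writers for the package's layer formats.

Vector layers (street network, administrative units, zoning,
destinations, delineations) are exchanged as GeoJSON FeatureCollections
with all attributes in feature properties; tabular data (participants,
outcomes, exposures) as CSV; model parameters as YAML.  Coordinates are
planar metres throughout (a local metric CRS), not longitude/latitude.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
import yaml
from shapely.geometry import Point, mapping, shape

from neighscale.delineation import NeighbourhoodDelineation
from neighscale.synthetic_city import (
    AdminUnit,
    AdminUnitSet,
    DestinationSet,
    Participant,
    StreetNetwork,
    TrueModelParams,
    ZoningSet,
)


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh)
    return path


# ---------------------------------------------------------------------------
# street network
# ---------------------------------------------------------------------------


def write_network_geojson(network: StreetNetwork, path: str | Path) -> Path:
    features = []
    for key in network.edge_keys():
        data = network.graph.edges[key]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(data["geometry"]),
                "properties": {
                    "node_a": key[0],
                    "node_b": key[1],
                    "length": data["length"],
                    "road_class": data["road_class"],
                },
            }
        )
    return _write_json(_feature_collection(features), path)


def read_network_geojson(path: str | Path) -> StreetNetwork:
    with open(path) as fh:
        fc = json.load(fh)
    g = nx.Graph()
    for feat in fc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        a, b = int(props["node_a"]), int(props["node_b"])
        (xa, ya), (xb, yb) = geom.coords[0], geom.coords[-1]
        g.add_node(a, x=xa, y=ya)
        g.add_node(b, x=xb, y=yb)
        g.add_edge(a, b, length=float(props["length"]), road_class=props["road_class"], geometry=geom)
    return StreetNetwork(g)


# ---------------------------------------------------------------------------
# administrative units and zoning
# ---------------------------------------------------------------------------


def write_admin_geojson(admin: AdminUnitSet, path: str | Path) -> Path:
    features = []
    for u in admin.units:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(u.polygon),
                "properties": {
                    "unit_id": u.unit_id,
                    "level": u.level,
                    "parent_id": u.parent_id,
                    "occupied_dwellings": u.occupied_dwellings,
                    "deprivation": u.deprivation,
                    "walkability_class": u.walkability_class,
                    "study_neighbourhood_id": u.study_neighbourhood_id,
                    "residential_ha": u.residential_ha,
                },
            }
        )
    return _write_json(_feature_collection(features), path)


def read_admin_geojson(path: str | Path) -> AdminUnitSet:
    with open(path) as fh:
        fc = json.load(fh)
    units = []
    for feat in fc["features"]:
        p = feat["properties"]
        units.append(
            AdminUnit(
                unit_id=int(p["unit_id"]),
                level=p["level"],
                polygon=shape(feat["geometry"]),
                parent_id=None if p.get("parent_id") is None else int(p["parent_id"]),
                occupied_dwellings=p.get("occupied_dwellings"),
                deprivation=p.get("deprivation"),
                walkability_class=p.get("walkability_class"),
                study_neighbourhood_id=p.get("study_neighbourhood_id"),
                residential_ha=p.get("residential_ha"),
            )
        )
    return AdminUnitSet(units)


def write_zoning_geojson(zoning: ZoningSet, path: str | Path) -> Path:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"kind": kind},
        }
        for poly, kind in zoning.polygons
    ]
    return _write_json(_feature_collection(features), path)


def read_zoning_geojson(path: str | Path) -> ZoningSet:
    with open(path) as fh:
        fc = json.load(fh)
    return ZoningSet(
        [(shape(f["geometry"]), f["properties"]["kind"]) for f in fc["features"]]
    )


# ---------------------------------------------------------------------------
# destinations
# ---------------------------------------------------------------------------


def write_destinations_geojson(dest: DestinationSet, path: str | Path) -> Path:
    domains = dest.domain
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(dest.xy[i])},
            "properties": {
                "dest_id": int(dest.dest_id[i]),
                "dest_type": int(dest.dest_type[i]),
                "domain": domains[i],
            },
        }
        for i in range(len(dest))
    ]
    return _write_json(_feature_collection(features), path)


def read_destinations_geojson(path: str | Path) -> DestinationSet:
    with open(path) as fh:
        fc = json.load(fh)
    xy = [f["geometry"]["coordinates"] for f in fc["features"]]
    types = [f["properties"]["dest_type"] for f in fc["features"]]
    return DestinationSet(xy, types)


# ---------------------------------------------------------------------------
# participants and tables
# ---------------------------------------------------------------------------


def write_participants_csv(
    participants: Sequence[Participant], path: str | Path, admin: AdminUnitSet | None = None
) -> Path:
    from neighscale.synthetic_city import participants_frame

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    participants_frame(participants, admin).to_csv(path, index=False)
    return path


def read_participants_csv(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            Participant(
                participant_id=int(r["participant_id"]),
                home=Point(float(r["home_x"]), float(r["home_y"])),
                sex=r["sex"],
                age=float(r["age"]),
                ethnicity=r["ethnicity"],
                income=r["income"],
                marital=r["marital"],
                education=r["education"],
                employment=r["employment"],
                car_access=bool(r["car_access"]),
                preference=int(r["preference"]),
                city_id=int(r["city_id"]),
                study_neighbourhood_id=int(r["study_neighbourhood_id"]),
            )
        )
    return out


def write_delineations(
    records: Sequence[NeighbourhoodDelineation], out_dir: str | Path
) -> dict[str, Path]:
    """One GeoJSON FeatureCollection per definition plus a CSV area index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_def: dict[str, list[NeighbourhoodDelineation]] = {}
    for r in records:
        by_def.setdefault(r.definition, []).append(r)
    paths: dict[str, Path] = {}
    for definition, recs in sorted(by_def.items()):
        features = [
            {
                "type": "Feature",
                "geometry": mapping(r.polygon),
                "properties": {
                    "participant_id": r.participant_id,
                    "definition": r.definition,
                    "area_km2": r.area_km2,
                },
            }
            for r in recs
        ]
        paths[definition] = _write_json(
            _feature_collection(features), out_dir / f"delineations_{definition}.geojson"
        )
    index = pd.DataFrame(
        [
            {"participant_id": r.participant_id, "definition": r.definition, "area_km2": r.area_km2}
            for r in records
        ]
    )
    paths["index"] = out_dir / "delineations_index.csv"
    index.to_csv(paths["index"], index=False)
    return paths


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------


def write_true_params_yaml(params: TrueModelParams, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "alpha": dict(params.alpha) if not isinstance(params.alpha, float) else params.alpha,
        "beta": params.beta,
        "gamma": dict(params.gamma),
        "sigma2_city": params.sigma2_city,
        "sigma2_nbhd": params.sigma2_nbhd,
        "sigma2_resid": params.sigma2_resid,
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
    return path


def read_true_params_yaml(path: str | Path) -> TrueModelParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return TrueModelParams(**doc)
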