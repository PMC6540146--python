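"""Shared fixtures: a toy grid, a small synthetic city, and a delineated cohort.

Problem sizes are deliberately modest (a 4.5 x 4.5 km region, cohorts of a
few hundred) so the whole suite runs quickly on one CPU; the statistical
checks that need replication use lightweight abstract cohorts instead of
the full spatial pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Point

from neighscale import delineation as dl
from neighscale import exposures as ex
from neighscale import synthetic_city as sc

EXTENT = (4480.0, 4480.0)
SPACING = 112.0
MB_CELL = 224.0


@pytest.fixture(scope="session")
def toy_grid() -> sc.StreetNetwork:
    """Intact 6x6 grid, 100-m spacing: 36 nodes, 60 edges."""
    return sc.generate_street_network((500.0, 500.0), 100.0, 0.0, 0.0, seed=1)


@pytest.fixture(scope="session")
def small_city() -> dict:
    """A complete small synthetic study region with 200 participants."""
    net = sc.generate_street_network(EXTENT, SPACING, 0.15, 0.02, seed=11)
    admin, zoning = sc.generate_admin_units(net, MB_CELL, seed=12)
    sc.assign_walkability_and_select(admin, net, n_neigh_per_class=6)
    dests = sc.generate_destinations(admin, seed=13)
    parts = sc.generate_participants(admin, 200, seed=14)
    return {
        "network": net,
        "admin": admin,
        "zoning": zoning,
        "destinations": dests,
        "participants": parts,
    }


@pytest.fixture(scope="session")
def pipeline(small_city) -> dict:
    """Delineations and exposures for a 120-participant sub-cohort."""
    parts = small_city["participants"][:120]
    records, summary = dl.delineate_all(
        parts, small_city["network"], small_city["admin"]
    )
    ped = dl.remove_inaccessible_roads(small_city["network"])
    table = ex.exposure_table(
        records,
        small_city["admin"],
        small_city["zoning"],
        ped,
        small_city["destinations"],
    )
    return {
        "participants": parts,
        "records": records,
        "summary": summary,
        "table": table,
        "pedestrian": ped,
    }


def make_abstract_cohort(
    n: int = 2000,
    n_cities: int = 4,
    nb_per_city: int = 12,
    seed: int = 0,
    exposure_mean: float = 10.0,
    exposure_sd: float = 3.0,
):
    """Cohort with group structure but no geometry, for model calibration.

    Mirrors the study's clustering design (4 cities x 12 study
    neighbourhoods) without the expense of spatial generation; the
    exposure is an arbitrary continuous covariate.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for pid in range(n):
        c = int(rng.integers(0, n_cities))
        nb = c * nb_per_city + int(rng.integers(0, nb_per_city))
        parts.append(
            sc.Participant(
                participant_id=pid,
                home=Point(0.0, 0.0),
                sex="female" if rng.random() < 0.55 else "male",
                age=float(rng.uniform(20, 65)),
                ethnicity=str(rng.choice(["nz_european", "maori", "asian"])),
                income=str(rng.choice(["low", "medium", "high"])),
                marital=str(rng.choice(["partnered", "single"])),
                education=str(rng.choice(["secondary", "degree"])),
                employment=str(rng.choice(["fulltime", "parttime"])),
                car_access=bool(rng.random() < 0.85),
                preference=int(rng.integers(1, 6)),
                city_id=30000 + c,
                study_neighbourhood_id=20000 + nb,
            )
        )
    exposure = {
        p.participant_id: float(rng.normal(exposure_mean, exposure_sd)) for p in parts
    }
    frame = sc.participants_frame(parts)
    frame["deprivation"] = rng.integers(1, 11, size=n)
    frame["exposure"] = frame["participant_id"].map(exposure)
    return parts, exposure, frame


@pytest.fixture(scope="session")
def abstract_cohort():
    return make_abstract_cohort(seed=7)
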