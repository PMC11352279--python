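"""Surface distances and co-localization: geometric oracles, symmetry,
nearest-neighbor logic, PHB spacing."""

import numpy as np
import pytest

from granulemetrics.morphometry import extract_objects
from granulemetrics.spatial_stats import (
    DistanceRecord,
    colocalization_fraction,
    nearest_neighbor_table,
    phb_spacing_summary,
    surface_distance,
    surface_distance_bruteforce,
)
from granulemetrics.synthetic_data import generate_phantom, rasterize_sphere_into
from granulemetrics.volume_io import LabelVolume
from tests.conftest import untreated_like_spec


def two_sphere_volume(c1, d1, c2, d2, vs=2.0, shape=(90, 90, 170)):
    data = np.zeros(shape, dtype=np.int8)
    rasterize_sphere_into(data, np.asarray(c1, float), d1, vs, 2)
    rasterize_sphere_into(data, np.asarray(c2, float), d2, vs, 3)
    return LabelVolume(data, voxel_size=vs)


def test_sphere_pair_distance_geometry():
    """r = 100 and r = 50 nm spheres, centers 300 nm apart: gap 150 nm."""
    vs = 2.0
    vol = two_sphere_volume([110, 110, 110], 200, [110, 110, 410], 100, vs=vs, shape=(112, 112, 250))
    a = extract_objects(vol, "PHB")[0]
    b = extract_objects(vol, "PP")[0]
    d = surface_distance(a, b, vs)
    assert d == pytest.approx(150.0, abs=2 * vs)


def test_adjoining_objects_have_zero_distance():
    data = np.zeros((8, 8, 16), dtype=np.int8)
    data[2:6, 2:6, 2:7] = 2
    data[2:6, 2:6, 7:12] = 3  # shares a voxel face
    vol = LabelVolume(data, voxel_size=1.0)
    a = extract_objects(vol, "PHB")[0]
    b = extract_objects(vol, "PP")[0]
    assert surface_distance(a, b, 1.0) == 0.0


def test_distance_symmetric_and_self_rejected():
    vol = two_sphere_volume([40, 40, 40], 30, [40, 40, 110], 40)
    a = extract_objects(vol, "PHB")[0]
    b = extract_objects(vol, "PP")[0]
    assert surface_distance(a, b, 2.0) == surface_distance(b, a, 2.0)
    with pytest.raises(ValueError, match="distinct"):
        surface_distance(a, a, 2.0)


def test_matches_bruteforce_on_random_pairs():
    rng = np.random.default_rng(4)
    vs = 1.0
    for _ in range(6):
        while True:
            c1 = rng.uniform(12, 48, 3)
            c2 = rng.uniform(12, 48, 3)
            d1, d2 = rng.uniform(8, 16, 2)
            if np.linalg.norm(c1 - c2) > (d1 + d2) / 2 + 2:
                break
        vol = two_sphere_volume(c1, d1, c2, d2, vs=vs, shape=(60, 60, 60))
        a = extract_objects(vol, "PHB")[0]
        b = extract_objects(vol, "PP")[0]
        fast = surface_distance(a, b, vs)
        brute = surface_distance_bruteforce(a, b, vs)
        assert abs(fast - brute) <= vs


def test_triangle_consistency_on_sphere_phantoms():
    """|center distance − surface distance − rA − rB| ≤ 2 voxels."""
    rng = np.random.default_rng(9)
    vs = 1.0
    for _ in range(4):
        c1 = rng.uniform(15, 30, 3)
        c2 = c1 + rng.uniform(18, 30, 3)
        d1, d2 = rng.uniform(10, 16, 2)
        if np.linalg.norm(c1 - c2) <= (d1 + d2) / 2 + 1:
            continue
        vol = two_sphere_volume(c1, d1, c2, d2, vs=vs, shape=(70, 70, 70))
        a = extract_objects(vol, "PHB")[0]
        b = extract_objects(vol, "PP")[0]
        center_dist = np.linalg.norm(c1 - c2)
        gap = surface_distance(a, b, vs)
        assert abs(center_dist - gap - d1 / 2 - d2 / 2) <= 2 * vs


def test_nearest_neighbor_picks_minimum():
    vs = 2.0
    data = np.zeros((60, 60, 200), dtype=np.int8)
    rasterize_sphere_into(data, np.array([60.0, 60.0, 60.0]), 40, vs, 2)
    rasterize_sphere_into(data, np.array([60.0, 60.0, 300.0]), 40, vs, 2)
    rasterize_sphere_into(data, np.array([60.0, 60.0, 130.0]), 30, vs, 3)
    vol = LabelVolume(data, voxel_size=vs)
    cells = {0: extract_objects(vol, "PHB") + extract_objects(vol, "PP")}
    records = nearest_neighbor_table(cells, "PP", "PHB", vs)
    assert len(records) == 1
    # nearer PHB is the one at x = 60 nm: gap = 70 − 20 − 15 = 35 nm
    assert records[0].surface_distance_nm == pytest.approx(35.0, abs=2 * vs)
    assert records[0].pp_width_nm == pytest.approx(30.0, rel=0.05)


def test_cells_missing_a_class_contribute_no_record():
    vs = 2.0
    data = np.zeros((40, 40, 40), dtype=np.int8)
    rasterize_sphere_into(data, np.array([40.0, 40.0, 40.0]), 30, vs, 3)
    vol = LabelVolume(data, voxel_size=vs)
    cells = {0: extract_objects(vol, "PP")}
    assert nearest_neighbor_table(cells, "PP", "PHB", vs) == []
    with pytest.raises(ValueError, match="unknown granule class"):
        nearest_neighbor_table(cells, "PP", "carboxysome", vs)


def test_generator_coloc_gap_recovered(phantom_cohort):
    """PP placed at a 10 nm surface gap from PHB measures ≤ gap + 1 voxel."""
    cells = {}
    vs = None
    for i, (vol, _) in enumerate(phantom_cohort):
        cells[i] = extract_objects(vol, "PHB", cell_id=i) + extract_objects(vol, "PP", cell_id=i)
        vs = vol.voxel_size
    records = nearest_neighbor_table(cells, "PP", "PHB", vs)
    assert len(records) == len(phantom_cohort)  # one PP per cell, all with PHB
    for r in records:
        assert r.surface_distance_nm <= 10.0 + vs


def make_records(distances):
    return [
        DistanceRecord(0, i, 0, "PP", "PHB", d, pp_width_nm=100.0) for i, d in enumerate(distances)
    ]


def test_colocalization_fraction_counts():
    """7 of 12 distances at or under 25 nm: fraction 0.583."""
    records = make_records([0, 5, 10, 12, 20, 24, 25, 30, 40, 80, 120, 300])
    k, n, frac = colocalization_fraction(records, 25.0)
    assert (k, n) == (7, 12)
    assert frac == pytest.approx(0.583, abs=5e-4)


def test_colocalization_edge_cases_and_monotonicity():
    assert colocalization_fraction(make_records([0.0, 0.0]), 25.0)[2] == 1.0
    with pytest.raises(ValueError):
        colocalization_fraction([], 25.0)
    records = make_records(np.linspace(0, 400, 29))
    fracs = [colocalization_fraction(records, t)[2] for t in np.linspace(0, 450, 12)]
    assert all(b >= a for a, b in zip(fracs, fracs[1:]))


def test_phb_spacing_pair_counts_and_cluster_cap(phantom_cohort):
    cells = {}
    vs = None
    for i, (vol, _) in enumerate(phantom_cohort):
        cells[i] = extract_objects(vol, "PHB", cell_id=i)
        vs = vol.voxel_size
    spacing = phb_spacing_summary(cells, vs)
    for i, objs in cells.items():
        n = len(objs)
        if n < 2:
            assert i not in spacing
            continue
        assert len(spacing[i]["pairwise_nm"]) == n * (n - 1) // 2
        # generator capped continuous surface gaps at 400 nm; the meshed
        # surfaces can only move the measurement by a voxel or two
        assert spacing[i]["max_nm"] <= 400.0 + 2 * vs
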