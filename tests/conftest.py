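"""Shared fixtures: small phantom volumes reused across test modules.

Everything is generated programmatically at collection time — there are no
stored data files.  Voxel sizes are coarse (whole-cell phantoms) except
where a test explicitly probes fine-voxel behavior.
"""

from __future__ import annotations

import numpy as np
import pytest

from granulemetrics.synthetic_data import (
    CellPhantomSpec,
    GranulePopulationSpec,
    generate_phantom,
    rasterize_sphere_into,
)
from granulemetrics.volume_io import DEFAULT_LABEL_MAP, LabelVolume

COARSE_VOXEL_NM = 9.202


def untreated_like_spec(seed: int = 0, cell_id: int = 0) -> CellPhantomSpec:
    """A growing-cell phantom: polar-clustered PHB + one PP near PHB."""
    return CellPhantomSpec(
        cell_length_nm=2200.0,
        cell_radius_nm=400.0,
        voxel_size_nm=COARSE_VOXEL_NM,
        seed=seed,
        cell_id=cell_id,
        populations=[
            GranulePopulationSpec(
                granule_class="PHB",
                count_law=("fixed", 4),
                diameter_mean_nm=179.0,
                diameter_sd_nm=55.6,
                placement="polar_cluster",
                cluster_max_spacing_nm=400.0,
            ),
            GranulePopulationSpec(
                granule_class="PP",
                count_law=("fixed", 1),
                diameter_mean_nm=106.0,
                diameter_sd_nm=34.0,
                placement="near_other_class",
                coloc_prob=1.0,
                coloc_gap_nm=10.0,
            ),
        ],
    )


@pytest.fixture(scope="session")
def untreated_phantom():
    """(LabelVolume, ground-truth frame) for one growing-like cell."""
    return generate_phantom(untreated_like_spec(seed=11))


@pytest.fixture(scope="session")
def phantom_cohort():
    """Five growing-like cells: list of (LabelVolume, truth)."""
    return [generate_phantom(untreated_like_spec(seed=100 + i, cell_id=i)) for i in range(5)]


def sphere_volume_at(center_nm, diameter_nm, voxel_size=1.0, shape=None, label=2):
    """A LabelVolume holding one rasterized sphere (helper for oracles)."""
    if shape is None:
        n = int(np.ceil((max(center_nm) + diameter_nm) / voxel_size)) + 2
        shape = (n, n, n)
    data = np.zeros(shape, dtype=np.int8)
    rasterize_sphere_into(data, np.asarray(center_nm, float), diameter_nm, voxel_size, label)
    return LabelVolume(data=data, voxel_size=voxel_size, label_map=dict(DEFAULT_LABEL_MAP))
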