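"""Phantom generator: rasterization accuracy, placement rules, determinism,
LC-MS simulation, fluorescence rendering."""

import numpy as np
import pandas as pd
import pytest

from granulemetrics.lcms_quant import fit_standard_curve, quantify_run
from granulemetrics.synthetic_data import (
    BACKGROUND,
    CELL,
    PHB,
    PP,
    CellPhantomSpec,
    GranulePopulationSpec,
    LcmsSimSpec,
    PlacementError,
    apply_label_noise,
    generate_fluorescence_image,
    generate_lcms_dataset,
    generate_phantom,
    generate_sphere_cohort,
    sample_truncated_diameters,
)
from tests.conftest import COARSE_VOXEL_NM, untreated_like_spec


def bare_cell_spec(**kw):
    defaults = dict(
        cell_length_nm=1500.0,
        cell_radius_nm=400.0,
        voxel_size_nm=COARSE_VOXEL_NM,
        populations=[],
        seed=1,
    )
    defaults.update(kw)
    return CellPhantomSpec(**defaults)


def test_zero_granules_gives_cell_only():
    vol, truth = generate_phantom(bare_cell_spec())
    assert set(np.unique(vol.data)) == {BACKGROUND, CELL}
    assert truth.empty


def test_single_sphere_rasterized_volume_matches_analytic():
    """A d = 200 nm sphere at 0.9202 nm voxels: voxel count × voxel volume
    within 2% of πd³/6 (it is far better in practice)."""
    vol, d = next(generate_sphere_cohort(1, 200.0, 0.0, voxel_size_nm=0.9202, seed=3))
    count = int((vol.data == PHB).sum())
    assert count * vol.voxel_volume == pytest.approx(np.pi / 6 * 200**3, rel=0.02)


def test_volume_conservation_is_bit_exact(untreated_phantom):
    vol, truth = untreated_phantom
    for cls, label in (("PHB", PHB), ("PP", PP)):
        sub = truth[truth.granule_class == cls]
        assert int((vol.data == label).sum()) == int(sub.voxel_count.sum())
        assert (sub.rasterized_volume_nm3 == sub.voxel_count * vol.voxel_size**3).all()


def test_ground_truth_analytic_identities(untreated_phantom):
    _, truth = untreated_phantom
    d = truth.true_diameter_nm
    assert np.allclose(truth.true_volume_nm3, np.pi / 6 * d**3)
    assert np.allclose(truth.true_surface_area_nm2, np.pi * d**2)
    assert truth.granule_id.is_unique


def test_same_seed_is_byte_identical():
    spec = untreated_like_spec(seed=42)
    vol_a, truth_a = generate_phantom(spec)
    vol_b, truth_b = generate_phantom(untreated_like_spec(seed=42))
    np.testing.assert_array_equal(vol_a.data, vol_b.data)
    pd.testing.assert_frame_equal(truth_a, truth_b)
    vol_c, _ = generate_phantom(untreated_like_spec(seed=43))
    assert not np.array_equal(vol_a.data, vol_c.data)


def test_polar_cluster_respects_pairwise_spacing_cap():
    for seed in range(5):
        _, truth = generate_phantom(untreated_like_spec(seed=seed))
        phb = truth[truth.granule_class == "PHB"]
        centers = phb[["center_z_nm", "center_y_nm", "center_x_nm"]].to_numpy()
        radii = phb.true_diameter_nm.to_numpy() / 2
        for i in range(len(phb)):
            for j in range(i + 1, len(phb)):
                gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
                assert gap <= 400.0
                assert gap >= 0.0  # same-class granules never interpenetrate


def test_granules_lie_inside_cell(untreated_phantom):
    vol, truth = untreated_phantom
    # every granule voxel would otherwise have been cytoplasm
    granule_mask = (vol.data == PHB) | (vol.data == PP)
    assert not (granule_mask & (vol.data == BACKGROUND)).any()
    # reconstruct: cell+granules form the full capsule, so granules touching
    # background would show as granule voxels 26-adjacent to background
    from scipy import ndimage

    dilated = ndimage.binary_dilation(granule_mask, np.ones((3, 3, 3), bool))
    assert not (dilated & (vol.data == BACKGROUND)).any()


def test_oversized_granule_raises():
    spec = bare_cell_spec(
        populations=[
            GranulePopulationSpec(
                granule_class="PHB",
                count_law=("fixed", 1),
                diameter_mean_nm=900.0,  # exceeds the 800 nm cell diameter
                diameter_sd_nm=0.0,
                placement="polar_cluster",
            )
        ]
    )
    with pytest.raises(PlacementError, match="exceeds cell diameter"):
        generate_phantom(spec)


def test_truncated_normal_volume_moment():
    """For diameters ~ N(µ, σ) truncated positive with σ ≪ µ, the mean true
    sphere volume approaches π/6·(µ³ + 3µσ²)."""
    rng = np.random.default_rng(7)
    d = sample_truncated_diameters(179.0, 55.6, 2 * 0.9202, rng, 10_000)
    vols = np.pi / 6 * d**3
    expected = np.pi / 6 * (179.0**3 + 3 * 179.0 * 55.6**2)
    se = vols.std() / np.sqrt(len(vols))
    assert abs(vols.mean() - expected) < 4 * se + 0.01 * expected


@pytest.mark.parametrize(
    "law,check",
    [
        (("fixed", 3), lambda c: c == 3),
        (("uniform", 1, 3), lambda c: 1 <= c <= 3),
        (("poisson", 2), lambda c: c >= 0),
    ],
)
def test_count_laws(law, check):
    spec = bare_cell_spec(
        cell_length_nm=2000.0,
        populations=[
            GranulePopulationSpec(
                granule_class="PHB",
                count_law=law,
                diameter_mean_nm=150.0,
                diameter_sd_nm=0.0,
                placement="dispersed_polar",
            )
        ],
        seed=5,
    )
    _, truth = generate_phantom(spec)
    assert check(len(truth))


# --- LC-MS simulation -------------------------------------------------------


def test_lcms_zero_noise_recovers_curve_and_mass_exactly():
    spec = LcmsSimSpec(slope=100.0, intercept=50.0, true_phb_mass_ug=607.0, dry_mass_mg=10.0)
    run = generate_lcms_dataset(spec)
    curve = fit_standard_curve(run)
    assert curve.slope == pytest.approx(100.0, abs=1e-9)
    assert curve.intercept == pytest.approx(50.0, abs=1e-7)
    table = quantify_run(run, curve)
    assert table.loc[0, "phb_ug"] == pytest.approx(607.0, rel=1e-9)
    assert table.loc[0, "percent_biomass"] == pytest.approx(6.07, rel=1e-9)


def test_lcms_is_drift_corrected_by_normalization():
    """10% internal-standard drift: quantified mass unbiased within 2% over
    50 replicates."""
    true_mass = 250.0
    recovered = []
    for rep in range(50):
        run = generate_lcms_dataset(
            LcmsSimSpec(is_area_cv=0.10, true_phb_mass_ug=true_mass, seed=1000 + rep)
        )
        recovered.append(quantify_run(run).loc[0, "phb_ug"])
    assert np.mean(recovered) == pytest.approx(true_mass, rel=0.02)


# --- fluorescence rendering -------------------------------------------------


def test_fluorescence_field_layout_and_masks():
    membrane, foci, mask = generate_fluorescence_image(
        [2.0, 3.0], [[0.5], [0.2, 0.8]], seed=1
    )
    assert membrane.shape == foci.shape == mask.shape
    assert set(np.unique(mask)) == {0, 1, 2}


def test_focus_position_bounds_validated():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        generate_fluorescence_image([2.0], [[1.5]])


def test_label_noise_flips_only_boundary_voxels(untreated_phantom):
    vol, _ = untreated_phantom
    noisy = apply_label_noise(vol, flip_prob=0.5, seed=0)
    changed = vol.data != noisy.data
    assert changed.any()
    # flipped voxels were granule voxels and are now cytoplasm
    assert set(np.unique(vol.data[changed])) <= {PHB, PP}
    assert set(np.unique(noisy.data[changed])) == {CELL}
    # interiors survive: granule voxel counts drop by less than half
    for label in (PHB, PP):
        assert (noisy.data == label).sum() > 0.5 * (vol.data == label).sum()
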