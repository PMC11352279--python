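"""Synthetic phantoms with ground truth for every pipeline stage.

No raw tomograms are publicly deposited for this system, so the test bed is
a phantom generator that emulates the reported biology: capsule-shaped
(sphero-cylindrical) cells 1–4 µm long; PHB granules that are numerous,
~179 ± 55.6 nm in diameter and polar-clustered in growing cells, but few
(1–3), ~383 ± 86.5 nm and dispersed to the poles after chloramphenicol
growth arrest; polyphosphate granules (~1 per cell, 106 ± 34 nm growing,
202 ± 34 nm arrested) that sit against PHB surfaces in roughly 55–58% of
cases; a linear LC-MS response with internal-standard scaling over
10–750 µg/mL; and fluorescent foci at granule positions.

Granules are rasterized spheres: a voxel belongs to a granule iff its
center lies inside the sphere.  This partial-volume-free rule keeps the
voxel-count volume conservation exact and its bias vanishes for granules
more than ~20 voxels across.  Diameters are drawn from a normal law
truncated (by rejection) to more than two voxel widths.  Same-class
granules never overlap; cross-class contact is allowed but never
interpenetration.  All sampling is driven by a single integer seed per
spec — determinism is byte-for-byte.

What the phantoms do NOT emulate: electron-optical contrast, noise, the
missing wedge, or CNN segmentation errors.  Passing recovery tests on
phantoms therefore validates the measurement arithmetic, not robustness to
imperfect segmentations (an optional boundary label-noise hook exists for
light perturbation studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from granulemetrics.lcms_quant import LcmsRun
from granulemetrics.volume_io import DEFAULT_LABEL_MAP, LabelVolume

#: Labels used in phantom volumes.
BACKGROUND, CELL, PHB, PP = 0, 1, 2, 3
CLASS_LABELS = {"PHB": PHB, "PP": PP}

#: Tomogram voxel size emulated by default (nm).
DEFAULT_VOXEL_SIZE_NM = 0.9202


class PlacementError(RuntimeError):
    """Raised when bounded rejection sampling cannot place a granule."""


@dataclass
class GranulePopulationSpec:
    """Statistical description of one granule class within a cell.

    count_law is ("fixed", k), ("uniform", lo, hi) (inclusive) or
    ("poisson", lam).  Placement is one of polar_cluster (all centers in one
    polar cap with pairwise surface gaps capped), dispersed_polar
    (alternating poles, no spacing cap) or near_other_class (placed against
    an existing granule of the other class with probability coloc_prob at
    surface gap coloc_gap_nm, otherwise uniformly at least
    noncoloc_min_gap_nm away).
    """

    granule_class: str
    count_law: tuple
    diameter_mean_nm: float
    diameter_sd_nm: float
    placement: str
    cluster_max_spacing_nm: float = 400.0
    coloc_prob: float = 0.55
    coloc_gap_nm: float = 10.0
    noncoloc_min_gap_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.granule_class not in CLASS_LABELS:
            raise ValueError(f"granule_class must be PHB or PP, got {self.granule_class!r}")
        if not self.diameter_mean_nm > 0:
            raise ValueError("diameter_mean_nm must be positive")
        if self.diameter_sd_nm < 0:
            raise ValueError("diameter_sd_nm must be non-negative")
        if not 0.0 <= self.coloc_prob <= 1.0:
            raise ValueError("coloc_prob must be in [0, 1]")
        if self.placement not in {"polar_cluster", "dispersed_polar", "near_other_class"}:
            raise ValueError(f"unknown placement {self.placement!r}")
        law = self.count_law[0]
        if law not in {"fixed", "uniform", "poisson"}:
            raise ValueError(f"unknown count law {law!r}")


@dataclass
class CellPhantomSpec:
    """One phantom cell: capsule geometry + granule populations + seed."""

    cell_length_nm: float
    cell_radius_nm: float
    populations: list[GranulePopulationSpec]
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM
    seed: int = 0
    cell_id: int = 0

    def __post_init__(self) -> None:
        if not self.voxel_size_nm > 0:
            raise ValueError("voxel_size_nm must be positive")
        if self.cell_length_nm < 2 * self.cell_radius_nm:
            raise ValueError("cell_length_nm must be at least twice cell_radius_nm")


@dataclass
class LcmsSimSpec:
    """Parameters of a simulated LC-MS quantification run.

    The response model is linear with multiplicative noise and
    internal-standard scaling: an observed analyte area is
    (slope·conc + intercept) × (IS_area / IS_mean) × (1 + cv·ε).
    Concentrations span the 10–750 µg/mL standard range by default;
    extract_volume_ml is the digestion volume the dried biomass dissolves
    into (4 mL).
    """

    standard_concs_ug_ml: Sequence[float] = (10, 25, 50, 100, 250, 500, 750)
    slope: float = 100.0  # area per (µg/mL)
    intercept: float = 0.0
    noise_cv: float = 0.0
    is_area_mean: float = 5e5
    is_area_cv: float = 0.0
    true_phb_mass_ug: float | Sequence[float] = 130.0
    dry_mass_mg: float = 10.0
    cfu_per_ml: float = 1.53e10
    extract_volume_ml: float = 4.0
    culture_volume_ml: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        concs = np.asarray(self.standard_concs_ug_ml, dtype=float)
        if not (concs > 0).all():
            raise ValueError("standard concentrations must be positive")
        if not (np.diff(concs) > 0).all():
            raise ValueError("standard concentrations must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


# ---------------------------------------------------------------------------
# geometry helpers


def _segment_endpoints(spec: CellPhantomSpec, margin_vox: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints (nm, zyx order) of the capsule's axis segment."""
    vs = spec.voxel_size_nm
    r = spec.cell_radius_nm
    ny = _shape(spec, margin_vox)[0]
    c = (ny - 1) / 2.0 * vs
    x0 = margin_vox * vs + r
    x1 = margin_vox * vs + spec.cell_length_nm - r
    return np.array([c, c, x0]), np.array([c, c, x1])


def _shape(spec: CellPhantomSpec, margin_vox: int = 2) -> tuple[int, int, int]:
    vs = spec.voxel_size_nm
    nyz = int(math.ceil(2 * spec.cell_radius_nm / vs)) + 2 * margin_vox + 1
    nx = int(math.ceil(spec.cell_length_nm / vs)) + 2 * margin_vox + 1
    return (nyz, nyz, nx)


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of points (n, 3) to segment [a, b] (all nm, zyx)."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(points))
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def rasterize_sphere_into(
    data: np.ndarray, center_nm: np.ndarray, diameter_nm: float, voxel_size: float, label: int
) -> int:
    """Set ``label`` on every voxel whose center lies inside the sphere;
    returns the voxel count.  Voxel centers are at index × voxel_size."""
    r = diameter_nm / 2.0
    lo = np.maximum(0, np.floor((center_nm - r) / voxel_size).astype(int))
    hi = np.minimum(np.array(data.shape), np.ceil((center_nm + r) / voxel_size).astype(int) + 1)
    idx = [np.arange(lo[k], hi[k]) for k in range(3)]
    dz2 = (idx[0] * voxel_size - center_nm[0]) ** 2
    dy2 = (idx[1] * voxel_size - center_nm[1]) ** 2
    dx2 = (idx[2] * voxel_size - center_nm[2]) ** 2
    plane = dy2[:, None] + dx2[None, :]
    count = 0
    # slice-wise to avoid a (z, y, x) distance temporary on large spheres
    for zi, z2 in enumerate(dz2):
        if z2 > r * r:
            continue
        inside = plane <= r * r - z2
        sub = data[lo[0] + zi, lo[1] : hi[1], lo[2] : hi[2]]
        sub[inside] = label
        count += int(inside.sum())
    return count


# ---------------------------------------------------------------------------
# granule sampling


def _sample_count(law: tuple, rng: np.random.Generator) -> int:
    kind = law[0]
    if kind == "fixed":
        return int(law[1])
    if kind == "uniform":
        return int(rng.integers(law[1], law[2] + 1))
    if kind == "poisson":
        return int(rng.poisson(law[1]))
    raise ValueError(kind)


def sample_truncated_diameters(
    mean: float, sd: float, lower: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw ``n`` diameters from Normal(mean, sd) truncated to > ``lower``
    by rejection — the law every phantom granule population follows.  For
    sd ≪ mean the mean rasterized sphere volume approaches
    π/6·(mean³ + 3·mean·sd²)."""
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean, sd, size=max(n - out.size, 16) * 2)
        out = np.concatenate([out, draw[draw > lower]])
    return out[:n]


def _sample_diameter(
    pop: GranulePopulationSpec, spec: CellPhantomSpec, rng: np.random.Generator
) -> float:
    """Truncated-normal diameter: > 2 voxel widths, by rejection.  A draw
    wider than the cell diameter is an error (the granule cannot exist)."""
    lo = 2.0 * spec.voxel_size_nm
    for _ in range(10_000):
        d = rng.normal(pop.diameter_mean_nm, pop.diameter_sd_nm)
        if d > lo:
            if d >= 2 * spec.cell_radius_nm:
                raise PlacementError(
                    f"{pop.granule_class} diameter {d:.0f} nm exceeds cell diameter "
                    f"{2 * spec.cell_radius_nm:.0f} nm"
                )
            return float(d)
    raise PlacementError(
        f"could not draw a {pop.granule_class} diameter > {lo:.2f} nm from "
        f"N({pop.diameter_mean_nm}, {pop.diameter_sd_nm})"
    )


@dataclass
class _Placed:
    granule_class: str
    center: np.ndarray  # nm, zyx
    diameter: float

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def _inside_eroded_capsule(
    center: np.ndarray, radius: float, spec: CellPhantomSpec, a: np.ndarray, b: np.ndarray
) -> bool:
    margin = spec.voxel_size_nm  # one-voxel guard keeps the raster inside the cell
    d = _dist_to_segment(center[None, :], a, b)[0]
    return d <= spec.cell_radius_nm - radius - margin


def _gap(p: _Placed, q: _Placed) -> float:
    return float(np.linalg.norm(p.center - q.center) - p.radius - q.radius)


def _sample_cap_point(
    pole: np.ndarray, inward: np.ndarray, cap_depth: float, spec: CellPhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform point in the box around one polar cap (accept/reject against
    the eroded capsule happens in the caller)."""
    s = rng.uniform(0.0, cap_depth)
    r = spec.cell_radius_nm
    off = rng.uniform(-r, r, size=2)
    return pole + inward * s + np.array([off[0], off[1], 0.0])


def _place_population(
    pop: GranulePopulationSpec,
    count: int,
    spec: CellPhantomSpec,
    placed: list[_Placed],
    rng: np.random.Generator,
    max_attempts: int = 2000,
) -> list[_Placed]:
    a, b = _segment_endpoints(spec)
    tip_a = a - np.array([0.0, 0.0, spec.cell_radius_nm])
    tip_b = b + np.array([0.0, 0.0, spec.cell_radius_nm])
    inward_a = np.array([0.0, 0.0, 1.0])
    inward_b = np.array([0.0, 0.0, -1.0])
    cap_depth = 2.0 * spec.cell_radius_nm
    cluster_pole = rng.integers(0, 2)  # polar_cluster picks one pole per cell

    new: list[_Placed] = []
    same_class = lambda: [p for p in placed + new if p.granule_class == pop.granule_class]
    other_class = lambda: [p for p in placed + new if p.granule_class != pop.granule_class]

    for i in range(count):
        d = _sample_diameter(pop, spec, rng)
        g = _Placed(pop.granule_class, np.zeros(3), d)
        ok = False
        # the co-localization coin is flipped ONCE per granule: re-flipping
        # inside the rejection loop would bias accepted placements toward
        # whichever branch rejects less and break coloc_prob recovery
        partners = other_class()
        coloc = bool(partners) and rng.random() < pop.coloc_prob
        for _ in range(max_attempts):
            if pop.placement == "polar_cluster":
                pole, inward = (tip_a, inward_a) if cluster_pole == 0 else (tip_b, inward_b)
                g.center = _sample_cap_point(pole, inward, cap_depth, spec, rng)
            elif pop.placement == "dispersed_polar":
                pole, inward = ((tip_a, inward_a), (tip_b, inward_b))[i % 2]
                g.center = _sample_cap_point(pole, inward, cap_depth, spec, rng)
            elif pop.placement == "near_other_class":
                if coloc:
                    host = partners[rng.integers(0, len(partners))]
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    g.center = host.center + u * (host.radius + pop.coloc_gap_nm + g.radius)
                else:
                    lo = np.array([0.0, 0.0, 0.0])
                    hi = np.array(_shape(spec)) * spec.voxel_size_nm
                    g.center = rng.uniform(lo, hi)
                    if partners and min(_gap(g, p) for p in partners) < pop.noncoloc_min_gap_nm:
                        continue
            if not _inside_eroded_capsule(g.center, g.radius, spec, a, b):
                continue
            # no interpenetration with anything; no overlap within class
            if any(_gap(g, p) < 0 for p in placed + new if p is not g):
                continue
            sames = same_class()
            if any(_gap(g, p) < spec.voxel_size_nm for p in sames):
                continue
            if pop.placement == "polar_cluster" and any(
                _gap(g, p) > pop.cluster_max_spacing_nm for p in sames
            ):
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"cell {spec.cell_id}: could not place {pop.granule_class} granule "
                f"{i + 1}/{count} (d = {d:.0f} nm, placement = {pop.placement}) "
                f"after {max_attempts} attempts"
            )
        new.append(g)
    return new


# ---------------------------------------------------------------------------
# public generators


def generate_phantom(
    spec: CellPhantomSpec, max_cell_attempts: int = 10
) -> tuple[LabelVolume, pd.DataFrame]:
    """Rasterize one phantom cell and return (label volume, ground truth).

    Labels: 0 background, 1 cytoplasm, 2 PHB, 3 PP.  The ground-truth table
    has one row per granule with the analytic sphere volume/area
    (πd³/6, πd²) and the rasterized voxel count; summed per class, the
    rasterized volumes equal the labeled-voxel totals exactly.

    A placement that jams (granules cannot satisfy their spacing rules) is
    retried with a fresh derived seed up to ``max_cell_attempts`` times
    before the error propagates.
    """
    last_err: Exception | None = None
    for attempt in range(max_cell_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        try:
            placed: list[_Placed] = []
            for pop in spec.populations:
                count = _sample_count(pop.count_law, rng)
                placed.extend(_place_population(pop, count, spec, placed, rng))
            break
        except PlacementError as err:  # jammed packing: retry whole cell
            last_err = err
    else:
        raise last_err  # type: ignore[misc]

    vs = spec.voxel_size_nm
    data = np.zeros(_shape(spec), dtype=np.int8)
    a, b = _segment_endpoints(spec)
    # cytoplasm: capsule = within cell_radius of the x-aligned axis segment;
    # radial (z, y) and axial (x) distance terms broadcast separately
    z = np.arange(data.shape[0], dtype=np.float32) * vs - a[0]
    y = np.arange(data.shape[1], dtype=np.float32) * vs - a[1]
    x = np.arange(data.shape[2], dtype=np.float32) * vs
    rad2 = z[:, None] ** 2 + y[None, :] ** 2
    ax = np.maximum(0.0, np.maximum(a[2] - x, x - b[2])) ** 2
    inside = rad2[:, :, None] + ax[None, None, :] <= spec.cell_radius_nm**2
    data[inside] = CELL

    rows = []
    for gid, g in enumerate(placed):
        count = rasterize_sphere_into(data, g.center, g.diameter, vs, CLASS_LABELS[g.granule_class])
        rows.append(
            {
                "cell_id": spec.cell_id,
                "granule_id": gid,
                "granule_class": g.granule_class,
                "center_z_nm": g.center[0],
                "center_y_nm": g.center[1],
                "center_x_nm": g.center[2],
                "true_diameter_nm": g.diameter,
                "true_volume_nm3": math.pi / 6.0 * g.diameter**3,
                "true_surface_area_nm2": math.pi * g.diameter**2,
                "voxel_count": count,
                "rasterized_volume_nm3": count * vs**3,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "granule_id",
            "granule_class",
            "center_z_nm",
            "center_y_nm",
            "center_x_nm",
            "true_diameter_nm",
            "true_volume_nm3",
            "true_surface_area_nm2",
            "voxel_count",
            "rasterized_volume_nm3",
        ],
    )
    vol = LabelVolume(data=data, voxel_size=vs, label_map=dict(DEFAULT_LABEL_MAP))
    return vol, truth


def generate_sphere_cohort(
    n: int,
    diameter_mean_nm: float,
    diameter_sd_nm: float,
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM,
    seed: int = 0,
    granule_class: str = "PHB",
) -> Iterator[tuple[LabelVolume, float]]:
    """Yield ``n`` single-granule volumes with diameters from the truncated
    normal law, each sphere rasterized in a tight volume with a random
    sub-voxel center offset (so voxel-grid alignment does not bias cohort
    statistics).  Yields (LabelVolume, true diameter)."""
    rng = np.random.default_rng(seed)
    label = CLASS_LABELS[granule_class]
    lo = 2.0 * voxel_size_nm
    for _ in range(n):
        d = rng.normal(diameter_mean_nm, diameter_sd_nm)
        while d <= lo:
            d = rng.normal(diameter_mean_nm, diameter_sd_nm)
        r = d / 2.0
        pad = 2
        half = int(math.ceil(r / voxel_size_nm)) + pad
        shape = (2 * half + 1,) * 3
        center = (np.array([half, half, half]) + rng.uniform(-0.5, 0.5, size=3)) * voxel_size_nm
        data = np.zeros(shape, dtype=np.int8)
        rasterize_sphere_into(data, center, d, voxel_size_nm, label)
        yield LabelVolume(data=data, voxel_size=voxel_size_nm), float(d)


def generate_lcms_dataset(spec: LcmsSimSpec) -> LcmsRun:
    """Simulate one LC-MS run under the linear + internal-standard model.

    At zero noise the downstream curve fit recovers slope and intercept
    exactly and quantification is an identity on the true mass.
    """
    rng = np.random.default_rng(spec.seed)
    concs = np.asarray(spec.standard_concs_ug_ml, dtype=float)

    def is_draw(size):
        if spec.is_area_cv == 0:
            return np.full(size, spec.is_area_mean)
        vals = rng.normal(spec.is_area_mean, spec.is_area_cv * spec.is_area_mean, size=size)
        return np.clip(vals, 0.05 * spec.is_area_mean, None)

    def response(conc, is_area):
        ideal = spec.slope * conc + spec.intercept
        drift = is_area / spec.is_area_mean
        noise = 1.0 + (spec.noise_cv * rng.standard_normal(np.shape(conc)) if spec.noise_cv else 0.0)
        return ideal * drift * noise

    std_is = is_draw(len(concs))
    standards = pd.DataFrame(
        {
            "conc_ug_ml": concs,
            "analyte_area": response(concs, std_is),
            "is_area": std_is,
        }
    )
    masses = np.atleast_1d(np.asarray(spec.true_phb_mass_ug, dtype=float))
    samp_is = is_draw(len(masses))
    sample_concs = masses / spec.extract_volume_ml
    samples = pd.DataFrame(
        {
            "sample_id": [f"sample_{i}" for i in range(len(masses))],
            "analyte_area": response(sample_concs, samp_is),
            "is_area": samp_is,
            "extract_volume_ml": spec.extract_volume_ml,
            "dry_mass_mg": spec.dry_mass_mg,
            "cfu_per_ml": spec.cfu_per_ml,
            "culture_volume_ml": spec.culture_volume_ml,
        }
    )
    return LcmsRun(standards=standards, samples=samples)


def generate_fluorescence_image(
    cell_lengths_um: Sequence[float],
    focus_positions: Sequence[Sequence[float]],
    cell_radius_um: float = 0.35,
    pixel_size_um: float = 0.065,
    focus_amplitude: float = 100.0,
    focus_sigma_px: float = 2.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a field of disjoint horizontal capsule cells.

    Returns (membrane, foci, mask): the membrane channel outlines each
    capsule, the foci channel holds Gaussian spots at the stated fractional
    positions along each cell's major axis (0 and 1 are the two tips), and
    the mask carries per-cell integer labels (1-based).
    """
    if len(cell_lengths_um) != len(focus_positions):
        raise ValueError("one focus-position list per cell required")
    for fp in focus_positions:
        if any(not 0.0 <= f <= 1.0 for f in fp):
            raise ValueError("focus positions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    r_px = cell_radius_um / pixel_size_um
    margin = int(math.ceil(2 * r_px))
    lengths_px = [l / pixel_size_um for l in cell_lengths_um]
    width = int(math.ceil(max(lengths_px))) + 2 * margin
    row_h = int(math.ceil(2 * r_px)) + margin
    height = row_h * len(lengths_px) + margin
    membrane = np.zeros((height, width), dtype=np.float32)
    foci = np.zeros_like(membrane)
    mask = np.zeros(membrane.shape, dtype=np.int32)
    yy, xx = np.mgrid[0:height, 0:width]
    for i, (length_px, fps) in enumerate(zip(lengths_px, focus_positions)):
        cy = margin // 2 + row_h * i + row_h // 2
        x0 = margin + r_px  # axis segment endpoint (tip at x0 - r_px)
        x1 = margin + length_px - r_px
        t = np.clip((xx - x0) / max(x1 - x0, 1e-9), 0.0, 1.0)
        px_ax = x0 + t * (x1 - x0)
        dist = np.hypot(xx - px_ax, yy - cy)
        capsule = dist <= r_px
        if (mask[capsule] != 0).any():
            raise ValueError(f"cell {i} overlaps a previously placed cell")
        mask[capsule] = i + 1
        membrane += np.where(np.abs(dist - r_px) <= 1.0, 1.0, 0.0)
        tip_lo = x0 - r_px
        for f in fps:
            fx = tip_lo + f * (length_px)
            foci += focus_amplitude * np.exp(
                -((xx - fx) ** 2 + (yy - cy) ** 2) / (2 * focus_sigma_px**2)
            )
    for img in (membrane, foci):
        img += background
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return membrane, foci, mask


def apply_label_noise(vol: LabelVolume, flip_prob: float, seed: int = 0) -> LabelVolume:
    """Optional perturbation hook: flip granule boundary voxels to cytoplasm
    with probability ``flip_prob`` (a crude stand-in for segmentation
    raggedness; tomographic contrast realism is out of scope)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    data = vol.data.copy()
    for label in (PHB, PP):
        m = data == label
        if not m.any():
            continue
        boundary = m & ~ndimage.binary_erosion(m)
        flip = boundary & (rng.random(data.shape) < flip_prob)
        data[flip] = CELL
    return LabelVolume(data=data, voxel_size=vol.voxel_size, label_map=dict(vol.label_map))
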