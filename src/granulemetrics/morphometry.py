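"""Per-granule and per-cell morphometry from label volumes.

Granules are extracted as 26-connected components of their class label;
volumes come from voxel counts, surface areas from a marching-cubes
triangulation of the binary mask, diameters as equivalent spherical
diameters, and cell length as the extent of the cell mask along its first
principal axis.

Estimator choices that matter
-----------------------------
* 26-connectivity keeps the staircase boundary of a rasterized sphere in
  one piece; 6-connectivity would fragment it.
* Surface area uses the marching-cubes mesh rather than counting exposed
  voxel faces — face counting overestimates a sphere's area by ~1.5×
  (staircase artifact), the mesh converges to the true area for objects a
  few tens of voxels across.
* "Diameter" always means the diameter of the sphere with the measured
  volume; Feret-style calliper diameters are noise-sensitive on voxelized
  boundaries and are not computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from granulemetrics.volume_io import LabelVolume

logger = logging.getLogger(__name__)

#: Components smaller than this many voxels are discarded as segmentation
#: noise — they are below meshing resolution.
MIN_OBJECT_VOXELS = 8


@dataclass
class GranuleObject:
    """One connected storage granule and its measurements (nm units)."""

    cell_id: int
    granule_id: int
    granule_class: str
    voxel_count: int
    volume_nm3: float
    surface_area_nm2: float
    eq_diameter_nm: float
    centroid_nm: tuple  # (z, y, x)
    voxels: np.ndarray = field(repr=False, compare=False, default=None)  # (n, 3) indices
    voxel_size: float = field(default=0.0, compare=False)


@dataclass
class CellRecord:
    """Per-cell aggregation of granule content."""

    cell_id: int
    cell_length_nm: float
    n_phb: int
    n_pp: int
    phb_volume_total_nm3: float
    pp_volume_total_nm3: float
    phb_surface_total_nm2: float
    pp_surface_total_nm2: float
    treated: bool


def equivalent_diameter(volume_nm3: float) -> float:
    """Diameter of the sphere with the given volume: (6V/π)^(1/3)."""
    if not volume_nm3 > 0:
        raise ValueError(f"volume must be positive, got {volume_nm3}")
    return float((6.0 * volume_nm3 / np.pi) ** (1.0 / 3.0))


def measure_surface_area(
    mask: np.ndarray, voxel_size: float, smoothing_sigma: float = 1.0
) -> float:
    """Surface area (nm²) of a binary object: marching cubes at level 0.5
    on the (lightly smoothed) mask.

    Meshing the raw binary mask inherits the voxel staircase and
    overestimates a sphere's area by ~9% regardless of size; a Gaussian
    pre-smoothing of ``smoothing_sigma`` voxels (default 1) anti-aliases the
    boundary and brings spheres ≥ 20 voxels across within 2% of πd².  The
    price is a stronger chamfer on sharp edges (a 10-voxel cube reads ~18%
    low); granules are round, so the sphere behavior is the one optimized.
    Pass ``smoothing_sigma=0`` for the raw-mask estimator.

    The mask is zero-padded so the isosurface closes around objects touching
    the array edge (and so single-voxel objects mesh at all).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot measure surface area of an empty object")
    pad = max(2, int(np.ceil(3 * smoothing_sigma)))
    padded = np.pad(mask, pad).astype(np.float32)
    if smoothing_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smoothing_sigma)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(voxel_size,) * 3
    )
    return float(measure.mesh_surface_area(verts, faces))


def surface_vertices(voxels: np.ndarray, shape_hint: tuple | None = None) -> np.ndarray:
    """Marching-cubes surface vertex coordinates (voxel-index units) for an
    object given as an (n, 3) array of voxel indices.

    Vertices are returned in the global index frame of the parent volume so
    distances between objects can be taken directly.  Used by the spatial
    statistics stage.
    """
    voxels = np.asarray(voxels)
    lo = voxels.min(axis=0)
    local = voxels - lo
    shape = tuple(local.max(axis=0) + 1)
    mask = np.zeros(shape, dtype=np.float32)
    mask[tuple(local.T)] = 1.0
    padded = np.pad(mask, 1)
    verts, _, _, _ = measure.marching_cubes(padded, level=0.5)
    # un-pad and shift back to the parent volume's index frame
    return verts - 1.0 + lo


def extract_objects(
    vol: LabelVolume,
    granule_class: str,
    cell_id: int = 0,
    min_voxels: int = MIN_OBJECT_VOXELS,
    compute_surface: bool = True,
    store_voxels: bool = True,
) -> list[GranuleObject]:
    """Extract one GranuleObject per 26-connected component of a class.

    Components below ``min_voxels`` are dropped (and logged) as segmentation
    noise.  Raises KeyError if ``granule_class`` is not in the volume's
    label map.  ``store_voxels=False`` skips caching voxel coordinates
    (needed only for surface-distance work) — worthwhile for very large
    objects.
    """
    mask = vol.class_mask(granule_class)  # KeyError if class unmapped
    labeled, n = measure.label(mask, connectivity=3, return_num=True)
    objects: list[GranuleObject] = []
    gid = 0
    slices = ndimage.find_objects(labeled)
    for idx in range(1, n + 1):
        sl = slices[idx - 1]
        sub = labeled[sl] == idx
        count = int(np.count_nonzero(sub))
        if count < min_voxels:
            logger.info(
                "cell %s: dropping %s component of %d voxels (< %d, below meshing resolution)",
                cell_id,
                granule_class,
                count,
                min_voxels,
            )
            continue
        offset = np.array([s.start for s in sl])
        voxels = (np.argwhere(sub) + offset) if store_voxels else None
        volume = count * vol.voxel_volume
        area = measure_surface_area(sub, vol.voxel_size) if compute_surface else float("nan")
        # centroid by axis reductions (cheap even on 1e8-voxel objects)
        axes_sums = [
            sub.sum(axis=tuple(k for k in range(3) if k != ax)) for ax in range(3)
        ]
        centroid = tuple(
            (float((np.arange(len(s)) * s).sum()) / count + offset[ax]) * vol.voxel_size
            for ax, s in enumerate(axes_sums)
        )
        objects.append(
            GranuleObject(
                cell_id=cell_id,
                granule_id=gid,
                granule_class=granule_class,
                voxel_count=count,
                volume_nm3=volume,
                surface_area_nm2=area,
                eq_diameter_nm=equivalent_diameter(volume),
                centroid_nm=centroid,
                voxels=voxels,
                voxel_size=vol.voxel_size,
            )
        )
        gid += 1
    return objects


def cell_length(mask: np.ndarray, voxel_size: float) -> float:
    """Cell length (nm): extent of the mask's voxel centers along its first
    principal axis, plus one voxel size.

    Orientation-invariant; on capsule phantoms it recovers the tip-to-tip
    length (the +1 voxel accounts for the half-voxel beyond the outermost
    voxel centers at each tip).  Raises if the mask has more than one
    26-connected component — crop per cell first.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    _, ncomp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if ncomp != 1:
        raise ValueError(
            f"cell mask has {ncomp} connected components; crop the volume to a single cell"
        )
    coords = np.argwhere(mask).astype(np.float64)
    coords -= coords.mean(axis=0)
    # principal axis from the covariance of voxel-center coordinates
    cov = np.cov(coords, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    proj = coords @ axis
    return float((proj.max() - proj.min() + 1.0) * voxel_size)


def cell_axis(mask: np.ndarray, voxel_size: float) -> tuple[np.ndarray, float]:
    """(unit principal axis (z,y,x), centroid projection nm) of a cell mask —
    the frame used to split a cell into its two axial halves."""
    coords = np.argwhere(np.asarray(mask).astype(bool)).astype(np.float64)
    if coords.size == 0:
        raise ValueError("empty cell mask")
    centroid = coords.mean(axis=0)
    cov = np.cov(coords - centroid, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    mid = float(centroid @ axis * voxel_size)
    return axis, mid


def aggregate_cell(
    objects: list[GranuleObject],
    cell_mask: np.ndarray,
    voxel_size: float,
    treated: bool,
    cell_id: int | None = None,
) -> CellRecord:
    """Aggregate a cell's granules into counts and class totals.

    All objects must share one cell_id (an empty object list is allowed and
    yields zero counts/totals).
    """
    ids = {o.cell_id for o in objects}
    if len(ids) > 1:
        raise ValueError(f"objects span multiple cells: {sorted(ids)}")
    if cell_id is None:
        cell_id = ids.pop() if ids else 0
    phb = [o for o in objects if o.granule_class == "PHB"]
    pp = [o for o in objects if o.granule_class == "PP"]
    return CellRecord(
        cell_id=cell_id,
        cell_length_nm=cell_length(cell_mask, voxel_size),
        n_phb=len(phb),
        n_pp=len(pp),
        phb_volume_total_nm3=float(sum(o.volume_nm3 for o in phb)),
        pp_volume_total_nm3=float(sum(o.volume_nm3 for o in pp)),
        phb_surface_total_nm2=float(sum(o.surface_area_nm2 for o in phb)),
        pp_surface_total_nm2=float(sum(o.surface_area_nm2 for o in pp)),
        treated=treated,
    )
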