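"""Reading and writing the pipeline's file formats.

Volumes are MRC (integer label data, voxel size carried in the header in
ångströms and exposed here in nanometres); tables are CSV with units encoded
in the column names (``volume_nm3``, ``mass_fg`` ...).

Axis order is (z, y, x) throughout, matching the MRC section/row/column
convention.  Physical coordinates are voxel-center based and 0-based: the
center of voxel (i, j, k) sits at (i, j, k) × voxel_size nm.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import mrcfile
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default semantic mapping for phantom and segmentation label volumes.
DEFAULT_LABEL_MAP = {0: "background", 1: "cell", 2: "PHB", 3: "PP"}

ANGSTROM_PER_NM = 10.0


@dataclass
class LabelVolume:
    """A 3D integer label volume with isotropic voxel size in nm.

    Parameters
    ----------
    data:
        3D integer array, axis order (z, y, x).
    voxel_size:
        Edge length of one voxel in nanometres (isotropic).
    label_map:
        Mapping from integer label to class name; must cover every nonzero
        label present in ``data``.
    """

    data: np.ndarray
    voxel_size: float
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must hold integers, got {self.data.dtype}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 nm, got {self.voxel_size}")
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in data but absent from label_map")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in nm³."""
        return float(self.voxel_size) ** 3

    def class_label(self, class_name: str) -> int:
        """Integer label carrying ``class_name``; KeyError if unmapped."""
        for lab, name in self.label_map.items():
            if name == class_name:
                return lab
        raise KeyError(f"class {class_name!r} not in label_map {self.label_map}")

    def class_mask(self, class_name: str) -> np.ndarray:
        return self.data == self.class_label(class_name)


def read_label_volume(
    path: str | Path,
    label_map: dict[int, str] | None = None,
    voxel_size_override: float | None = None,
) -> LabelVolume:
    """Read an MRC label volume.

    The header voxel size (Å) is converted to nm by dividing by 10.  A zero
    header voxel size is an error unless ``voxel_size_override`` (nm) is
    supplied, in which case the override is used with a logged warning.
    Anisotropic voxel sizes are rejected: the downstream morphometry assumes
    isotropy.
    """
    path = Path(path)
    with mrcfile.open(path, permissive=True) as mrc:
        data = np.asarray(mrc.data)
        vs = mrc.voxel_size
        vs_angstrom = np.array([float(vs.z), float(vs.y), float(vs.x)])
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise ValueError(f"{path}: MRC data is not integer-representable ({data.dtype})")
    if np.any(vs_angstrom == 0):
        if voxel_size_override is None:
            raise ValueError(
                f"{path}: header voxel size is zero; pass voxel_size_override (nm) to proceed"
            )
        logger.warning(
            "%s: header voxel size is zero, using override %.4f nm", path, voxel_size_override
        )
        voxel_nm = float(voxel_size_override)
    else:
        if not np.allclose(vs_angstrom, vs_angstrom[0], rtol=1e-4):
            raise ValueError(f"{path}: anisotropic voxel size {vs_angstrom} Å unsupported")
        voxel_nm = float(vs_angstrom[0]) / ANGSTROM_PER_NM
        if voxel_size_override is not None and not np.isclose(voxel_nm, voxel_size_override):
            logger.warning(
                "%s: override %.4f nm replaces header value %.4f nm",
                path,
                voxel_size_override,
                voxel_nm,
            )
            voxel_nm = float(voxel_size_override)
    return LabelVolume(data=data, voxel_size=voxel_nm, label_map=label_map or dict(DEFAULT_LABEL_MAP))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a LabelVolume as MRC with the voxel size stored in Å.

    Data is stored as int8 when the label range allows (MRC mode 0),
    otherwise int16 (mode 1).
    """
    path = Path(path)
    data = vol.data
    if data.min() >= np.iinfo(np.int8).min and data.max() <= np.iinfo(np.int8).max:
        out = data.astype(np.int8)
    elif data.min() >= np.iinfo(np.int16).min and data.max() <= np.iinfo(np.int16).max:
        out = data.astype(np.int16)
    else:
        raise ValueError("label range exceeds int16; MRC integer modes cannot store it")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mrcfile.new(path, overwrite=True) as mrc:
            mrc.set_data(out)
            mrc.voxel_size = vol.voxel_size * ANGSTROM_PER_NM


def write_measurements(records, path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    """Write measurement records to CSV with a stable column order.

    ``records`` may be a DataFrame, a list of dataclass instances, or a list
    of dicts.  An empty list with ``columns`` given yields a header-only CSV.
    Array-valued dataclass fields (e.g. cached voxel coordinates) are dropped.
    Returns the frame that was written.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        rows = []
        for rec in records:
            if dataclasses.is_dataclass(rec):
                d = {
                    f.name: getattr(rec, f.name)
                    for f in dataclasses.fields(rec)
                    if not isinstance(getattr(rec, f.name), np.ndarray)
                }
            else:
                d = dict(rec)
            rows.append(_flatten(d))
        frame = pd.DataFrame(rows, columns=columns if not rows else None)
    if columns is not None and len(frame) == 0:
        frame = pd.DataFrame(columns=columns)
    frame.to_csv(path, index=False)
    return frame


def _flatten(d: dict) -> dict:
    """Expand small tuple/list values into suffixed scalar columns (x/y/z)."""
    out = {}
    for key, val in d.items():
        if isinstance(val, (tuple, list)) and len(val) == 3:
            for suffix, item in zip(("z", "y", "x"), val):
                out[f"{key}_{suffix}"] = item
        else:
            out[key] = val
    return out


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
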