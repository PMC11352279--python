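"""Geometry-to-mass conversion and cohort summary statistics.

Granule volumes (nm³) convert to femtograms through the polymer density:
1 g/cm³ ≡ 10⁻⁶ fg/nm³, and PHB has density 1.170 g/cm³, so

    mass_fg = volume_nm3 × density × 1e-6.

Cohort statistics are computed per cell and then averaged over cells; the
per-granule basis is also emitted (suffix ``_per_granule``) because counts
per cell differ strongly between conditions and the two bases answer
different questions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from granulemetrics.morphometry import CellRecord, GranuleObject

#: PHB density, g/cm³.
PHB_DENSITY_G_CM3 = 1.170

#: 1 g/cm³ expressed in fg/nm³.
FG_PER_NM3_PER_G_CM3 = 1e-6


@dataclass
class MassConstants:
    phb_density: float = PHB_DENSITY_G_CM3  # g/cm³

    def __post_init__(self) -> None:
        if not self.phb_density > 0:
            raise ValueError("density must be positive")


@dataclass
class ConditionSummary:
    """Cohort-level summary for one growth condition."""

    condition: str
    n_cells: int
    phb_mass_fg_per_cell_mean: float
    phb_mass_fg_per_cell_sd: float
    pp_volume_nm3_per_cell_mean: float
    pp_volume_nm3_per_cell_sd: float
    phb_surface_nm2_per_cell_mean: float
    v_sa_ratio_nm_per_cell: float       # mean of per-cell V/SA quotients
    v_sa_ratio_nm_pooled: float         # total V / total SA over the cohort
    phb_diameter_nm_mean: float
    phb_diameter_nm_sd: float
    pp_diameter_nm_mean: float
    pp_diameter_nm_sd: float
    phb_count_per_cell_mean: float
    pp_count_per_cell_mean: float
    phb_volume_nm3_per_cell_mean: float
    phb_volume_nm3_per_granule_mean: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d.update(self.extras)
        return d


def volume_to_mass(volume_nm3: float, density_g_cm3: float = PHB_DENSITY_G_CM3) -> float:
    """Convert a polymer volume (nm³) to mass (fg) via its density."""
    if volume_nm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_nm3}")
    return float(volume_nm3 * density_g_cm3 * FG_PER_NM3_PER_G_CM3)


def sphere_volume(diameter_nm: float) -> float:
    """Volume (nm³) of a sphere of the given diameter: πd³/6."""
    if not diameter_nm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_nm}")
    return float(np.pi / 6.0 * diameter_nm**3)


def v_sa_ratio(total_volume_nm3: float, total_surface_nm2: float) -> float:
    """Volume-to-surface-area quotient (nm) for one cell; d/6 for a sphere."""
    if not total_surface_nm2 > 0:
        raise ValueError("surface area must be positive")
    return float(total_volume_nm3 / total_surface_nm2)


def fold_change(mean_treated: float, mean_untreated: float) -> float:
    """treated / untreated ratio of two positive cohort means."""
    if not mean_untreated > 0 or not mean_treated > 0:
        raise ValueError("fold change requires two positive means")
    return float(mean_treated / mean_untreated)


def phb_pp_volume_ratio(record: CellRecord) -> float | None:
    """Per-cell PHB:PP volume ratio; None (with a logged warning, no error)
    for cells without PP — such cells exist and cohort averages skip them."""
    if record.pp_volume_total_nm3 <= 0:
        logger.warning("cell %s has no PP volume; PHB:PP ratio skipped", record.cell_id)
        return None
    return float(record.phb_volume_total_nm3 / record.pp_volume_total_nm3)


def summarize_condition(
    cell_records: list[CellRecord],
    granule_objects: list[GranuleObject],
    constants: MassConstants | None = None,
    condition: str = "",
) -> ConditionSummary:
    """Cohort summary: per-cell masses/volumes averaged over cells, granule
    diameters averaged over granules.  SDs are population SDs over the
    cohort (ddof=0 — the cohort is the population reported)."""
    if not cell_records:
        raise ValueError("summarize_condition needs at least one cell")
    constants = constants or MassConstants()
    masses = np.array(
        [volume_to_mass(c.phb_volume_total_nm3, constants.phb_density) for c in cell_records]
    )
    pp_vols = np.array([c.pp_volume_total_nm3 for c in cell_records])
    phb_vols = np.array([c.phb_volume_total_nm3 for c in cell_records])
    surfaces = np.array([c.phb_surface_total_nm2 for c in cell_records])
    per_cell_ratios = [
        v_sa_ratio(v, s) for v, s in zip(phb_vols, surfaces) if s > 0
    ]
    phb_d = np.array(
        [o.eq_diameter_nm for o in granule_objects if o.granule_class == "PHB"]
    )
    pp_d = np.array([o.eq_diameter_nm for o in granule_objects if o.granule_class == "PP"])
    phb_granule_vols = np.array(
        [o.volume_nm3 for o in granule_objects if o.granule_class == "PHB"]
    )

    ratios = [r for r in (phb_pp_volume_ratio(c) for c in cell_records) if r is not None]
    extras = {
        "phb_pp_volume_ratio_per_cell_mean": float(np.mean(ratios)) if ratios else float("nan"),
        "phb_mass_fg_per_granule_mean": float(
            np.mean(phb_granule_vols) * constants.phb_density * FG_PER_NM3_PER_G_CM3
        )
        if phb_granule_vols.size
        else float("nan"),
    }
    return ConditionSummary(
        condition=condition,
        n_cells=len(cell_records),
        phb_mass_fg_per_cell_mean=float(masses.mean()),
        phb_mass_fg_per_cell_sd=float(masses.std()),
        pp_volume_nm3_per_cell_mean=float(pp_vols.mean()),
        pp_volume_nm3_per_cell_sd=float(pp_vols.std()),
        phb_surface_nm2_per_cell_mean=float(surfaces.mean()),
        v_sa_ratio_nm_per_cell=float(np.mean(per_cell_ratios)) if per_cell_ratios else float("nan"),
        v_sa_ratio_nm_pooled=float(phb_vols.sum() / surfaces.sum()) if surfaces.sum() > 0 else float("nan"),
        phb_diameter_nm_mean=float(phb_d.mean()) if phb_d.size else float("nan"),
        phb_diameter_nm_sd=float(phb_d.std()) if phb_d.size else float("nan"),
        pp_diameter_nm_mean=float(pp_d.mean()) if pp_d.size else float("nan"),
        pp_diameter_nm_sd=float(pp_d.std()) if pp_d.size else float("nan"),
        phb_count_per_cell_mean=float(np.mean([c.n_phb for c in cell_records])),
        pp_count_per_cell_mean=float(np.mean([c.n_pp for c in cell_records])),
        phb_volume_nm3_per_cell_mean=float(phb_vols.mean()),
        phb_volume_nm3_per_granule_mean=float(phb_granule_vols.mean())
        if phb_granule_vols.size
        else float("nan"),
        extras=extras,
    )
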