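"""LC-MS standard-curve quantification of extracted PHB.

The arithmetic mirrors routine targeted-LC-MS practice: analyte peak areas
are rescaled by the co-injected internal standard (methyl benzoate), a
linear standard curve over 10–750 µg/mL maps normalized area to
concentration, and the recovered PHB mass is normalized two ways —
as a percentage of lyophilized dry biomass, and per viable cell via
CFU counts:

    conc  = (A_norm − b) / m            [µg/mL]
    PHB   = conc × V_extract            [µg]
    %biomass = PHB / (dry_mass_mg × 1000) × 100
    fg/cell  = PHB × 1e9 / (CFU/mL × V_culture)

The internal-standard reference is the mean IS area over the standards, so
a run with no drift is left unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STANDARD_RANGE_UG_ML = (10.0, 750.0)


@dataclass
class LcmsRun:
    """One quantification run: standards + samples.

    ``standards`` columns: conc_ug_ml, analyte_area, is_area.
    ``samples`` columns: sample_id, analyte_area, is_area, extract_volume_ml,
    dry_mass_mg, cfu_per_ml, culture_volume_ml.
    """

    standards: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.standards["conc_ug_ml"] <= 0).any():
            raise ValueError("standard concentrations must be positive")
        for col in ("analyte_area", "is_area"):
            if (self.standards[col] < 0).any():
                raise ValueError(f"negative {col} in standards")

    @property
    def is_reference_area(self) -> float:
        """Mean internal-standard area over the standards."""
        return float(self.standards["is_area"].mean())


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    valid_range_ug_ml: tuple = STANDARD_RANGE_UG_ML


@dataclass
class SampleQuant:
    sample_id: str
    conc_ug_ml: float
    phb_ug: float
    percent_biomass: float
    fg_per_cell: float
    extrapolated: bool = False
    clamped: bool = False


def normalize_to_is(analyte_area: float, is_area: float, is_reference_area: float) -> float:
    """Rescale an analyte area by the internal-standard ratio
    (reference / observed)."""
    if not is_area > 0:
        raise ValueError("internal-standard area must be positive")
    return float(analyte_area * (is_reference_area / is_area))


def fit_standard_curve(run: LcmsRun) -> StandardCurve:
    """Ordinary least squares of IS-normalized analyte area on concentration.

    Needs at least 3 distinct concentrations; a design with zero
    concentration variance is rejected.
    """
    std = run.standards
    conc = std["conc_ug_ml"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    ref = run.is_reference_area
    norm = np.array(
        [normalize_to_is(a, i, ref) for a, i in zip(std["analyte_area"], std["is_area"])]
    )
    if np.var(conc) == 0:
        raise ValueError("zero variance in standard concentrations")
    res = stats.linregress(conc, norm)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid_range_ug_ml=(float(conc.min()), float(conc.max())),
    )


def quantify_sample(run: LcmsRun, curve: StandardCurve, sample: pd.Series | dict) -> SampleQuant:
    """Quantify one sample row against a fitted curve.

    Concentrations below zero are clamped to 0 with a warning; values
    outside the curve's fitted range are flagged as extrapolated.
    """
    s = pd.Series(sample) if not isinstance(sample, pd.Series) else sample
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    norm = normalize_to_is(float(s["analyte_area"]), float(s["is_area"]), run.is_reference_area)
    conc = (norm - curve.intercept) / curve.slope
    clamped = False
    if conc < 0:
        logger.warning("sample %s: concentration %.3g < 0, clamped to 0", s.get("sample_id"), conc)
        conc, clamped = 0.0, True
    lo, hi = curve.valid_range_ug_ml
    extrapolated = bool(conc > 0 and not (lo <= conc <= hi))
    if extrapolated:
        logger.warning(
            "sample %s: concentration %.3g µg/mL outside fitted range [%g, %g]",
            s.get("sample_id"),
            conc,
            lo,
            hi,
        )
    phb_ug = conc * float(s["extract_volume_ml"])
    dry_mass_mg = float(s["dry_mass_mg"])
    if not dry_mass_mg > 0:
        raise ValueError("dry mass must be positive for biomass normalization")
    percent_biomass = phb_ug / (dry_mass_mg * 1000.0) * 100.0
    cfu = float(s["cfu_per_ml"])
    if not cfu > 0:
        raise ValueError("CFU/mL must be positive for per-cell normalization")
    n_cells = cfu * float(s["culture_volume_ml"])
    fg_per_cell = phb_ug * 1e9 / n_cells  # 1 µg = 1e9 fg
    return SampleQuant(
        sample_id=str(s.get("sample_id", "")),
        conc_ug_ml=float(conc),
        phb_ug=float(phb_ug),
        percent_biomass=float(percent_biomass),
        fg_per_cell=float(fg_per_cell),
        extrapolated=extrapolated,
        clamped=clamped,
    )


def quantify_run(run: LcmsRun, curve: StandardCurve | None = None) -> pd.DataFrame:
    """Quantify every sample of a run; fits the curve if not supplied."""
    curve = curve or fit_standard_curve(run)
    rows = [quantify_sample(run, curve, row).__dict__ for _, row in run.samples.iterrows()]
    return pd.DataFrame(rows)
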