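"""End-to-end orchestration: phantoms (or volumes) → morphometry →
spatial statistics → quantification → condition summary and comparison.

The default configuration encodes the two study conditions:

* ``untreated`` — 22 cells, ~7 PHB granules/cell (Poisson), diameters
  N(179, 55.6) nm in one polar cluster with pairwise surface gaps ≤ 400 nm;
  ~1 PP granule/cell, N(106, 34) nm, 58% placed within 25 nm of a PHB
  surface.
* ``cm_treated`` — 20 growth-arrested cells, 1–3 PHB granules/cell,
  N(383, 86.5) nm dispersed to the poles; ~1 PP granule/cell,
  N(202, 34) nm, 55% co-localized.

Phantom cohorts are rasterized at 9.202 nm voxels (10× the tomogram pixel)
— granules stay tens of voxels across, which the geometry-oracle tests show
is well inside the regime where voxelization bias is negligible, while
whole-cell volumes stay small enough to iterate on.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import yaml

from granulemetrics import morphometry, quantification, spatial_stats
from granulemetrics.synthetic_data import (
    CellPhantomSpec,
    GranulePopulationSpec,
    generate_phantom,
)
from granulemetrics.volume_io import write_measurements

logger = logging.getLogger(__name__)


def default_config() -> dict:
    return {
        "voxel_size_nm": 9.202,
        "coloc_threshold_nm": 25.0,
        "phb_density": quantification.PHB_DENSITY_G_CM3,
        "conditions": {
            "untreated": {
                "treated": False,
                "n_cells": 22,
                "cell_length_nm": [1500.0, 3500.0],
                "cell_radius_nm": 400.0,
                "phb": {
                    "count_law": ["poisson", 7],
                    "diameter_mean_nm": 179.0,
                    "diameter_sd_nm": 55.6,
                    "placement": "polar_cluster",
                    "cluster_max_spacing_nm": 400.0,
                },
                "pp": {
                    "count_law": ["fixed", 1],
                    "diameter_mean_nm": 106.0,
                    "diameter_sd_nm": 34.0,
                    "placement": "near_other_class",
                    "coloc_prob": 0.58,
                    "coloc_gap_nm": 10.0,
                },
            },
            "cm_treated": {
                "treated": True,
                "n_cells": 20,
                "cell_length_nm": [1500.0, 3500.0],
                "cell_radius_nm": 400.0,
                "phb": {
                    "count_law": ["uniform", 1, 3],
                    "diameter_mean_nm": 383.0,
                    "diameter_sd_nm": 86.5,
                    "placement": "dispersed_polar",
                },
                "pp": {
                    "count_law": ["fixed", 1],
                    "diameter_mean_nm": 202.0,
                    "diameter_sd_nm": 34.0,
                    "placement": "near_other_class",
                    "coloc_prob": 0.55,
                    "coloc_gap_nm": 10.0,
                },
            },
        },
    }


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return default_config()
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    base.update({k: v for k, v in cfg.items() if k != "conditions"})
    if "conditions" in cfg:
        base["conditions"] = cfg["conditions"]
    return base


def _population_from_cfg(granule_class: str, cfg: dict) -> GranulePopulationSpec:
    law = cfg["count_law"]
    return GranulePopulationSpec(
        granule_class=granule_class,
        count_law=tuple(law),
        diameter_mean_nm=float(cfg["diameter_mean_nm"]),
        diameter_sd_nm=float(cfg["diameter_sd_nm"]),
        placement=cfg["placement"],
        cluster_max_spacing_nm=float(cfg.get("cluster_max_spacing_nm", 400.0)),
        coloc_prob=float(cfg.get("coloc_prob", 0.55)),
        coloc_gap_nm=float(cfg.get("coloc_gap_nm", 10.0)),
        noncoloc_min_gap_nm=float(cfg.get("noncoloc_min_gap_nm", 100.0)),
    )


def build_cell_spec(cond_cfg: dict, voxel_size_nm: float, cell_id: int, seed: int) -> CellPhantomSpec:
    rng = np.random.default_rng(np.random.SeedSequence([seed, cell_id]))
    lo, hi = cond_cfg["cell_length_nm"]
    length = float(rng.uniform(lo, hi))
    populations = []
    if "phb" in cond_cfg:
        populations.append(_population_from_cfg("PHB", cond_cfg["phb"]))
    if "pp" in cond_cfg:
        populations.append(_population_from_cfg("PP", cond_cfg["pp"]))
    return CellPhantomSpec(
        cell_length_nm=length,
        cell_radius_nm=float(cond_cfg["cell_radius_nm"]),
        populations=populations,
        voxel_size_nm=voxel_size_nm,
        seed=int(np.random.SeedSequence([seed, cell_id, 7]).generate_state(1)[0] % (2**31)),
        cell_id=cell_id,
    )


def measure_volume(vol, cell_id: int, treated: bool):
    """Morphometry + per-cell aggregation for one single-cell label volume."""
    objects = []
    for cls in ("PHB", "PP"):
        objects.extend(morphometry.extract_objects(vol, cls, cell_id=cell_id))
    cell_mask = vol.data > 0  # cytoplasm + granules
    record = morphometry.aggregate_cell(objects, cell_mask, vol.voxel_size, treated, cell_id=cell_id)
    axis = morphometry.cell_axis(cell_mask, vol.voxel_size)
    return objects, record, axis


def run_condition(
    config: dict,
    condition: str,
    outdir: str | Path,
    seed: int,
    volumes: list | None = None,
) -> dict:
    """Run one condition end to end and write its tables.

    ``volumes`` may supply pre-loaded LabelVolumes (measurement of real
    segmentations); otherwise phantoms are generated from the condition's
    spec.  Writes granules.csv, cells.csv, distances.csv, spacing.csv and
    summary.json under ``outdir``; returns the in-memory results.
    """
    cond_cfg = config["conditions"][condition]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    treated = bool(cond_cfg.get("treated", False))
    voxel_size = float(config.get("voxel_size_nm", 9.202))

    all_objects, cell_records = [], []
    cells: dict[int, list] = {}
    axes: dict[int, tuple] = {}
    if volumes is None:
        n_cells = int(cond_cfg["n_cells"])
        cond_tag = zlib.crc32(condition.encode()) % (2**31)
        cond_seed = int(np.random.SeedSequence([seed, cond_tag]).generate_state(1)[0] % (2**31))
        for i in range(n_cells):
            spec = build_cell_spec(cond_cfg, voxel_size, cell_id=i, seed=cond_seed)
            vol, _truth = generate_phantom(spec)
            objects, record, axis = measure_volume(vol, cell_id=i, treated=treated)
            all_objects.extend(objects)
            cell_records.append(record)
            cells[i] = objects
            axes[i] = axis
    else:
        for i, vol in enumerate(volumes):
            objects, record, axis = measure_volume(vol, cell_id=i, treated=treated)
            all_objects.extend(objects)
            cell_records.append(record)
            cells[i] = objects
            axes[i] = axis

    distances = spatial_stats.nearest_neighbor_table(
        cells, "PP", "PHB", voxel_size, cell_lengths_axis=axes
    )
    spacing = spatial_stats.phb_spacing_summary(cells, voxel_size)

    constants = quantification.MassConstants(phb_density=float(config.get("phb_density", 1.170)))
    summary = quantification.summarize_condition(
        cell_records, all_objects, constants, condition=condition
    )
    threshold = float(config.get("coloc_threshold_nm", 25.0))
    if distances:
        k, n, frac = spatial_stats.colocalization_fraction(distances, threshold)
        summary.extras.update(
            {"coloc_k": k, "coloc_n": n, "coloc_fraction": frac, "coloc_threshold_nm": threshold}
        )

    write_measurements(all_objects, outdir / "granules.csv")
    write_measurements(cell_records, outdir / "cells.csv")
    write_measurements(distances, outdir / "distances.csv")
    spacing_rows = [
        {"cell_id": cid, "n_pairs": len(v["pairwise_nm"]), "max_pairwise_nm": v["max_nm"]}
        for cid, v in spacing.items()
    ]
    write_measurements(spacing_rows, outdir / "spacing.csv", columns=["cell_id", "n_pairs", "max_pairwise_nm"])
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")
    return {
        "objects": all_objects,
        "cell_records": cell_records,
        "distances": distances,
        "spacing": spacing,
        "summary": summary,
    }


def compare_conditions(summary_untreated, summary_treated) -> dict:
    """Fold changes (treated / untreated) for the headline quantities, plus
    the two co-localization fractions side by side."""
    a, b = summary_untreated, summary_treated
    fc = quantification.fold_change
    out = {
        "phb_mass_per_cell_fold": fc(b.phb_mass_fg_per_cell_mean, a.phb_mass_fg_per_cell_mean),
        "pp_volume_per_cell_fold": fc(b.pp_volume_nm3_per_cell_mean, a.pp_volume_nm3_per_cell_mean),
        "phb_surface_per_cell_fold": fc(
            b.phb_surface_nm2_per_cell_mean, a.phb_surface_nm2_per_cell_mean
        ),
        "phb_diameter_fold": fc(b.phb_diameter_nm_mean, a.phb_diameter_nm_mean),
        "pp_diameter_fold": fc(b.pp_diameter_nm_mean, a.pp_diameter_nm_mean),
        "coloc_fraction_untreated": a.extras.get("coloc_fraction"),
        "coloc_fraction_treated": b.extras.get("coloc_fraction"),
    }
    ra = a.extras.get("phb_pp_volume_ratio_per_cell_mean")
    rb = b.extras.get("phb_pp_volume_ratio_per_cell_mean")
    if ra and rb and np.isfinite(ra) and np.isfinite(rb):
        out["phb_pp_volume_ratio_fold"] = fc(rb, ra)
    return out


def run_report(config: dict, outdir: str | Path, seed: int) -> dict:
    """Both conditions + comparison.json; the full phantom pipeline."""
    outdir = Path(outdir)
    results = {}
    for condition in config["conditions"]:
        results[condition] = run_condition(config, condition, outdir / condition, seed)
    names = list(config["conditions"])
    comparison = {}
    if len(names) == 2:
        untreated = next(
            (n for n in names if not config["conditions"][n].get("treated")), names[0]
        )
        treated = next((n for n in names if n != untreated), names[1])
        comparison = compare_conditions(
            results[untreated]["summary"], results[treated]["summary"]
        )
        with open(outdir / "comparison.json", "w") as fh:
            json.dump(comparison, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return {"results": results, "comparison": comparison}
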