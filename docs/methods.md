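# Methods

`granulemetrics` quantifies bacterial storage organelles — polyhydroxybutyrate
(PHB) and polyphosphate (PP) granules — from labeled 3D segmentation volumes
of cryo-electron tomograms, and carries the companion LC-MS and
fluorescence-microscopy analyses used to cross-validate those measurements.
This note records the models, estimator choices, defaults, and the limits of
what the synthetic phantoms can establish.

## Measurement model

**Inputs.** A label volume is a 3D integer array (axis order z, y, x) with an
isotropic voxel size; labels are 0 background, 1 cytoplasm, 2 PHB, 3 PP.
Volumes are read and written as MRC, with the header voxel size in ångströms
converted to nanometres (÷10, applied exactly once). Physical coordinates are
voxel-center based and 0-based. Tomographic segmentations in this problem
domain arrive at ~0.9 nm voxels (9.202 Å after 2× binning), so granules of
interest are 100–600 voxels across.

**Granule extraction.** Granules are 26-connected components of their class
label. 26-connectivity is deliberate: the staircase boundary of a voxelized
sphere is not 6-connected everywhere, and face-connectivity would shear off
boundary shells. Components under 8 voxels are discarded as segmentation
noise (they are below meshing resolution); every discard is logged.

**Volume and diameter.** Object volume is `voxel_count × voxel_size³` —
exact under the rasterization model below and conserved bit-exactly per
class. Diameters are always *equivalent spherical diameters*,
`(6V/π)^(1/3)`. Calliper (Feret) diameters were rejected: on voxelized
boundaries they inherit staircase noise and depend on orientation.

**Surface area.** Area comes from a marching-cubes triangulation (level 0.5)
of the object's mask after a Gaussian pre-smoothing of σ = 1 voxel. Meshing
the raw binary mask retains the voxel staircase and overestimates a sphere's
area by ~9% *independent of size* — an irreducible bias, not a resolution
effect. The σ = 1 smoothing anti-aliases the boundary; rasterized spheres
≥ 20 voxels across then measure within ~2% of πd². The cost is a stronger
chamfer on sharp edges (a 10-voxel cube reads ~18% low). Storage granules
are round, so the sphere regime is the one optimized; `smoothing_sigma=0`
restores the raw estimator.

**Cell length.** The extent of the cell mask's voxel centers projected on
its first principal axis, plus one voxel (the half-voxel beyond the
outermost centers at each tip). This is orientation-invariant and recovers
tip-to-tip capsule length on phantoms to within 2 voxels.

**Surface-to-surface distance.** The minimum Euclidean distance between the
marching-cubes surface vertex sets of two objects, computed with a KD-tree.
Objects sharing or 26-adjoining voxels get distance 0, and cross-class
overlap reports 0 rather than a negative penetration depth. A brute-force
minimum over all boundary-voxel pairs is retained as an independent oracle;
the two agree within one voxel. A PP granule is called *co-localized* with
PHB when its nearest PHB surface lies within 25 nm (configurable).
Nearest-neighbor partners are searched cell-wide; each record carries a
`same_half` flag (computed from centroid projections on the cell axis) so
downstream analyses can restrict to same-pole pairs — the pole-assignment
rule itself is not standardized, so the pipeline flags rather than filters.

**Mass and summary statistics.** Polymer volume converts to mass via the
density of PHB, 1.170 g/cm³; since 1 g/cm³ = 10⁻⁶ fg/nm³,
`mass_fg = V_nm³ × ρ × 10⁻⁶`. Cohort statistics are computed per cell and
then averaged over cells; per-granule bases are also emitted (suffixed
`_per_granule`) because treated and untreated cells differ strongly in
granule count, and the two bases answer different questions. Volume-to-
surface-area ratios are reported both as the mean of per-cell quotients and
as the pooled quotient of totals — the two differ whenever per-cell values
are heteroscedastic, and neither is privileged. SDs are population SDs
(ddof = 0) over the cohort.

## LC-MS quantification

Analyte peak areas are rescaled by the internal standard (methyl benzoate):
`A_norm = A × (IS_ref / IS)`, with `IS_ref` the mean IS area over the
standards (the normalization constant is not standardized in practice; the
mean makes a drift-free run a no-op). The standard curve is unweighted OLS
of normalized area on concentration over the 10–750 µg/mL range; a 1/x
weighting is available in configuration but not default, as the simulated
response has constant CV only multiplicatively. Quantities then follow as

    conc = (A_norm − b)/m          µg/mL
    PHB  = conc × V_extract        µg   (V_extract default 4 mL digestion)
    %biomass = PHB / (dry_mass_mg × 1000) × 100
    fg/cell  = PHB × 10⁹ / (CFU/mL × V_culture)

Negative concentrations clamp to zero with a warning; concentrations outside
the fitted range are flagged as extrapolated, not rejected. The methyl
3-hydroxybutyrate ↔ PHB-monomer equivalence is treated as 1:1 at the
concentration level: the standard curve is built from the same ester, so
response factors cancel.

## Fluorescence demographs

Cell masks are an input (or derived from the membrane channel by Otsu
thresholding); robust segmentation is out of scope. Each cell reduces to an
axial profile: fluorescence integrated across the minor axis in 50 (default)
fractional-position bins along the major axis, oriented so the brighter half
sits at position 1 (0 = dim pole, 1 = bright pole); orientation is
idempotent. Foci are local maxima of the σ = 1 px smoothed image inside the
mask, with minimum separation 3 px, exceeding the in-cell background median
by ≥ 3× the MAD; background statistics are taken from the *raw* channel
because smoothing deflates the MAD and would let noise bumps clear the bar.
On phantoms at SNR ≥ 5 this detector achieves ≥ 95% sensitivity at ≤ 0.05
false positives per cell. The demograph stacks per-cell-max-normalized
profiles sorted by cell length; pairs of planted foci closer than ~5 px
merge into one (documented resolution limit).

## The phantom generator

Phantoms give every stage a ground-truthed input because no raw tomograms
are publicly deposited for this system. A phantom cell is a sphero-cylinder
(capsule) — rod-shaped bacteria carry no published shape model, and the
capsule is the simplest body with distinct poles — with default radius
400 nm and lengths 1–4 µm. Granules are spheres; a voxel belongs to a
granule iff its center lies inside the sphere. This center-in-sphere rule is
partial-volume-free, makes voxel-count volume conservation exact, and its
volume bias vanishes for granules ≳ 20 voxels across (the regime all tests
and defaults occupy).

Population defaults encode the two study conditions:

| parameter | growing (untreated) | growth-arrested (Cm) |
|---|---|---|
| PHB per cell | Poisson(7) | uniform 1–3 |
| PHB diameter | N(179, 55.6) nm | N(383, 86.5) nm |
| PHB placement | one polar cluster, pairwise surface gaps ≤ 400 nm | dispersed to alternating poles |
| PP per cell | 1 | 1 |
| PP diameter | N(106, 34) nm | N(202, 34) nm |
| PP co-localized with PHB | 58% | 55% |
| co-localization surface gap | 10 nm | 10 nm |

Diameters are drawn from the normal law truncated (by rejection) to more
than two voxel widths and are treated as population SDs — whether published
spreads include measurement error is unknowable from summary statistics, so
the generator puts all variance in the population. Same-class granules never
overlap (minimum surface gap of one voxel); cross-class contact is allowed
but never interpenetration. Non-co-localized PP is placed at least 100 nm
from any PHB surface so the 25 nm calling threshold sits far from both
modes. Placement is rejection sampling with 2000 attempts per granule; a
jammed cell is resampled (fresh derived seed) up to 10 times before an
error naming the granule propagates. A single integer seed drives all
sampling; identical seed and spec give byte-identical volumes and tables.

Whole-cell phantom cohorts are rasterized at 9.202 nm voxels — 10× the
tomogram pixel — keeping granules tens of voxels across (inside the regime
the geometry oracles validate) while a cell fits in a few million voxels.
The diameter-recovery cohorts use the full 0.9202 nm voxel in granule-tight
single-sphere volumes.

The LC-MS simulator uses a linear response with multiplicative noise and
internal-standard scaling, `A = (m·c + b)(IS/IS_mean)(1 + cv·ε)`; at zero
noise, quantification is an exact identity on the true mass, which anchors
the round-trip tests. The fluorescence renderer draws disjoint capsule
cells, a membrane outline channel, and Gaussian foci (σ = 2 px) at stated
fractional axial positions over Gaussian background noise.

**What the phantoms do not emulate:** electron-optical contrast, tomographic
noise, the missing wedge, CNN segmentation errors, non-spherical granules,
or cell curvature. Passing recovery tests therefore validates the
measurement arithmetic and its voxel-scale error bounds — not robustness to
imperfect real segmentations. An optional label-noise hook flips granule
boundary voxels for light perturbation studies.

## Known limitations and open ends

- Published volume-to-surface-area ratios from segmentation models depend
  on the (unstated) surface estimator of the original toolchain; they are
  not reproducible from summary statistics, and this package fixes and
  documents its own estimator instead. Both per-cell-averaged and pooled
  ratios are emitted; neither is asserted against published values.
- Published per-cell PHB masses for growing cells are not arithmetically
  consistent with the published granule counts and diameter law
  (~7 × πd̄³/6 × ρ overshoots the published mean several-fold); the phantom
  cohorts therefore validate against their own generator's closed-form
  expectations, while the published masses enter only the exact fold-change
  identities.
- The per-granule small-object filter (8 voxels) is resolution-dependent:
  at coarser voxel sizes it removes proportionally larger granules.
- Distance records flag, but do not resolve, cross-pole nearest-neighbor
  pairs; a principled pole-assignment rule would need the cell septum.
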