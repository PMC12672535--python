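# Methods

This note records the models behind each module, the parameter choices that
matter, the numerical conventions, and what the synthetic phantoms do and do
not establish about real data.

## The synthetic lymph node

`phantom.generate_phantom` builds a voxelised node from a `PhantomSpec`. The
geometry is a set of concentric ellipsoidal shells in the normalised
coordinate ρ (ρ = 1 on the organ surface):

| region | definition | class |
|---|---|---|
| adjacent tissue | 1 < ρ ≤ 1.05 | `adjacent_tissue` (+ `outer_vasculature` tubes) |
| subcapsular sinus | 0.95 < ρ ≤ 1 | `subcapsular_sinus` |
| deep cortical unit | ellipsoid of radius fraction 0.42 displaced to ζ = −0.40 | `dcu` |
| medulla | interior with ζ ≥ 0.12 (ζ = normalised z) | base `parenchyma` |
| cortex | the remaining interior shell | base `parenchyma` |

ζ is the normalised coordinate along the pole axis, so the DCU sits at one
pole and the medulla at the other — follicles are cortical, nodules
medullary, reproducing the topology that the analysis assumes without any
anatomical fitting. Within the medulla, sinus lumina are drawn as
overlapping ellipsoidal blobs (25–60 µm) until 8 % of the medulla is sinus.
Discrete objects (follicles, nodules, adipocytes) are ellipsoids placed by
rejection sampling with three rules that matter for the statistics:

1. **Sizes are drawn first, positions second.** Re-drawing a size after a
   failed placement would bias the realised law small near compartment
   boundaries; drawing the whole size multiset up front and placing
   largest-first preserves the law exactly (packing order is irrelevant to
   it) while letting big objects find room.
2. **A two-voxel separation margin** (> √3, the 26-connectivity diagonal)
   keeps distinct objects distinct under component labelling.
3. **Strict containment** in the host region; a bounded attempt budget
   (10 000 per object) turns an over-packed compartment into an explicit
   `PlacementError` naming the compartment.

The phantom represents the *embedded* specimen: object sizes are native
sizes × (1 − s) with s = 0.30, the resin-embedding shrinkage. The nodule
size law is a truncated normal whose location is re-solved so the
*truncated* mean equals the requested mean (reported size laws are means
over the observed, in-window population, so the generator reproduces that
moment rather than the latent one). The truncation window defaults to
(30, 172) µm embedded scale — slightly inside the (30, 180) µm morphological
window so that digitised Feret measurements, which overshoot by about half a
voxel, never push a generated nodule out of the window. Nodule axis ratios
are uniform in [0.7, 1.0] ("spherical to ovoid"); orientations are
axis-aligned with a random axis permutation, a deliberate simplification
that keeps the maximum-axis/Feret relation exact.

Capillaries are 3-voxel-thick capsule segments (length 4–12 voxels) confined
to their host compartment and converted from host voxels until the converted
fraction reaches the configured per-compartment target, so the realised
density `converted / original-host-voxels` equals the configuration up to
one segment (well within the 10 % acceptance band).

Intensity is a per-class base level (follicles and nodules brightest,
lumina darkest, matching the contrast ordering of lead-stained phase
tomograms) plus Gaussian noise (σ = 0.05). No intensity statistics are
published for the real classes; the contrast is stipulated, not fitted, and
nothing downstream depends on its absolute values.

### Packaged configurations (`presets`)

* **Mandibular pairs** (nodule census): counts 28/29 (young) and 59/60
  (old), whose means are the reported 28.5 and 59.5. The node semi-axes
  (427 × 470 × 534 µm) are *derived*, not free: they are the unique size at
  which 59.5 nodules of the 90 ± 27 µm embedded law occupy the reported
  4.7 % of node volume. Fixture pitch is 4.8 µm so the smallest in-window
  nodule (30 µm ≈ 92 voxels) stays comfortably above both the sphericity
  floor (8 voxels) and any noise-removal threshold; the native 1.8 µm pitch
  is kept for single-object experiments, where a whole node is not needed.
* **Vasculature phantom** (256³, 7.2 µm): capillary fractions 0.10 (DCU),
  0.22 (follicles), 0.218 (nodules), 0.05 (parenchyma), i.e. the reported
  follicle/DCU = 2.2 and nodule/DCU = 2.18 ratios over a stipulated DCU
  reference density of 0.10 (only the ratios are published).
* **Young popliteal phantom** (3.6 µm pitch): 15 adipocytes of 28–63 µm
  embedded diameter (40–90 µm after correction); node semi-axes again
  derived from self-consistency with the reported 0.26 % volume share. The
  finer pitch keeps the small adipocytes well rasterised.

`simulate_shrinkage` contracts all linear dimensions by (1 − s) via
`scipy.ndimage.zoom` (trilinear for intensities, nearest-neighbour for
labels, edge-aligned coordinate mapping, which measured most faithfully on
digital-ball oracles); `voxel_um` is unchanged because the specimen shrinks,
not the detector.

## Preprocessing

Background subtraction returns `img − G_σ(img) + mean(img)`; adding back the
global mean keeps the result in the original range (the published pipeline
does not state its offset handling; subtraction rather than division was
chosen and is noted here — "Gaussian blur background subtraction" reads most
naturally as subtractive). The unsharp mask uses the renormalised
subtractive form `(img − w·G_r(img)) / (1 − w)`, the common
imaging-software meaning of a weight parameter. Flat-field correction
divides by the Gaussian-smoothed feature-empty reference (σ_ff default
50 px; σ_ff = 0 divides by the raw reference) with an ε-guard and unit-mean
rescale. Stitching refines each tile's nominal offset by phase correlation
against the already-placed tiles, constrained to ±8 px, trusting the pair
with the widest overlap (ties prefer the smaller displacement), then blends
with separable tent weights normalised to sum to one at every covered
pixel — constant tiles therefore stitch to an exactly constant composite.
8-bit conversion exists only as a lossy export (`to_uint8`), not on the
analysis path, and no JPEG path is provided (storage detail without analytic
effect).

## Registration

The imaging model is `img = A(slice(vol, pose))`: `pose` is a rigid slice
pose (rotations rx, ry, rz in degrees applied z·y·x, translations in voxels
relative to the volume centre, right-handed (x, y, z) frame) and `A` an
in-plane affine (sx, sy > 0, shear k, rotation θ2d). The optimizer compares
`slice(vol, pose)` with `A⁻¹(img)` under histogram mutual information
(dense joint histogram, per-image min–max binning, 64 bins, fill pixels
masked out rather than penalised; at coarse pyramid levels the bin count is
shrunk to ≈ √(n/5) so bins stay populated). Partial-volume interpolation
was rejected in favour of the dense histogram for determinism.

The search is a deterministic coordinate-descent hill-climb in the fixed
order (tz, rx, ry, tx, ty, θ2d, sx, sy, k) — plane depth and orientation
first — over a pyramid (8, 4, 2, 1) of block-mean-downsampled arrays, with
all steps halved after a sweep without improvement (initial steps 4°/4 vox/
0.04, floors 0.125°/0.125 vox/0.002). Ties keep the current value;
registering the same pair twice is bit-identical. The published description
says "minimizing the mutual information metric"; MI between matching images
is maximal, and the pipeline's own inversion step exists to make contrasts
match, so this implementation maximises MI (equivalently minimises its
negative) and says so rather than guessing further. If the optimizer ends
below the initialisation's MI (a capture failure — possible because coarse
levels optimise a slightly different objective), the initialisation is
returned and the result carries `fallback_to_init=True`; failures are
flagged, never silent. Binarised MI (Otsu, 2×2 joint histogram) is a
schedule switch, off by default, since whether the cited pipeline binarises
at all levels is unstated.

`reapply_full_res` re-applies the saved affine to the full-resolution
micrograph (integer upscale enforced) and bilinearly upscales the registered
CT slice onto the same grid; `refine_region` freezes the plane (rx, ry, tz)
and re-optimises only in-plane parameters for zoomed images.

Measured on the structured 128³ phantom over the capture range (|r| ≤ 10°,
|t| ≤ 10 voxels, shear ≤ 0.1; 20 poses), median absolute errors are below
1° / 0.3 voxel / 0.003 shear (`analysis/04_registration_recovery.py`); a
minority of extreme-corner poses escape capture, which the median-based
contract tolerates by design.

## Morphometry

* **Components**: 26-connectivity, ordered by the raster position of each
  component's first voxel for reproducible ids.
* **Feret**: maximum pairwise distance between surface-voxel centres
  (computed on the convex hull's vertices; brute force on degenerate
  objects) plus one voxel pitch, so a single voxel has Feret = voxel size.
  Digitisation makes measured Feret overshoot the continuous diameter by
  roughly half a voxel on average.
* **Sphericity**: ψ = π^{1/3}(6V)^{2/3}/A with A from boundary-face
  counting corrected by the lattice factor 0.735 (face counting
  overestimates areas on a cubic grid; the corrected estimator yields
  ψ ≈ 0.9 for large digital balls and ≈ 0.59 for a 1×1×20 rod). Needs ≥ 8
  voxels.
* **Nodule criteria**: medullary centroid, ψ ≥ 0.6, Feret in (30, 180) µm
  embedded scale. The molecular criterion (LYVE-1⁺ encapsulation) is not
  computable from geometry and is excluded. The medullary region is
  reconstructed from the labels as the convex span of the medullary-sinus
  system (the medulla is convex here: ellipsoid ∩ half-space), tested via
  Delaunay membership on a 4 000-point subsample, with a 60 µm margin
  applied toward the hull: the sinus-derived region is inward-biased by
  about one nodule radius because nodules locally exclude sinus lumina.
  Follicle centroids sit ≥ 100 µm outside the reconstructed region, so the
  margin cannot leak cortical objects in. The exact medulla definition used
  manually in the original analysis is unstated; this rule is the package's
  own operationalisation and is configurable.
* **Capillary density** is defined as the capillary volume fraction of a
  compartment (the source work does not define its measure): capillary
  voxels are attributed to the compartment of their nearest non-capillary
  voxel (Euclidean distance transform), and density =
  attributed / (compartment + attributed). Ratios of densities are reported
  compartment-pair-wise; with one phantom per run the ratio of means and
  mean of per-node ratios coincide.
* **Volume fractions** are percentages of the whole-node mask (all classes
  except background and adjacent tissue) and sum to 100 % by construction.
* **Group comparison**: two-sided Wilcoxon rank-sum (Mann–Whitney U), exact
  enumeration when both n ≤ 8 without ties, normal approximation with
  continuity correction otherwise; stars at P ≤ 0.05 / P ≤ 0.01.

## Proteomics statistics

Abundances are log₂; `total_sum_normalize` emulates "normalised to total
protein amount" as per-sample total-sum scaling of linear abundances before
the log. Proteins quantified in < 60 % of any group's samples are dropped
before testing (the source is silent on missingness). The adaptive test
gates on Shapiro–Wilk normality in *all* groups of the contrast
(p > 0.05); zero-variance groups fail the gate; the parametric branch is
Welch's unequal-variance t-test (the robust default where pooled vs Welch
is unstated). The four contrast families (mandibular vs subiliac as mean /
young / old, and old vs young within each site) difference group means of
log₂ values; "mean" contrasts average the two age-group means per site
first. BH adjustment is statsmodels' step-up FDR. The age-independent
filter removes proteins with log2fc > 0 and q ≤ 0.05 in *both* old-vs-young
comparisons; these thresholds are exposed parameters, not asserted as the
original choice, which is unstated. Volcano categories: strong
(fold ≥ 2, q ≤ 0.05), moderate (1.5 ≤ fold < 2, q ≤ 0.05), none.

ssGSEA follows the rank-weighted running-sum convention: proteins ranked by
abundance per sample (average ranks on ties), in-set steps weighted by
rank^0.25, score = summed difference between the weighted in-set ECDF and
the uniform out-of-set ECDF; scores are rank-invariant per sample and
visualised as row-wise z-scores. Pre-ranked GSEA uses the classic weighted
Kolmogorov–Smirnov ES (weight |t|) on per-protein Welch t-statistics —
limma-style moderated t is deliberately out of scope, a documented deviation
from the original cross-check — with a null of random same-size sets,
NES = ES / mean |same-sign null|, and p = (1 + #{|null| ≥ |ES|})/(1 + nperm)
(plain permutation p with the +1 correction instead of fGSEA's adaptive
multilevel estimate: deterministic and desk-scale). GO-style enrichment is
provided only as a hypergeometric over-representation test against
user-supplied sets; no external annotation database is consulted.

Calibration, measured by the suite: on Gaussian nulls (1 000 proteins,
n = 10/group) the adaptive test rejects at 0.049 ± 0.007 at α = 0.05
(mean over seeds); at site effects of 1.5 log₂ units power exceeds 0.8 and
empirical FDR at q ≤ 0.05 stays below 0.10.

## What the phantoms do and do not show

The phantoms carry the *statistical structure* the analysis assumes — known
object counts, size laws, compartment fractions, capillary fractions, pose
ground truth — so every pipeline stage can be checked for exact recovery.
They do not emulate X-ray physics, phase-contrast or reconstruction
artifacts, vascular tree topology, anisotropic shrinkage, real class
contrast statistics, or segmentation error: passing tests demonstrate that
the measurement chain is unbiased on clean geometry at matched scales, not
that a trained segmenter would reproduce these numbers on raw tomograms.
Branching-order analysis, HEV detection and cell-scale SEM morphometry are
out of scope.

## Problem sizes and seeds

Fixture phantoms are 196×212×240 at 4.8 µm (about 10 Mvoxel), the
vasculature phantom 256³ at 7.2 µm, the popliteal phantom 228×252×276 at
3.6 µm — sizes chosen so a whole node fits in memory at a pitch where the
smallest analysed objects stay well resolved. Every stochastic path draws
from one seeded `numpy.random.Generator`; identical configuration + seed is
bit-identical, and `scripts/acceptance.py` derives per-stage seeds from its
single `--seed` argument.
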