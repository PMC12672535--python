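# lymphomorph

Quantitative machinery for whole-organ lymph-node (LN) morphometry and the
statistics around it: synthetic LN phantom generation, tomography/SEM image
conditioning, mutual-information slice-to-volume registration, compartment
morphometry (nodule counting, 3D Feret diameters with shrinkage correction,
capillary densities, volume fractions), and adaptive proteomics
differential-abundance plus gene-set enrichment statistics.

## The problem

Synchrotron micro-CT of murine lymph nodes (isotropic 1.8 µm pitch) resolves
previously undescribed *medullary B-cell nodules*: spherical-to-ovoid,
cell-dense aggregates confined to the medulla of mucosa-draining nodes.
Quantifying them — and the accompanying vascular, lipomatous and proteomic
differences between mucosa- and skin-draining nodes — requires a chain of
fairly ordinary but fiddly computations:

* **Phantoms.** Real whole-organ volumes are enormous and scarce, so every
  stage here is exercised against a parametric LN phantom: an ellipsoidal
  organ with subcapsular sinus, cortical B-cell follicles, a deep cortical
  unit (DCU, the T-cell paracortex) at one pole, a sinus-threaded medulla at
  the other, nodules, adipocytes and per-compartment capillary networks —
  with known ground truth for every object.
* **Preprocessing.** Wide-Gaussian background subtraction (σ 300–500 px),
  unsharp masking (1.5 px, weight 0.4–0.6), histogram clipping and [0, 1]
  float32 normalisation for CT stacks; flat-field division, grid stitching
  with phase-correlation refinement and feathered blending, and contrast
  inversion for backscatter SEM mosaics.
* **Registration.** Given a 2D micrograph of a physical section, find the
  oblique *virtual slice* through the 3D volume that matches it, by
  maximising histogram mutual information over a rigid slice pose (three
  rotations, three translations) plus an in-plane affine (anisotropic scale,
  shear `x' = x + k·y`, rotation), coarse-to-fine with step halving.
* **Morphometry.** 26-connected components; maximum 3D Feret diameter
  (max pairwise surface-voxel distance + one voxel); sphericity
  ψ = π^{1/3}(6V)^{2/3}/A; the operational nodule definition (medullary
  centroid, ψ ≥ 0.6, Feret within 30–180 µm at embedded scale); capillary
  volume-fraction densities with nearest-label attribution; shrinkage
  correction `d / (1 − s)` with s ≈ 0.30 for resin embedding.
* **Proteomics.** log₂ abundances over a 2×2 site (mandibular/subiliac) ×
  age (young/old) design; per-protein Shapiro–Wilk-gated Welch t vs Wilcoxon
  rank-sum tests; Benjamini–Hochberg q-values; removal of proteins rising
  with age in both node types; volcano categorisation; ssGSEA (rank-weighted
  running sum per sample) and pre-ranked GSEA with a permutation null.

## Worked example

```python
import lymphomorph as lm
from lymphomorph.morphometry import NoduleCriteria, classify_nodules, \
    connected_components, volume_fraction
from lymphomorph.presets import mandibular_spec

vol, labels = lm.generate_phantom(mandibular_spec("old", 0))
crit = NoduleCriteria(min_voxels=8)
objs = connected_components(labels, "nodule", crit.min_voxels)
accepted = classify_nodules(objs, labels, crit)
print(len(accepted), round(volume_fraction(labels, "nodule"), 2))
```

prints `59 4.06`: all 59 generated nodules of the first old-mouse fixture
phantom survive the morphological criteria, and the nodule class occupies
4.06 % of the node volume. The numbered drivers under `analysis/` run the
full studies and write their tables to `results/`; for example
`python analysis/01_nodule_census.py` reports

```
mean young: 28.5 nodules, 2.02% of LN volume
mean old: 59.5 nodules, 4.62% of LN volume
mean accepted nodule Feret (embedded): 92.8 µm; corrected: 132.6 µm
```

i.e. the census doubles with age by construction and the embedded-scale
Feret distribution recovers its configured 90 µm law, which the 30 %
shrinkage correction maps to ≈ 130 µm native scale.

A command-line interface mirrors the library stages:

```bash
lymphomorph phantom --config spec.yaml --out DIR --seed 42
lymphomorph preprocess ct IN.tif OUT.tif
lymphomorph register --volume ct.tif --image sem.tif --out result.yaml
lymphomorph morph --labels labels.tif --out DIR
lymphomorph proteo diff --matrix m.csv --design d.csv --out DIR
lymphomorph fixtures --seed 42 --out tests/fixtures
```

## Layout

```
src/lymphomorph/   phantom, preprocess, register, morphometry, proteomics,
                   presets, pipeline, io, cli
analysis/          numbered narrative drivers writing tables to results/
tests/             unit, property and end-to-end acceptance tests
docs/methods.md    models, parameter choices, numerical conventions, limits
```
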