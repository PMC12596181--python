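# cryoset

Curated, quality-filtered voxel datasets from cryoEM density maps and
their fitted atomic models.

Deep-learning tools for cryoEM structure modeling (secondary-structure
segmentation, backbone tracing, nucleic-acid group detection) train on
map/label voxel pairs assembled from the EMDB and PDB. Assembling such
a dataset well is most of the work: public depositions are redundant
(hundreds of near-identical ribosome reconstructions), inconsistently
scaled, and sometimes globally mismatched — a model covering half the
map, or density with no model under it. `cryoset` is a library (plus a
thin `cryoset` CLI) for the entire path from an EMDB metadata query to
an AI-ready dataset, for researchers building or retraining such
models.

## What it computes

**Two-tier redundancy filtering.** Each entry carries a merged set of
UniProtKB/AlphaFold cross-reference accessions *A*. The *uniqueness*
tier collapses groups with identical sets to the best-resolution
(smallest Å) member and flags entries with no cross-references; the
*similarity* tier sweeps entries best-resolution-first and discards any
entry whose overlap with an already-retained entry exceeds a threshold
(default 0.70). Overlap is containment |A∩B| / min(|A|, |B|) by
default, Jaccard |A∩B| / |A∪B| optionally; after the sweep every
retained pair has similarity ≤ the threshold. A Q-score filter
(default ≥ 0.4) runs first.

**Adaptive contour-anchored normalization.** Instead of clipping maps
at 0, a per-map threshold *t* is derived so that the deposition's
recommended contour level *c* sits at the 85th percentile of retained
density: with N voxels strictly above *c* and anchor fraction *p*,
retain k = round(N / (1 − p)) voxels, take *t* as the k-th largest
value, zero everything below, and map [t, v_max] linearly onto [0, 1].

**Volume Overlap Fraction (VOF).** Map and voxelized model are each
summed to 2-D along six directions — the X/Y/Z axes and three discrete
diagonal line families (constant (x−y, z), (x, y−z), (x−z, y)) — and
binarized at ≥ 1. VOF is the mean per-direction IoU excluding the
single highest-scoring direction; pairs below a threshold (default
0.82) are discarded. A Dice-like coefficient (overlap over the sum of
mask sizes) is reported alongside.

**Nearest-atom voxel labels and dataset assembly.** Each voxel center
within a radius (default 1.5 Å) of a selected atom gets the label of
the *nearest* such atom (ties → earlier file order). Atom selection is
three-tier: secondary-structure class (helix/sheet/coil/rna/dna, or
"none" for ligands), residue name, atom name. Map/label volumes are
cut into cubic patches (default 64³) with zero padding and split
train/val/test by entry (no leakage) or by subvolume.

**Voxel-wise evaluation.** Probability volumes are discretized (argmax
class if its probability exceeds 0.8, else background) and scored with
per-label and micro-averaged precision, recall, F1, and multi-class
accuracy.

## Worked example

`examples/` contains one narrative script per capability. Conditioning
and fitness scoring (`02`, `03`):

```text
$ python examples/02_condition_density_map.py
raw map: (24, 24, 24) voxels at 2.0 A, contour level 0.0408
resampled: (48, 48, 48) voxels at 1.0 A
denoise threshold t = 0.0164 (t <= contour 0.0408 <= max 1.1683)
normalized range: [0.0, 1.0]
fraction of retained voxels above the contour: 0.1500
```

The map is upsampled from 2.0 Å to the 1.0 Å training grid, and the
derived threshold leaves exactly 15% of the surviving voxels above the
contour — the contour sits at the 85th percentile of retained density,
as the normalization promises.

```text
$ python examples/03_score_map_model_fitness.py
well-fitted pair:
  per-direction IoU: {'X': 0.839, 'Y': 0.781, 'Z': 0.941, 'D_xy': 0.657, 'D_yz': 0.697, 'D_xz': 0.709}
  dropped direction: Z (highest IoU)
  VOF = 0.737   Dice-like = 0.423
misaligned pair: VOF = 0.000
```

The model the density was built from scores a high VOF (the flattering
Z view is excluded from the mean); the same model translated out of
its density scores 0.

The pipeline is also runnable from a shell:

```sh
cryoset fetch  --query "ribosome AND resolution:[3 TO 4]" --workdir work
cryoset curate --qscore-min 0.4 --similarity-max 0.7 --vof-min 0.82 --workdir work
cryoset build  --patch 64 --split 0.8,0.2,0 --seed 1 --workdir work
```

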