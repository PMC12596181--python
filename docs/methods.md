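# Methods

## Scope and data model

`cryoset` turns EMDB/PDB-style inputs into voxel datasets for
supervised learning. Its in-memory types are deliberately small: an
`Entry` (one deposition's curated metadata), a `DensityMap` (3-D grid,
per-axis voxel size in Å, world origin in Å), an `AtomicModel`
(ordered atoms with a three-tier identity), a `LabelVolume` (integer
grid on a map's frame), and a `CurationReport` whose per-stage
accounting always satisfies `retained + discarded + flagged = input`.
Grids use the node convention: `grid[i, j, k]` sits at world position
`origin + (i, j, k) · voxel_size`. Density values are stored as
float32, the precision of the MRC payload itself; all derived
thresholds are computed at that precision.

## Metadata curation

Cleaning removes entries missing a fitted PDB ID, a resolution, or a
recommended contour level, then collapses duplicate-ID and
duplicate-title groups. Wherever a group must be reduced to one
member, "best resolution" means the numerically smallest Å value, with
ties broken by lexicographically smallest EMDB ID, so every reduction
is deterministic. The Q-score filter discards entries strictly below
the threshold (default 0.4); entries with *no* deposited Q-score also
fail, with a distinct reason, rather than passing silently — an
unscored map gives no evidence of quality.

Redundancy filtering treats the merged, deduplicated union of
UniProtKB and AlphaFold accessions as a proxy for structural content
(AlphaFold references are UniProt-derived, so merging loses nothing; a
per-namespace mode exists for users who disagree). Tier one removes
exact set duplicates and flags cross-reference-less entries for manual
review. Tier two is a greedy sweep in best-resolution-first order: an
entry is kept iff its similarity to every already-kept entry is ≤ the
threshold. Greedy sweeping (rather than connected-component
clustering) was chosen because it directly yields the guarantee the
filter is for — *no retained pair exceeds the threshold* — and always
keeps the best-resolution representative of any redundant
neighborhood. Similarity defaults to containment |A∩B|/min(|A|,|B|):
a sub-complex whose references are a subset of a larger complex's is
redundant with it, which Jaccard would understate; Jaccard is
selectable where that behaviour is unwanted.

## Map conditioning

Resampling maps each output node `j` (at world `origin + j·target`) to
input index `j·target / voxel` and interpolates with an order-3
spline, edge-clamped; output dimensions are round-half-up of
`dim · voxel/target` per axis. Implementing the coordinate mapping
explicitly (rather than relying on a zoom routine's endpoint
convention) keeps the node positions exactly on the stated grid, which
the linear-ramp test exploits. Spline order is configurable; order 1
guarantees outputs bounded by the input range. Anisotropic inputs
resample per-axis to one isotropic target.

Adaptive normalization anchors the deposition's recommended contour
level `c` at percentile `p` (default 0.85) of the retained density:
with `N_above` voxels strictly above `c`, retain `k = round(N_above /
(1 − p))` voxels, set the threshold `t` to the k-th largest value,
zero values below `t`, and map `[t, v_max]` linearly to [0, 1].
Percentiles are nearest-rank on an ascending sort and "above" is
strict, which makes the closed form exact (the worked example: 100
distinct values, contour 92.5 → N_above = 8, k = 53, t = 48, and the
85th percentile of the retained set is 93, one rank from the contour).
Two conditions abort normalization for an entry: `N_above = 0` (the
contour clears the whole map) and `k >` voxel count (the contour is
below the map's own p-percentile). Aborts are tallied in the curation
report as unsuccessful normalizations and drop the entry, never the
batch. Conditioning order is resample first, then normalize, so the
anchor percentile is computed on the grid the labels will live on.

## VOF map–model fitness

The fitness score asks a global question Q-scores cannot: does the
model occupy the density and the density support the model,
*everywhere*? The normalized map and the voxelized model (voxel = 1
iff its center is within the radius of a heavy atom; default radius
equals the 1.5 Å labeling radius) are summed to 2-D along six
directions and binarized at ≥ 1. The three diagonal projections are
exact discrete line sums over families of constant (x−y, z),
(x, y−z), (x−z, y), with the difference index offset to be
non-negative — no interpolation, so a brute-force loop reproduces
every pixel bit-for-bit. Per direction, IoU = |A∩B|/|A∪B| and a
Dice-like score = |A∩B|/(|A|+|B|). The VOF is the mean IoU excluding
the single highest-scoring direction (ties: the first in the fixed
order X, Y, Z, D_xy, D_yz, D_xz is dropped); the Dice-like aggregate
excludes the same direction for symmetry. Two empty projections agree
vacuously (both scores 1 — an empty direction carries no mismatch
evidence); exactly one empty projection scores 0. Identical non-empty
masks therefore score IoU 1 but Dice-like ½ — the Dice-like value is a
companion diagnostic, not a second pass/fail score.

## Labels and dataset assembly

A label specification is an ordered list of (selection rule, label ≥
1) pairs plus a radius. Selection rules constrain any subset of three
tiers — secondary-structure class, residue name, atom name — with the
ss value "none" selecting only non-polymer atoms (the ligand path).
Secondary structure comes from deposited annotations (HELIX/SHEET
records, struct_conf/struct_sheet_range); files without annotations
default protein residues to coil, logged, since recomputing geometry
is out of scope. Multi-model files contribute the first model only,
and only first alternate locations.

Labeling assigns each voxel within the radius of ≥ 1 selected atom the
label of the nearest one. Atoms are processed in file order with a
strictly-closer update, so exact distance ties deterministically keep
the earlier atom; an atom matched by several rules takes the first
matching rule's label. Cross-rule conflicts therefore resolve by
geometry (nearest atom), not rule priority.

Partitioning places patch corners at stride multiples with per-axis
count `ceil(dim / stride)` and zero-pads edge patches (dropping them
would bias against map borders; an optional minimum-labeled-fraction
filter exists, off by default). Splitting shuffles with a seeded
generator and assigns by cumulative rounding, so realized counts are
within one unit of the targets. The default granularity is *entry*:
all patches of one deposition stay in one split, preventing a
structure from leaking between train and validation; per-subvolume
splitting is available where that leakage is acceptable.

## Evaluation metrics

Discretization assigns the argmax non-background class when its
probability strictly exceeds the threshold (0.8 for the
secondary-structure setting, 0.4 for nucleic-acid atom groups), else
background; exact argmax ties go to the lowest class index. Confusion
counts are one-vs-rest per label over all voxels. Aggregate
precision/recall/F1 micro-average the non-background labels, while
overall accuracy is multi-class voxel agreement (background included)
— the two aggregates answer different questions and are reported side
by side. Zero-denominator metrics are defined as 0 and carry an
explicit `undefined` flag instead of NaN, so downstream tables stay
numeric without hiding the degeneracy.

## Synthetic data

The fixture generator emulates only what the pipeline computations
depend on. Maps are sums of unit-amplitude isotropic Gaussians on
pseudo-atom positions — an ideal α-helix Cα trace (2.3 Å radius,
1.5 Å rise, 100° twist), a two-strand nucleic ladder of P/C4′ atoms,
or uniform random coil — plus optional Gaussian noise; the contour
level is the (1 − f) quantile so a known fraction f of voxels exceed
it (f < 0.15 guarantees the adaptive threshold is derivable). Models
are written with annotation records consistent with their layout, so
parsing round-trips the intended secondary-structure classes.
Metadata tables realize a requested overlap structure exactly:
identical-set duplicate groups, nested subset chains (containment 1),
disjoint singletons, and empty-set entries, with Q-scores uniform on a
configurable range. What this does *not* emulate: CTF, realistic
noise spectra, B-factor variation, deposition errors, or the actual
marginal distributions of EMDB metadata. Passing tests therefore
demonstrate the correctness of the computations and the bookkeeping,
not the field-realism of any particular threshold value.

## Problem sizes and numerical choices

Tests and the acceptance script run on grids of 8³–100³ voxels and
metadata tables of tens of entries — sizes at which every oracle
(triple-loop labeling, explicit line-sum projections, exhaustive
threshold scans, per-voxel tallies) is exact and the whole suite
completes in seconds; the computations are size-independent, so these
sizes exercise the same code paths as deposition-scale maps. Network
retrieval is exercised only through the offline cache path; online
fetching uses stdlib HTTP with bounded retries and an on-disk JSON
cache, and completed downloads are skipped on rerun.

## Known limitations

- Secondary structure is trusted from deposited annotations; models
  deposited without them are labeled all-coil.
- The VOF voxelization radius is a convention (default = labeling
  radius); absolute VOF values shift with it, so thresholds should be
  calibrated per radius.
- The EMDB record adapter accepts a canonical field naming (plus
  common aliases); exotic API response shapes may need a custom cache.
- Entries are processed whole; maps too large for memory are not
  streamed.
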