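# Methods

`opscreen` implements the computational chain of an optical pooled
screen: cells carrying barcoded protein variants are imaged over many
sequencing cycles, each cell's variant is decoded from the images, and the
morphological consequences of each variant are summarized, scored, and
clustered.  This note records the models, the parameter choices, what the
synthetic data does and does not emulate, and the numerical decisions a
maintainer would want to know about.

## Stitching and registration

All tiles from all imaging cycles are nodes of a single offset graph.
Intra-cycle edges join tile pairs whose stage-predicted overlap area is at
least a full-length band `min_overlap_px` (default 8) wide; this area form
keeps adjacent seams and excludes the small corner square shared by diagonal
neighbours, whose minimum overlap *extent* is otherwise indistinguishable
from an adjacent pair's.  Inter-cycle edges join the same tile across all
cycle pairs by default (`consecutive` is available for large cycle counts).

Each edge's translation offset comes from phase cross-correlation with
10x-upsampled subpixel refinement.  Two spectral normalizations are tried
(phase-normalized, which is sharp on feature-rich content, and plain
correlation, which is stable on smooth content) and the FFT wrap-around
ambiguity contributes up to four candidate offsets per run; the candidate
whose implied overlap scores the highest normalized cross-correlation (NCC:
dot product of mean-centered, unit-normalized overlap patches) wins.

Edge pruning uses a null NCC threshold: the 95th percentile of the scores
the *full estimator* reports on randomly chosen non-overlapping tile pairs.
Running the estimator itself (rather than scoring random offsets) matters:
the estimator maximizes NCC over its candidates, so a signal-free estimate
is an extreme value of the pointwise null, and a threshold calibrated
against single random offsets sits several-fold too low to catch real
estimation failures.  A second, stage-consistency veto removes edges whose
offset deviates from the stage-predicted delta by more than 8 MADs + 3 px
(robust statistics over all edges); stage repeatability is a few pixels, so
this only fires on gross failures.  Pruned-off portions of the graph are
reconnected with `inferred` edges whose offsets come from an affine model of
offset on stage-position deltas fitted to the surviving edges.

Global positions minimize the summed absolute residual of all edge
equations (`pos_b − pos_a = offset`), solved per axis as a linear program
(HiGHS) with slack variables; the y and x systems decouple.  The anchor
(lexicographically smallest node) is pinned at the origin to remove the
translation gauge.  The L1 objective bounds the influence of any remaining
bad offset, unlike least squares, which spreads it over the whole layout.
Because L1 is robust but statistically inefficient, an optional refinement
(on by default in `stitch`) re-solves by least squares restricted to edges
with residual ≤ 3 px, iterating the classify/solve cycle up to three times;
this recovers L2's averaging efficiency without re-admitting outliers.
Robustness has a breakdown point: if the edges crossing some graph cut are
half (or more) corrupted and agree on a wrong shift, no estimator can
recover the far side, so the robustness experiments draw corruption
patterns and keep only ones whose idealized noise-free instance the L1
solve inverts exactly — a geometric property fixed before the measured
offsets are consulted.

Composites use a feathered weighted average: weight = distance to the
nearest tile edge, floored at 1e-6, so the overlap midline averages both
tiles equally and seams blend linearly.  Multi-cycle composites share one
canvas (common origin) so cross-cycle pixel identity is preserved.

## Read calling

The rolony signal model: a diffraction-limited dot, present in exactly one
of four channels per cycle, hopping channels as the barcode is read.  The
filter chain per cycle and channel: subtract a σ=4 Gaussian blur (removes
cell background), z-score normalize (equalizes channels), subtract the
per-pixel second-largest channel (cancels debris present in all channels
while leaving single-channel dots intact), smooth with a σ=1 blur.  A
per-pixel standard deviation across cycles (population convention, ddof=0),
summed over channels, highlights exactly the pixels whose channel identity
fluctuates; Laplacian-of-Gaussian blob detection (σ ∈ [1, 3]) finds rolonies
there.  The absolute LoG threshold is a free parameter; the default (0.8)
was calibrated on synthetic stacks so that an empty (pure-noise) image
yields fewer than one false detection per megapixel while SNR-8 rolonies
are detected with recall ≥ 0.99.

Base intensities are sampled from the background-subtracted, z-scored stage
of the filter chain (before second-max subtraction; a config switch allows
the fully filtered stage), after grey dilation with a radius-2 square
footprint so the dot's maximum is sampled even when the detection is a
pixel off.  The base is the argmax channel (exact ties break to the lowest
channel index with quality 0); per-cycle quality is the top-two margin.

Genotypes are assigned by Levenshtein distance (edlib) to the lookup table;
a read equidistant from two distinct genotypes is a no-call.  In the
dual-barcode dialect the read splits at the first barcode's length, each
half matches its own column independently, and only an ordered pair present
in the table yields a call.  Distances are returned even when they exceed
the dialect's cap (1 single, 2 dual) — cell-level filtering happens later.

## Genotyping and filters

Nuclear label masks can be expanded up to 25 px (Euclidean distance
transform; labels never merge) to approximate whole-cell masks where only
nuclei segment reliably.  Reads on mask background are discarded.  A cell's
consensus barcode is the per-position plurality over its reads (positional
tie → most frequent whole read; residual tie → no consensus); the doublet
signal `n_distinct_barcodes` counts distinct lookup barcodes among the
cell's reads.  Population filters run in a fixed order — consensus distance
cap, doublet removal, barcodes in < 10 cells, variants with < 5 distinct
barcodes — and are idempotent.  The per-barcode cell counts are taken after
the distance filter; the order is documented because the thresholds
interact.  The bundled desk-scale demo lowers the two abundance thresholds
to 1 because its simulated screens have tens of cells, not millions; the
dialect defaults carry the production values.

## Profiles

A variant's profile concatenates per-feature medians and 1-D
earth-mover (Wasserstein-1) distances from the pooled WT cells.  Features
whose EMD is irreproducible within WT are removed first: for 25 random
half-splits of the WT cells, score = EMD(half₁, half₂)/MAD (MAD unscaled);
scores are averaged per feature and features above Q1 + 1.5·IQR (quartiles
taken across features) are dropped.  The threshold direction is as
specified even though an upper-quartile fence would be more customary; the
multiplier and the quartile population are configurable.  Selection then
drops blocklisted names (orientation/position patterns), low-variance
columns, and the lower-variance member of any pair correlated above 0.95
(greedy, descending-variance order, deterministic).  Normalization z-scores
each column against the synonymous variants (single-barcode dialect) or
against all variants (dual dialect); zero-SD columns are dropped.

Illumination correction subtracts the per-pixel 5th percentile across
fields sharing a position in the well; bleed-through correction subtracts a
scaled source channel, floored at zero, with a Theil–Sen helper to estimate
the coefficient from source-dominated pixels since no coefficient is part
of the data model.

## Scores

* **Impact score** = ½(1 − cos) between a profile and the per-column median
  synonymous profile; 0 for wild-type-like, ½ for orthogonal, 1 for
  anti-correlated.  Zero-norm profiles are NaN-flagged, not scored.
* **KS tests** are two-sided two-sample per feature.  The batched
  implementation computes the exact D statistic by pooled sorting with tie
  handling and the asymptotic p-value on the same formula scipy uses
  (`kstwo.sf(D, round(nm/(n+m)))`); scipy's per-pair exact mode is available
  and is the oracle in the tests.  Bonferroni spans features x variants by
  default; the family size is recorded in every output row.
* **Hit features**: Bonferroni p < 0.001 in ≥ 25 variants (boundary
  inclusive).
* **Landmark calls**: EMD-z mode requires z > 2.5 one-sided (an EMD grows
  from zero under any perturbation, so only the upper tail means anything);
  median-z mode requires |z| > 2.5; both require Bonferroni KS p < 0.01;
  all thresholds strict.
* **Mislocalization**: OLS of the localization feature on abundance and
  activity across variants; the score is the residual standardized by the
  residual SD (ddof = number of regressors).  Residual SDs below numerical
  noise (perfect fits) give all-zero scores rather than amplified rounding
  error.  Collinear designs raise with the condition number.
* **Interface calling** profiles, per chain position, the minimum C-beta
  distance to any other chain, finds local minima along the sequence
  (strict neighbours; equal-value plateaus are one minimum; a constant
  profile is one degenerate minimum covering everything), and labels
  interacting every position within 1.5 Å of its nearest minimum's depth.
  The rule has no absolute distance cutoff by design; an optional
  `max_distance` guard (off by default) vetoes calls at implausible ranges.

## Embedding and clustering

PCA keeps the fewest components explaining 70% (single-barcode screen) or
60% (dual) of variance.  The kNN graph is the undirected union of each
node's k = 25 cosine nearest neighbours (ties break by index).  Louvain
runs at resolution 1.0 with an explicit seed; communities are relabelled by
smallest member so labels are reproducible.  UMAP is visualization only —
the contract is shape, finiteness, and determinism given a seed.
Cluster-characterizing features use Mann–Whitney U per (feature, cluster)
against all other variants, filtered by two robust z effect sizes (vs all
variants and vs synonymous variants, both |z| > 1.5) and ranked by
ascending p with deterministic tie-breaks.  Position-level structure
averages PCA vectors per mutated position and cuts an average-linkage
dendrogram on correlation distance at a fixed cluster count (count-based
cut; the alternative height-based cut was not needed).

## Classifiers

Per-variant distinguishability: XGBoost on the selected features, variant
vs WT, stratified 8:1:1 train/validation/test, early stopping on validation
log-loss (50 rounds), AUROC on the untouched test stratum; variants under
150 cells are skipped.  Defaults are shallow trees (depth 3), learning rate
0.05, up to 800 rounds: on morphology-like tabular features with modest
mean shifts this tracks the Gaussian closed form Φ(d/√2) for a d-SD
single-feature shift, where deeper trees underperform by overfitting noise
features.  WT is subsampled to 10x the variant count before splitting.
The multiclass clinical procedure trains a linear SVC on landmark features
and macro-averages one-vs-rest ROC curves on a common specificity grid with
equal class weight; decision scores are 5-fold cross-validated so the curve
is out-of-sample.  Two caveats this implies: an identical pair of classes
plus one separable class yields per-class AUCs near (0.75, 0.75, 1), not
(0.5, 0.5, 1), because a one-vs-rest score still ranks a class above the
distant one; and under label permutation cross-validated scores on
*structured* features are pessimistically biased below 0.5 (the familiar CV
anti-learning effect), so chance-level calibration is asserted on
structureless data, where it holds.

## Synthetic data

The generators are pure functions of configuration + seed (no global RNG).
Tile grids render one global scene per run — static correlated texture
shared by all cycles plus a 20%-amplitude per-cycle component — and crop
each tile at its true position, adding unit-SD read noise; "SNR" is the
texture SD in noise units, so it is unambiguous.  Rolony stacks place
isotropic Gaussian point sources (σ ∈ [1, 3] px) whose per-cycle channel
follows the barcode, over white noise plus an optional low-frequency
all-channel cell background that exercises the second-max suppression.
Feature tables draw WT cells from per-feature Gaussians (a t with 5 df
option stresses robust statistics) and shift/scale variant cells by the
planted effect and dispersion matrices; synonymous variants are forced to
null at construction.  Barcode tables are rejection-sampled to a minimum
pairwise Levenshtein distance.

The integrated screen (`simulate_screen`) ties the pieces together: disk
cells scattered over the stitched scene, each expressing one variant
through a few rolonies near its centre, imaged as a jittered tile grid.

What the fixtures do *not* emulate: real point-spread functions and optical
aberrations, spectral crosstalk between channels, sequencing
phasing/prephasing, cell-shape segmentation errors, batch and well effects,
or CellProfiler's actual feature definitions.  Passing tests therefore
demonstrate correctness of the algorithms under the stated signal models
and calibration of the statistics under those nulls — not performance on
real microscopy data.

## Problem sizes

The test and acceptance workloads are scaled for a desk run: stitching uses
4x4 grids of 128-px tiles over 2 cycles (5 seeds); read calling 500
rolonies over 8 cycles at SNR 8; genotyping oracle checks 10,000 reads
against a 100-code table; calibration 500 null replicates of a 300-feature
x 50-variant KS family at 100 cells per sample; landmark operating
characteristics 120 variants x 3,000 cells; classifiers 2,000 cells per
class.  The integrated demo screen is a 3x3 grid with ~70 cells and 12
variants, with abundance filters scaled accordingly.

## Known limitations

* Translation-only registration; no rotation, affine, or chromatic
  correction.
* The LoG detection threshold is calibrated on the synthetic signal model;
  real data will need recalibration.
* No color-crosstalk estimation or phasing correction in read calling.
* The EMD reproducibility fence direction follows the stated procedure; on
  heavy-tailed feature sets it is aggressive and may remove many features
  (override via `SelectionConfig`).
* Louvain is run through networkx; modularity maximization is heuristic and
  only seed-level reproducibility is guaranteed.
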