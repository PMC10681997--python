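# Methods

This note documents the models and procedures `fragseq` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Fragment demultiplexing

**Barcode design.** `demux.design_barcodes` draws random DNA candidates and
greedily rejects any candidate within the minimum Hamming distance of an
accepted code, with a restart budget of 5000·n candidates and an immediate
capacity error for requests beyond the Singleton bound 4^(L−d+1). Any set
satisfying the pairwise-distance invariant is conformant; the invariant is
always re-verified post hoc by the O(n²·L) direct check. Barcode length is
a required parameter with a default of 8 nt (typical for lipid-hashing
chemistries); homopolymer/GC filters are off by default.

**Cell classification.** Per barcode, log1p UMI counts across cells are
split into a background and a signal component by one-dimensional 2-means.
Candidate thresholds are quantiles q ∈ {0.10, 0.15, …, 0.90} of the
interval between the two component centers; one global q is selected to
maximize the singlet fraction, the objective the established hashing
workflows optimize. A raw quantile of the per-barcode count distribution
would not work here: with B barcodes and roughly 1/B of cells positive per
barcode, any fixed count quantile ≤ 0.9 marks ~10% of cells positive per
barcode and floods the data with spurious doublets; anchoring the sweep on
the background/signal mode interval keeps the threshold between the two
populations regardless of the positive fraction. Calls: 0 barcodes above
threshold → NEGATIVE, 1 → POSITIVE, ≥ 2 → DOUBLET; the three sentinel
fragment ids (NEGATIVE, DOUBLET, UNASSIGNED) are reserved strings excluded
from every per-fragment statistic.

**Species mixing.** Assignment accuracy compares each cell's species with
its well's expected species. A fragment whose cells are 100% mismatched has
its well species flipped before scoring (a whole-well sorting error, not a
hashing failure); the flip threshold is configurable but defaults to
exactly 1.0.

## Size calibration

TOF is regressed on bead size (OLS, replicate readings as individual
points), and the line is inverted for fragment sizing — the regression
direction matters with noisy calibration, and the standard curve is
acquired as TOF-on-size. Negative predicted sizes are flagged, never
clamped. Gate intervals are closed on both ends so published gates such as
211–325 and 326–457 µm tile without overlap.

## Zonation reconstruction

**Landmark filtering.** A reference profile (per-layer means and SEMs, 9 or
10 layers accepted; the fold-change predicate uses the first and last
available layer) passes if (i) its maximum layer mean exceeds 10⁻⁵, (ii)
the fold change between the two poles is at least 1.1, and (iii) the mean
over layers of SEM/mean is below 0.2. Predicate (i) is deliberately
max-over-layers: a gene silenced at one pole is among the most zonated and
must not be discarded; such genes carry an infinite fold change and are
flagged.

**ZC computation.** Pseudobulk expression (fragments × genes) is divided by
each gene's maximum over fragments so every landmark contributes equally;
ZC_raw = pLM/(pLM+cLM); fragments with pLM+cLM = 0 (no landmark signal,
typically no LECs) are dropped with a logged id list rather than imputed;
the min–max rescale spans the retained fragments and errors out if all raw
ZCs coincide. ZC_raw is invariant to per-gene positive rescaling, and the
rescale is strictly order-preserving.

**Layer binning.** L_k covers [0.1(k−1), 0.1k) for k = 1…9 and L10 covers
[0.9, 1.0]. Closing L10 at 0.9 makes the binning a total function on
[0, 1]; a literal half-open reading would leave 0.9 unassignable. The
sparse poles can be merged into L1–L3 and L8–L10; zones are L1–L5
(pericentral) and L6–L10 (periportal).

**Proximity labels.** Samples with fewer than 20 landmark (metastatic)
cells overall are excluded as low-burden; fragments with fewer than 5 cells
are excluded; a retained fragment is proximal iff it contains ≥ 1 landmark
cell. Both cutoffs are parameters.

**Landmark clustering.** Fragment mean-pseudobulks restricted to a small
landmark panel are scaled to unit variance, projected to min(10, rank)
principal components and partitioned by k-means, choosing k ∈ 2…6 by
silhouette. This route is fully deterministic under seed and reproduces the
two-niche outcome without a graph resolution parameter; a shared-nearest-
neighbor/modularity variant would be an acceptable alternative but maps its
resolution onto cluster count less predictably.

## Pseudobulk models

Counts are summed per fragment over cells of one type; only fragments with
at least 5 (zonation trend) or 2 (two-group contrast) cells of the type
enter. Lowly expressed genes are removed first: a gene is kept if it
reaches 10 counts in at least 70% × (smallest design group) units — the
heuristics of the common filtering functions are version-dependent, so the
thresholds are explicit parameters here.

Each gene is fit with a negative binomial log-linear model, log µ = Xβ +
log(library size). The layer covariate uses equally spaced scores 1…6 on
the merged ordered levels L1–L3 < L4 < L5 < L6 < L7 < L8–L10 (equal spacing
after merging is an assumption; nothing in the merged design identifies the
within-group spacing). Samples enter as fixed effects (one coefficient per
sample). The NB dispersion α (variance µ + αµ²) is estimated per gene by
method of moments from a Poisson fit, with an optional shrinkage toward the
trimmed-mean dispersion across genes; inference on the covariate uses a
quasi-likelihood-style t-test — the Wald statistic scaled by the Pearson
dispersion, referred to a t distribution with the residual degrees of
freedom. This mirrors the robustness logic of the established empirical-
Bayes quasi-likelihood F-test while remaining self-contained; the pipeline
contribution is the pseudobulk/design construction, and the model's
acceptance surface is calibration and recovery, not coefficient-level
equality with any particular package. All fits run as one batched IRLS
across genes (shared design matrix), which keeps 2000-gene × 20-replicate
calibration studies in seconds; the batched fitter is checked against an
independent GLM implementation in the test suite.

Abundance testing aggregates cells to sample × group units, models each
cell type's count with the group covariate, sample blocking and a
log-total-cells offset (the counts-per-million normalization), and adjusts
across cell types. The normalized log abundances are exactly invariant to
scaling any unit's total cell count; the NB coefficients are invariant in
expectation (weights shift slightly), which the tests check via unchanged
signs and significance calls.

Fragment covariates (size, cell count) between two groups are compared with
the two-sided Wilcoxon rank-sum test: the groups are unpaired, so the
rank-sum — not the signed-rank — test is the coherent choice.

## Ligand–receptor scoring

An interaction is tested only if every ligand component is expressed
(count > 0) in more than 10% of sender cells and every receptor component
likewise in receiver cells. Component expression is the mean log1p
counts-per-10k over the cluster's cells; any monotone common normalization
is acceptable for the calibration guarantees. Multi-subunit complexes are
summarized by the minimum over components — the limiting subunit — so
removing a component can only raise or preserve the summary. The score is
the ligand/receptor mean; the null permutes cluster labels over the pooled
sender+receiver cells (a within-sample permutation option exists for
multi-sample groups; pooled permutation is the default). One-sided
enrichment p = (#{null ≥ observed}+1)/(n_perm+1); no multiple-testing
correction, matching how such screens are conventionally reported. The
add-one formula bounds p in [1/(n_perm+1), 1].

## Colocalization test

Cells are vertices; edges connect pairs strictly closer than the radius
(default 10 µm, ties at exactly the radius excluded); the kd-tree search
caps each vertex at k_cap − 1 = 40 neighbors and warns on saturation, since
a saturated cap silently drops edges. Within each ROI the edge count of an
unordered type pair is divided by n_t1 + n_t2 (same-type pairs by 2·n_t).
Per slide, the statistic is the group-2 minus group-1 difference of ROI
means (a pooled-count variant is not offered; per-ROI means weight ROIs
equally). The null permutes cell-type labels over the slide's vertices with
the graph fixed, preserving the type multiset and the spatial structure.
The default tail is two-sided on |difference| with the observed sign
carried into the cross-slide score (fraction of slides significant, signed
by direction); a literal one-sided variant is available but is
anti-conservative when its direction is chosen from the observed sign. MAD
in the segment-area filter is raw (no 1.4826 consistency scaling); the
cutoff is median + 4·MAD by default. Polygon boundaries are closed —
a cell exactly on an edge is inside.

## Synthetic data

The generator emulates the statistical structure of a fragment experiment
on a metastasis-bearing liver:

* True ZC per fragment is uniform on [0, 1] by default; a truncated-normal
  option mimics datasets whose extreme layers are sparse.
* Expression counts are negative binomial (α = 0.3) with log-mean linear in
  the true ZC for planted genes; landmark genes are two opposed monotone
  gradients of 20 genes each (base mean 5 counts/cell in LECs, slope ±2 on
  the log scale). Off-type expression is 10% of base with no gradient.
* Cell-type composition is niche-dependent: distal fragments are
  {LEC .40, KC .37, mac/mono .04, T .12, B .07, metastatic 0}; proximal
  fragments {.30, .27, .20, .09, .05, .09} — metastatic cells appear and
  macrophages/monocytes are enriched while KCs and LECs are depleted, the
  direction the abundance tests must recover. Magnitudes are free
  parameters of the generator, near published proportion scales but not
  calibrated to any dataset.
* 200 fragments across 3 samples, ~30 cells per fragment (NB), 30%
  proximal.
* Hashing counts are Poisson: signal mean 500, background mean 5, doublet
  rate 0.05, negative rate 0.02. These are order-of-magnitude choices; no
  quantitative hashing noise parameters are published for this chemistry,
  so recovery results should be read as achievable-regime statements.
* Sorter readouts: size uniform in 200–450 µm, TOF = 2·size + 10 + N(0, 5²).
* Point patterns: cells uniform in square ROIs; planted attraction places a
  stated fraction of B cells uniformly within a pair distance of a random A
  cell, in one ROI group only.

What the generator does **not** emulate: ambient RNA, transcriptome
doublets, batch effects beyond sample blocking, gene–gene correlation,
irregular ROI shapes, and segmentation errors. Tests passing on this
generator show the algorithms recover their own generative structure at
realistic noise; they do not certify performance on any real dataset.

## Problem sizes used in the checks

Calibration studies use 2000 genes × 20 replicates at 120 pseudobulk units
across 3 samples; permutation-null uniformity uses 200 replicates at 199
permutations (100 cells per cluster for L–R; 100 cells per type, 3 ROIs per
group for colocalization — at much smaller patterns the discrete
permutation distribution leaves visible ties and the add-one p becomes
mildly conservative); power checks use 20 replicates at the planted effect
sizes (zonated slope +1 per unit ZC, 4-fold group difference, 50% paired
cells at 5 µm). Observed type-I error sits within [0.03, 0.07] at nominal
0.05 and the planted effects are recovered with correct sign in ≥ 90% of
replicates.

## Known limitations

* The NB inference is asymptotic per gene; at very few pseudobulk units
  (< ~15 per design cell) the t-approximation degrades.
* Zero-inflated or heavily multimodal hashing distributions can defeat the
  2-means threshold anchor; the quantile grid is configurable.
* The colocalization score treats slides symmetrically; slides with very
  different cell densities contribute equally.
* `landmark_cluster_fragments` assumes the landmark panel separates niches
  linearly in PCA space; k selection by silhouette can undercount clusters
  for strongly unbalanced niche sizes.
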