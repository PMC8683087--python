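# Methods

This note documents the models, conventions, and numerical choices behind
`urchin-atlas`, and what the synthetic-data validation does and does not
establish about real data.

## Expression summaries

**Pseudobulk CPM.** "Transcripts per million" is computed per cluster as
counts summed over the cluster's cells, rescaled to 1e6. UMI counts carry no
gene-length bias, so CPM is the appropriate reading of TPM for 3'-tag data.
An alternative (mean of per-cell CPM, `cell_mean=True`) is provided; the two
differ when library sizes vary within a cluster, because pseudobulk weights
cells by depth.

**Expressed-gene rule.** A gene is expressed in a cluster iff its pseudobulk
CPM is *strictly* greater than the threshold (default 3). The union over
clusters ("expressed anywhere") defines the gene universe for tree building.
The rule is deliberately shared between the tree, TF-sharing and
intersection modules so "expressed" means one thing package-wide.

**QC filtering.** Genes detected (count > 0) in fewer than 3 cells are
removed first; cells with fewer than 200 detected genes (among the surviving
genes) second. Both cuts are strict and each pass runs once, which makes the
operation idempotent. Cells lost here may still appear in annotation tables;
profile construction therefore requires only that every *matrix* cell be
annotated.

**Marker test.** Candidate genes must reach a detection fraction of
`min_pct` (default 0.01) in the focal cluster OR in the rest group. The OR
reading is a documented choice — the source convention is ambiguous — and an
AND mode is available. Per-cell expression is depth-normalized to 10,000
counts and log1p-transformed; group differences are assessed by a two-sided
Wilcoxon rank-sum test with average ranks for ties: exact permutation
enumeration when both groups have ≤ 10 cells (exactness under ties is what
makes the brute-force oracle test meaningful), otherwise the tie-corrected
normal approximation with continuity correction. Multiplicity is handled by
Bonferroni over the tested genes. Fold changes are reported as
log2((CPM_in + 1)/(CPM_out + 1)) on pseudobulk CPM.

**Dotplot scaling.** Per gene, log1p(mean CPM) is z-scored across clusters
with the sample SD (ddof = 1), so a two-cluster contrast scales to ±1/√2;
zero-variance genes get z = 0.

## Cell-type trees

Distances are computed on the expressed-anywhere universe (optionally
intersected with a catalogue, e.g. transcription factors only, and with an
`exclude` list for catch-all clusters):

- `spearman` (primary): 1 − Spearman ρ of mean CPM, bounded in [0, 2] and
  invariant to any strictly increasing per-cluster transform;
- `pearson_log`: 1 − Pearson r of log1p(CPM);
- `pearson_sqrt`: 1 − Pearson r of √CPM;
- `euclidean_scaled`: Euclidean distance of per-gene z-scored log1p(CPM).

Neighbor joining follows Saitou–Nei exactly: Q-criterion pair selection,
standard branch-length and distance-update formulas. Two numerical policies:
negative branch lengths are clamped to zero with the deficit moved to the
sister edge (path lengths through the join are preserved); and all ties are
broken lexicographically by the smallest leaf label in each subtree, making
the algorithm fully deterministic. On additive matrices these policies never
trigger and NJ reproduces the generating tree and its branch lengths.

**Bootstrap.** The gene universe is fixed once from the full data and then
resampled with replacement at its original size; it is *not* recomputed per
replicate (a flag enables that), so supports measure distance noise rather
than set-selection noise. Support is the integer percentage of replicate
trees containing each internal bipartition of the point tree, stored in
internal-node labels on Newick export. Splits are compared as unordered
{side, complement} leaf-set pairs, so comparisons are rooting-invariant.

## The independent-swap co-expression test

The family-level submatrix (all cells of the chosen cluster, genes detected
in it) is randomized by attempted swaps of uniformly sampled 2×2 quartets;
a checkerboard quartet (one diagonal nonzero, the other zero) has its values
moved along their rows onto the zero diagonal. Invariants: grand total, each
row's multiset of nonzero values, binarized row sums, binarized column sums.
This is the abundance generalization of the occupancy independent-swap null;
it conditions on both gene prevalence and per-cell detected-gene counts.

`n_iter` counts *attempted* swaps by default, matching common usage; a
successful-swaps mode is available, and matters at small matrix sizes where
most attempts are rejected (see study designs below).

The statistic follows the source procedure literally: the observed panel
count k_obs (default detection rule: ≥ 1 nonzero entry in the target
subcluster's columns; mean-based rules are flags) against the randomized
mean over 500 randomizations of 100,000 iterations, rounded half-up, in a
2×2 expressed/not-expressed table, tested by Pearson chi-squared with Yates
continuity correction (the default for 2×2 tables in the environment the
procedure originated in; a flag disables it). Because the rounded-mean table
discards replicate variance, the empirical permutation p-value
(1 + #{replicate counts ≥ k_obs})/(n_replicates + 1) is always reported
alongside and is the better-calibrated quantity. Degenerate tables (a zero
margin) return chi² = 0, p = 1. Each replicate draws from an independent
child stream of the master seed, so results are reproducible and
parallel-safe.

## The synthetic atlas

The generator emulates exactly the structure the analyses assume. Counts are
negative binomial with size `nb_dispersion` (default 2; `inf` switches to
Poisson) and mean `lib_factor(cell) × mean[cluster, gene]`; per-cell library
factors are log-normal (σ = 0.3 by default). Per-gene baselines are
log-normal around `baseline_mean` (default 0.5 counts/cell, σ = 1 on the log
scale — a realistic UMI regime of a few hundred to a few thousand counts per
cell at desk-scale gene counts). Cluster structure comes from exponentiating
a Brownian walk (step SD `branch_sd` per unit branch length, default 0.6)
along a planted binary tree, so expression distance grows with tree
distance and tree recovery is well-posed. Markers multiply their cluster's
mean by 2^`marker_log2fc`. Layer-restricted TFs sit at baseline in their
germ layer's clusters and at `tf_off_mean` (default 0) elsewhere — with
relative (CPM) thresholds, only a near-zero off-state makes a gene
layer-specific. Panel genes sit at `panel_off_mean` everywhere except the
first subcluster of the panel cluster, where they are multiplied by
`panel_effect`. The knockdown table draws its targets from the panel
cluster's robustly expressed genes (expected CPM > 30, so sampling noise
cannot drop a target below the 3-CPM call) and signs exactly
round(`frac_down`·n) of them negative.

Not emulated: ambient RNA, doublets, batch-integration artifacts, gene–gene
correlation beyond the shared tree signal, and UMAP geometry. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the stated model, not robustness to those artifacts.

## Canonical study designs

Fixed configurations (`*_config(seed)` in `synthetic_atlas`) define the
conditions under which the validation suite runs:

- **Tree recovery**: 8 clusters, 200 cells each, 1,000 genes, on a *balanced*
  planted tree with unit branch lengths and `branch_sd` = 1. Equal branch
  lengths keep Spearman distances well inside [0, 2]; with strongly
  heterogeneous branch lengths or much larger walks the distance saturates
  near 2 and short internal edges become unresolvable — a property of
  rank-correlation distances, not of the NJ implementation.
- **Co-expression power**: a 180-cell family among three 40-cell clusters,
  100 genes, a 20-gene panel near-silent outside a 20-cell target subcluster
  (off mean 0.005 counts/cell, ×100 inside). Panel genes are detected in a
  handful of target cells each — the sparse signature the swap null can
  destroy. Two desk-scale effects shaped this design: (i) *mixing* — at this
  matrix size roughly 100,000 attempted swaps are needed to reach the
  stationary ensemble, so the scaled-down demonstration (10,000 swaps, 50
  replicates) runs in successful-swaps mode; and (ii) *column-margin bias* —
  the swap conserves per-cell detected-gene counts, and the panel's own
  detections inflate the target columns' margins, so the randomized count
  does not fall to the naive uniform-placement expectation. Keeping the
  panel a small fraction of the gene set bounds this bias.
- **Co-expression null**: the same test with `panel_effect` = 1, a tiny
  family matrix (30 genes × 36 cells) so 10,000 attempts mix fully, and
  library-size variation off so detections are exchangeable across cells.
  Under these conditions the empirical p is approximately uniform; with
  integer counts and 50 replicates it remains slightly conservative (ties
  count against rejection), which the calibration check accommodates.
- **Marker recovery**: 6 clusters × 200 cells, five markers each at 4-fold,
  baseline 1 count/cell with moderate spread (σ = 0.5) and a short Brownian
  walk, so power is limited by the effect size rather than by near-zero
  baselines.
- **Knockdown intersection**: 6 clusters × 300 cells, 1,200 genes, a 249-gene
  target set at 65% down — mirroring the magnitudes of the motivating
  experiment as planted truth.

## Known limitations

- The swap chain's mixing time is not monitored; users applying the test to
  large matrices with the default 100,000 attempts should increase the
  budget or use successful-swaps mode (under-mixing biases the test toward
  conservatism, not false positives).
- The chi-squared-on-rounded-mean statistic ignores replicate variance; it
  is reported for fidelity to the original procedure, and the empirical p
  should be preferred for inference.
- Pseudobulk CPM near the 3-CPM threshold is Monte-Carlo noisy at realistic
  depths (a 50-CPM gene summed over 500 cells carries a relative SE of
  several percent), so expressed-set membership of borderline genes is not
  reproducible draw-to-draw; analyses here aggregate over sets, which damps
  the effect.
- Exact rank-sum enumeration is limited to groups of ≤ 10 cells; beyond that
  the normal approximation is used, which is standard but approximate at
  group sizes just above the cutoff.
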