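# Methods

This note documents the statistical procedures implemented in `sccrosstalk`,
the assumptions behind the synthetic-data generator, the default parameters
and why they were chosen, and the known limits of what the benchmarks show.

## Quality control and normalization

Input is a genes × cells matrix of TPM values (each column of raw input sums
to 10⁶ over all quantified transcripts, spike-ins included). Per cell we
compute the number of detected genes (strictly positive values — "expressed"
means `> 0` on the TPM scale throughout the package), the mitochondrial
fraction (sum over `mt-`-prefixed genes divided by the cell total, computed
on the raw TPM scale before spike-in removal), and the total.

A cell is removed when `detected < 1500` **or** `mito_fraction > 0.20`.
Both comparisons are strict, so boundary cells survive. The disjunctive
rule is the universal scRNA-seq convention; `QCThresholds(require_both=True)`
restores a conjunctive reading. Genes expressed in fewer than 3 cells are
then dropped, `ERCC-`-prefixed rows are removed, each remaining column is
rescaled to sum to 10⁶ (all-zero columns stay zero; within-cell proportions
among endogenous genes are exactly preserved), and the matrix is
log(x+1)-transformed with the natural log.

The 1500-gene default assumes a genome-scale gene universe; on the
generator's ~1000-gene transcriptome the benchmarks use a proportionally
scaled threshold of 300. Whether detected-gene counts are taken before or
after spike-in removal is a free choice; the default is before.

## Clustering and annotation

* **HVG selection** bins genes by mean log expression (20 equal-frequency
  bins, reduced when genes are few) and z-scores the dispersion
  (variance/mean) within each bin; the top `n_top` standardized dispersions
  win, ties broken by gene name for determinism.
* **PCA** operates on per-gene centered (and by default unit-scaled) log
  expression, with a full SVD and a deterministic sign convention (the
  largest-magnitude loading of each component is made positive), so
  embeddings are identical across runs and BLAS builds. The default of 20
  components is the midpoint of the conventional 10–30 range; an elbow
  inspection is left to the analyst rather than auto-applied.
* **SNN clustering**: each cell's neighbor set is its k = 20 nearest cells
  (Euclidean in PC space, itself included); edges are weighted by the
  Jaccard overlap of neighbor sets and pruned below 1/15; communities are
  found by Leiden optimization of resolution-parametrized modularity
  (resolution 0.8 by default), seeded and deterministic. Cluster ids are
  relabeled contiguously by decreasing size. `merge_clusters` supports the
  manual curation step of collapsing clusters the analyst judges to be one
  cell type.
* **Markers**: per gene, a two-sided Wilcoxon rank-sum test (normal
  approximation with tie correction) of in-cluster vs all other cells.
  Fully tied genes get p = 1. The reported log fold-change is
  `ln((mean expm1 in + 1) / (mean expm1 out + 1))`; the pseudocount of 1
  keeps near-silent genes from producing unbounded fold-changes. Bonferroni
  adjustment over genes is the default (Benjamini–Hochberg by option), and
  rows sort by p, then |lfc|, then name.
* **Module score**: mean expression of a gene set minus the mean of control
  genes drawn per set gene from the same average-expression bin (25 bins,
  50 controls per gene, seeded). Scores center near zero on signal-free
  sets.
* **regress_out** replaces each gene by its OLS residual against a per-cell
  covariate, adding the gene mean back. Residuals may be negative, as in
  any covariate-corrected expression matrix; a constant covariate is a
  warned no-op.

## Cell-cycle scoring

A phase's marker-pair table lists ordered gene pairs (a, b) chosen (by the
published training scheme, external to this package) so that expr(a) >
expr(b) in that phase and the inequality reverses elsewhere. The score of a
cell is the fraction of usable pairs (both genes present) satisfying the
inequality strictly; ties — including the all-zero cell — count as "not
greater", so an empty cell scores 0 for every phase. Assignment takes the
argmax among phases scoring above 0.5, falls back to the plain argmax when
none clears the bar, and returns "unassigned" on exact ties. Pair training
is out of scope; tables are consumed from CSV.

## Communication inference

For an interaction with partners A and B and ordered cluster pair (i, j),
partner A is evaluated in cluster i and partner B in cluster j:

* a single-gene partner qualifies iff its expressed fraction in the cluster
  is **strictly greater than 0.10**; its statistic is the cluster mean of
  log(TPM+1);
* a heteromeric complex qualifies iff **every** subunit clears the
  fraction filter; its statistic is the cluster mean of the subunit with
  the minimum average expression in that cluster (the "effective gene";
  first-listed wins exact ties);
* the interaction statistic is the arithmetic mean of the two partner
  statistics, so simultaneously swapping partners and clusters leaves it
  unchanged. Autocrine (i = j) pairs are computed identically and flagged.

The null distribution globally permutes the cluster labels of all cells —
one shuffle per permutation, shared by every cluster pair, preserving
cluster sizes — and recomputes the statistic. Two decisions are made once
on the observed labels and held fixed across permutations: which pairs are
tested (the fraction filter) and each complex's effective gene. Re-deciding
either per permutation would change the hypothesis being tested from
"label-specific elevation of this gene pair" to a composite over varying
gene choices.

The p-value is the plain proportion of null statistics as high or higher
than the observed one, so it can be exactly 0 at finite permutations;
`add_one=True` gives the (1+k)/(1+N) estimator. Tie comparison uses an
absolute slack of 1e-9 so that exactly degenerate data (all cells equal)
yields p = 1 despite floating-point roundoff. No multiple-testing
correction is applied to the primary p-values; Benjamini–Hochberg q-values
are reported as an auxiliary column only. Every interaction is evaluated in
both orientations, emitted as separate directed rows.

`exhaustive_pvalues` enumerates all distinct arrangements of the label
multiset (feasible to 12 cells) and applies the same comparison rule; since
the observed arrangement is among those enumerated, the exact p is at least
1/#arrangements. It is the independent oracle against which the sampled
test is validated.

## Projection

An L2-regularized multinomial logistic model (lbfgs, tolerance 1e-6) is
trained on reference clusters using log-normalized expression. Features are
standardized per gene on training statistics by default — the L2 penalty is
not scale-invariant, and without standardization a handful of very highly
expressed genes dominate the decision geometry; `scale=False` fits the raw
log values. The feature space defaults to all reference genes and can be
restricted (e.g. to the reference∩query intersection or an HVG subset)
before fitting. Query genes are aligned by name; genes missing from the
query are imputed as zero with a logged count. Predicted probabilities sum
to one per cell, and group summaries average them within user-supplied
query groups. The inverse penalty defaults to 1.0; accuracy on the
benchmark conditions is insensitive to it over several orders of magnitude.

## The synthetic-data generator

The generator emulates a Smart-seq2 plate experiment on a structured
tissue: `n_clusters` = 4 populations × 50 cells, 1000 endogenous genes, 10
mitochondrial and 20 ERCC rows.

* **Baseline**: per-gene log-mean drawn from N(log 5, 2²), per-cell
  log-expression N(gene log-mean, 0.4²). The wide per-gene scale reproduces
  the heavy tail of real transcriptomes, where a few genes carry most of
  the TPM mass and the typical gene sits at a few TPM — the regime in which
  detection filters and dropout behave realistically.
* **Markers**: each cluster owns 50 genes whose baseline is drawn from a
  low, narrow band (log-mean N(log 0.08, 0.5²)) and up-shifted
  `marker_fold` = 8× in its cluster. Two reasons: real cell-type markers
  behave as on/off genes, near-silent outside their type, which is also
  where a fold change carries the most information under dropout; and a
  small, balanced marker mass per cluster prevents the final TPM
  renormalization from imprinting a compositional cluster signature on
  every baseline gene, which would silently break the global-null
  benchmarks (renormalization couples genes: if one cluster's markers
  happened to be high-mass genes, all of that cluster's baseline values
  would shift).
* **Dropout** is Bernoulli per gene × cell at rate 0.3, independent of
  magnitude (spike-in rows are exempt — they are added to every well).
  Magnitude-independent dropout is the simplest null for the tests; it is
  harsher than real data, where high-expression genes essentially never
  drop out.
* **Planted signals**: `plant_interaction` multiplies all subunit genes of
  a ligand in the source cluster and of a receptor in the target cluster by
  a fold, reviving zero cells (set to the in-cluster positive mean) until
  the expressed fraction strictly exceeds 10%, then rescales columns to
  10⁶. With `exclusive=True` the planted genes are additionally silenced
  outside their cluster — the cell-type-restricted expression real ligands
  and receptors show, and what makes a planted signal *cluster-pair
  specific* rather than merely elevated: a broadly expressed gene raised in
  one cluster genuinely elevates every pair involving that cluster, which
  the statistic correctly reports.
* **QC failures**: `inject_qc_failures` zeroes chosen cells down to fewer
  than the detected-gene threshold and raises others' mitochondrial share
  to 30% (above the 20% cutoff), recording them in the ground truth.
* Everything is deterministic given the seed; every operation that rescales
  leaves each column summing to 10⁶ within 1e-6 relative.

## Benchmark experiments and problem sizes

`sccrosstalk.experiments` fixes the reference conditions used by the test
suite and `scripts/acceptance.py`:

* **Oracle agreement**: the 6-cell toy (exact p = 1/20 over 20
  arrangements) and randomized ≤ 12-cell instances, sampled at 10⁴
  permutations, agree within the binomial 99% interval.
* **Type-I error**: 50 interactions built from moderately expressed
  baseline genes on the default simulation, 1000 permutations, all 16
  ordered pairs → 800 tested null combinations per run. Because one shuffle
  serves all pairs, rejections within a run are strongly correlated, so the
  rate is pooled over 3 independent simulations (2400 combinations); it
  stays within [0.03, 0.07] of the nominal 0.05.
* **Power/specificity**: ten fold-8 signals (one with a 3-subunit complex)
  planted with restricted expression on distinct cluster pairs; power is
  the fraction of planted pairs with p < 0.05 (10/10 across seeds),
  specificity the fraction of the same interactions' other 150 ordered
  pairs that are filtered out or non-significant (1.0 across seeds).
* **Clustering**: ARI ≥ 0.9 against generator truth (typically 0.96–1.0).
* **Projection**: 75/25 split of the default simulation; held-out accuracy
  ≥ 0.9 (typically 1.0) with a diagonal-dominant group-probability table.
* **QC**: 10 low-complexity + 5 high-mito injected cells are removed
  exactly, and boundary cells at the thresholds survive.

All experiments finish in seconds on one CPU at these sizes; they scale
linearly in cells × permutations.

## Limitations

The generator does not simulate read-level data, batch effects, doublets,
library-size variation, or magnitude-dependent dropout (available only as a
planted-signal side effect via `exclusive`). Passing benchmarks on it shows
the implementation is correct and calibrated under its assumptions, not
that any particular biological dataset satisfies them — in real data,
ambient contamination and compositional coupling between clusters can
inflate communication-test significance in ways the global-null benchmark
cannot detect. Interaction databases and cell-cycle pair tables are
consumed, not curated; ortholog mapping between species is out of scope,
and queries must arrive in the reference gene namespace.
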