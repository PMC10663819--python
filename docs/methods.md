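# Methods

## Scope and data model

`commscreen` operates on cluster-annotated expression data; clustering,
integration, doublet and empty-droplet handling are upstream concerns and
cluster labels are inputs. Single-cell data live in an `AnnData` (cells ×
genes) with raw integer counts in `layers["counts"]`, log-normalized values
in `X`, and per-cell `cluster` / `tissue` / `patient` / `dataset` columns in
`obs`. Bulk data are a genes × samples count DataFrame plus a tumor/normal
condition vector. The ligand-receptor database is a validated record list;
each record is a directed ligand-complex → receptor-complex interaction
(1-2 / 1-3 subunits) with a family label from a controlled vocabulary
(cytokine, chemokine, immune_checkpoint, growth_factor, cell_adhesion,
other). Records deduplicate on unordered subunit sets per side; direction
is preserved (A→B ≠ B→A). Symbols are upper-cased at ingest because curated
tables mix HGNC alias casings.

## Preprocessing

Cells are retained when they express ≥ 200 genes, carry ≥ 1000 total
counts, and have a mitochondrial fraction strictly below 20%
(mitochondrial genes identified by the configurable symbol prefix `MT-`).
Normalization is `log2(count / cell_total × 10⁴ + 1)`. The scale factor
10,000 and pseudocount 1 are this package's choices (the dominant
single-cell convention) and are recorded in `uns["normalization"]` so any
output can be traced to its normalization parameters. Zero counts map
exactly to 0.

Cluster profiles are arithmetic means of the normalized values per
(cluster[, tissue]) group together with the fraction of cells with a
nonzero raw count (`pct`, computed on raw counts — the dropout-relevant
quantity). The percent-expressed filter zeroes a communication gene's mean
in every group where its `pct` is strictly below 10%; it applies only to
the communication scores, not to family scores or differential expression,
and a gene at exactly 10% is kept.

## Communication scores

The pair score from emitter C₁ to receiver C₂ sums, over all database
records, the product of the emitter's ligand-complex expression and the
receiver's receptor-complex expression. Complex expression aggregates
subunit means by the **minimum** by default — limiting-subunit semantics: a
complex cannot signal beyond its scarcest subunit, and a subunit zeroed by
the percent-expressed filter silences its complex. The mean rule is
available (`complex_rule="mean"`), and the choice is part of every run
manifest because reasonable conventions differ. Absent subunits count as
zero expression and are logged.

Internally the scorer builds interaction × cluster matrices of ligand- and
receptor-side complex expression once; the K × K totals are their matrix
contraction, and per-interaction or per-family decompositions are exact
slices of the same arrays (tests verify equality with a naive per-record
double loop to 1e-10). Score grids can be rescaled to 0-100 by the grid
maximum, either for the K × K totals or per interaction channel.

## Specificity screen

For each interaction and candidate emitter C, the outgoing summed score is
l_i^C × Σ_k r_j^k over all K clusters; incoming mirrors it with the
receptor on the focal side. The counterpart sum includes the focal cluster
itself by default because autocrine loops are biologically meaningful hits;
`include_focal_in_sum=False` removes the focal column from the shared sum.
The specificity rule passes when the focal value is ≥ 1.5× ("at least"
read inclusively) the best competing cluster's value. When every competitor
is zero the ratio is undefined; the rule then passes iff the focal value is
positive (specificity is maximal), and the ratio is reported as infinity.
A per-pair variant (`per_pair_specificity=True`) compares best single
cluster-pair contributions instead of counterpart sums, for sensitivity
analysis.

The differential-expression gate compares the focal cluster (tumor tissue)
with a reference cluster from juxtatumor tissue — the focal population's
presumed cell of origin. Fold changes use the de-logged-mean convention
log2((mean(2^x−1)+1)/(mean(2^x−1)+1)); genes below the 0.25 log2FC
threshold are not tested, Bonferroni correction runs over tested genes
only, and selection requires log2FC ≥ 0.25 and adjusted p < 0.05. For
outgoing channels the gate applies to the ligand side, for incoming to the
receptor side; heterodimers require **every** subunit of the gated side to
be selected (complex function needs all subunits; `de_gate_subunits="any"`
relaxes this, `de_gate_both_sides=True` gates both sides).

The cancer-vocabulary selector runs pairwise focal-vs-other DE over
communication genes with a two-branch criterion — (1) log2FC ≥ 0.25, or
(2) log2FC ≥ 0.1 with the other cluster below 10% expression and a
percent-expressed gap above 5 points, each at adjusted p < 0.05 — and
returns the intersection across all pairwise comparisons.

Cross-dataset intersection keeps (interaction, direction) hits found in at
least 2 datasets and tiers them (`all` vs `>=2`).

## Family scores

Per cell, a family's score is the sum of normalized expression over every
gene annotated to that family (a gene annotated to two families counts in
both). Group means are centered-reduced as z-scores across groups; by
default the groups are the tumor-tissue clusters (z-scoring across
cluster × tissue jointly is available by passing `tissue=None` and grouping
by both keys). Zero-variance families get z = 0 with a warning. The
tumor-vs-juxtatumor contrast runs a two-sided Wilcoxon rank-sum test on
per-cell scores per (cluster, family), Benjamini-Hochberg corrected across
the whole grid in one batch, with log2FC = log2((mean_t + ε)/(mean_j + ε)),
ε = 1e-9 guarding empty means; significance requires adjusted p < 0.001
and |log2FC| > 0.25. A tumor-only cluster can be paired with its
juxtatumor counterpart (e.g. cancer vs proximal tubule) via
`cluster_pairing`.

## Bulk validation

Counts are normalized by median-of-ratios size factors (reference genes =
all-nonzero rows; factors are per-sample medians of count / per-gene
geometric mean). Note these factors are invariant to a global rescaling of
the matrix — ratios to the geometric mean cancel common constants — and
recover per-sample scalings exactly on proportional matrices up to a
common constant. Each gene is then centered-reduced across samples
(zero-variance genes → 0, flagged).

Per candidate pair and sample, a ligand × receptor product is formed and
tumor vs normal products are compared by Wilcoxon rank-sum with Bonferroni
correction across the tested pairs; significance requires adjusted
p < 0.001 and log2FC ≥ 1. **The rank test runs on products of the
normalized (non-centered) layer by default.** Products of z-scored genes
are sign-ambiguous: when both genes rise in tumors, tumor products
(+ × +) and control products (− × −) are both positive, and in a balanced
cohort the two rank distributions coincide, giving the test no power (we
measured 0/30 detections of a 2× fold at 60/60 samples on that layer,
versus 30/30 on the normalized layer; in strongly unbalanced cohorts the
per-gene mean sits inside the tumor group and both layers agree). The
scaled layer is still computed and reported (per-pair products and
tumor-minus-normal mean difference), and `test_layer="scaled"` restores
the test on it. The fold change is always computed on normalized-layer
products with a +1 shift, since centered products can be negative. Pairs
with missing genes are skipped and logged. Because the exact fold-change
definition on scaled products is underdetermined, cohort-specific
significant-pair counts are data-dependent and not a package-level
constant.

## Synthetic data generator

The generator defines the study conditions the test suite measures under.
Single-cell counts are negative binomial with dispersion θ and gene-level
baseline means drawn log-normal (σ = 0.5) around μ, thinned by independent
Bernoulli dropout. Defaults: K = 6 tumor clusters × 400 cells (a focal
"cancer" cluster plus five TME clusters), a 400-cell "PT" reference
cluster at baseline expression in juxtatumor tissue, 1000 genes (the
database's gene universe padded with background genes), μ = 2, θ = 2,
dropout 0.3, planted ligand fold 8. The focal cluster exists only in tumor
tissue and the reference only in juxtatumor, mirroring the
cell-of-origin contrast; other clusters can optionally appear in both
tissues for tissue-contrast testing. Planted channels multiply the NB
means of an interaction's ligand and/or receptor genes in the focal
cluster; a family shift multiplies all of a family's genes in one cluster.
Everything is deterministic under the config seed.

The bulk generator draws NB counts (θ = 10) with log-normal gene means
(μ = 100, σ = 1), log-normal per-sample library factors (σ = 0.3), 60
tumor + 60 normal samples, and a tumor-side fold on both partners of the
planted pairs.

What the generator does **not** emulate: batch effects, trajectories,
compositional shifts, mean-variance trends beyond NB, gene-gene
correlation, ambient RNA. Passing tests therefore demonstrate that the
pipeline recovers planted mean-level asymmetries at realistic depth,
dropout and over-dispersion, and that its decision rules are calibrated
under its own null — not that any specific biological channel would be
found in real tissue.

## Numerical choices and limitations

- Wilcoxon rank-sum tests use the Mann-Whitney U statistic with tie
  correction (`scipy.stats.mannwhitneyu`, `method="auto"`); count data are
  tie-heavy, which rules out the exact no-ties method at small n. All-tied
  comparisons get p = 1.
- Simulation sizes in the test and acceptance runs (e.g. 100 or 30 seeds,
  1000-gene universes, 200-gene bulk panels) are chosen to estimate the
  reported rates with small Monte-Carlo error while keeping runs
  interactive; the acceptance script reports the n used with each value.
- The degenerate specificity pass (focal > 0, all competitors 0) can admit
  channels whose partners sit just above the percent-expressed filter only
  in the focal cluster; the realized ratio column (inf sentinel) makes
  these auditable.
- Ties in `ratio` ranking are not broken deliberately; hits are sorted by
  focal value.
- The synthetic curated table reproduces the published family tallies with
  synthetic symbols to exercise read/merge/count bookkeeping; it carries no
  real curation and is labelled synthetic wherever it appears.
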