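# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does not
emulate, and the design decisions taken where more than one convention is
defensible.

## Synthetic data model

The generator emulates a two-condition (pre/post thoracic irradiation),
two-strain mouse-lung single-cell experiment with known structure.

**Counts.** Each gene *g* draws a baseline mean *μ*g = `nb_mean` ×
LogNormal(0, 0.5), and counts are negative binomial via a gamma–Poisson
mixture with dispersion `nb_dispersion` (variance *μ* + *μ*²/θ). Defaults
`nb_mean = 0.3`, `nb_dispersion = 0.5` give the sparse, overdispersed
profiles typical of droplet data (roughly 20–25% nonzero entries per gene);
rank-based downstream tests only need this qualitative shape.

**Radiosensitivity.** Depletion acts on *cell numbers*, not expression:
post-irradiation cell counts per cluster are Binomial(n_pre, s) with
survival factor *s* ∈ [0, 1]. This mirrors measuring radiosensitivity
purely as compositional change. When no survival factors are supplied, they
are evenly spaced from 1.0 (resistant) down to 0.05 (highly sensitive)
across clusters.

**Programs.** Each cluster owns a disjoint block of marker genes whose
means are multiplied by e^`marker_log_effect` inside the cluster (default
effect 2.0). A per-cluster `cycling_fraction` of cells carries an S or G2M
program (coin flip between the two) on dedicated gene blocks with the same
effect size. Mitochondrial genes (`mt-` prefix, 13 by default — the count
of protein-coding genes on the mouse mitochondrial genome) receive a
per-cell Beta-distributed fraction of the library (mean 5%, concentration
30), giving the QC filter realistic outliers.

**Planted L-R edges.** For an edge (sender, receiver, ligand, receptor,
b), a fraction *b* of sender-cluster cells receives extra ligand counts
(1 + Poisson(`lr_boost_mean`)) and likewise the receptor in the receiver
cluster, raising the nonzero-expression rate by ≈ *b*(1 − baseline rate).
Condition-specific edges apply the boost only to post-irradiation cells.
Strain is a free label with no simulated effect.

All randomness flows from one `numpy.random.default_rng(seed)` stream, so
an identical configuration reproduces a bit-identical dataset.

**What the generator does not emulate:** doublets, ambient RNA, batch
effects, UMI saturation, gene–gene correlation beyond the planted programs,
and realistic library-size variation between samples. Passing tests
therefore demonstrate that the statistical machinery recovers planted
effects under a clean overdispersed model, not that it is robust to every
artifact of real droplet data.

## Quality control and normalization

Cells are removed when they detect fewer than 500 or more than 8,000 genes
or when more than 15% of their UMIs are mitochondrial; genes expressed in
fewer than 3 cells are removed. Boundary semantics are strict exclusion:
a cell sitting exactly at a bound is retained. The mitochondrial fraction
uses UMIs of all genes in the input matrix. Both masks are computed on the
input matrix and applied in one pass (create-then-filter semantics, no
fixpoint iteration); consequently a second pass may drop genes that fell
below the cell threshold after cell removal, but it never removes cells.
Mitochondrial genes are recognized by the case-insensitive symbol prefix
`mt-` (mouse convention); the regex is configurable.

Normalization is library-size scaling to 10,000 counts per cell followed by
ln(1 + x). Per-cell values are independent of all other cells.

## Clustering and cell typing

Graph clustering is deliberately delegated plumbing: PCA (≤ 50
components), an SNN graph (15 neighbors), and Leiden community detection
at the requested resolution, all seeded. The pipeline accepts externally
supplied cluster labels unchanged, because everything this package
contributes lies downstream of the labels. Batch alignment is out of
scope.

Cluster-to-cell-type assignment scores each reference marker set by its
mean z-scored expression within the cluster and takes the best-scoring
type; ties go to the lexicographically smallest name and are flagged.

## Differential screens

All screens use the Mann–Whitney U test. Because single-cell vectors are
heavily tied (zero-inflated), the implementation is explicit about ties:

* both groups ≤ 8 cells — exact enumeration of all C(n₁+n₂, n₁)
  assignments of the pooled values (correct under ties);
* otherwise — normal approximation with the standard tie-corrected
  variance and a 0.5 continuity correction;
* an all-tied sample has zero permutation variance and reports p = 1.

Marker detection is one-vs-rest, two-sided, Bonferroni-adjusted over tested
genes, filtered at avg_logFC > 1 and adjusted p < 0.01. The fold change is
ln((mean expm1 in-cluster + 1) / (mean expm1 rest + 1)), i.e. natural-log
fold change of de-logged normalized means with a pseudocount. Condition DE
within a cluster is one-sided (post greater) at raw p < 0.05 with positive
fold change. The cross-cell-type "common upregulated genes" operation is an
exact set intersection.

**Multiple testing in the L-R screen.** The overexpression screen defaults
to Bonferroni adjustment over the tested genes within each cluster, with
`correction=None` available for a raw per-test threshold. The corrected
default is deliberate: with ~400 database genes and 8 clusters, a raw
p < 0.05 one-vs-rest screen admits roughly 5% false significances per test,
which cross-multiply into dozens of spurious edges and overwhelm a
20-edge true network (measured planted-edge precision ≈ 0.34 raw versus
1.0 corrected at the package's reference configuration). The same default
applies to the post- vs pre-irradiation upregulation screen.

## Radiosensitivity statistics

Composition rows are restricted to clusters with strictly more than
`min_cells` (default 50) total cells; fractions are normalized within each
condition over the retained clusters, so they sum to 1 and the
unirradiated ratio is scale-free with respect to recovered cell numbers —
relevant because the two conditions pool different samples and strains.
The per-cluster test is Pearson χ² without Yates correction (cell counts
are typically in the thousands; a flag restores the correction);
adjustment is Bonferroni over retained clusters, direction is called at
adjusted p < 0.05. Strain comparisons reuse the same operations grouped by
strain; no bespoke statistic.

## Cell-cycle phases

S and G2M scores are the mean normalized expression of the program minus
that of an expression-matched random control set (seeded; control size and
bin count scale down gracefully on small gene panels). The S/G2M calls
follow the standard rule (S when s > 0 and s ≥ g2m; G2M when g2m > 0 and
g2m > s). The G0/G1 split among the remaining cells is a declared
convention, since quiescence is not identifiable from these two scores
alone: a non-cycling cell is G0 when its combined score (s + g2m) is at or
below the `g0_quantile` (default 0.25) quantile of non-cycling cells,
else G1. The at-or-below boundary makes a cell with zero expression of
every program and control gene quiescent whenever it sits at the bottom of
the pool, which is the intended degenerate behavior. The correlation stage
accepts any externally produced phase table, decoupling the
radiosensitivity/G0 finding from this convention.

The correlation itself is a Pearson r between per-cluster unirradiated
ratio and G0 fraction (of all four phases), with the two-sided t-test p
and the least-squares line; it requires ≥ 3 clusters and nonzero variance
on both axes.

## Problem sizes in tests and the acceptance script

The validation suite runs at desk scale, chosen so each check finishes in
seconds while leaving comfortable statistical margins: composition
recovery uses 12 clusters × 500 pre-irradiation cells over 100 replicates
(gene content is irrelevant to composition, so those runs carry a minimal
20-gene panel); network recovery uses 8 clusters × ~300 cells with 20
planted edges among 200 decoy pairs over 20 replicates; the condition
network uses 6 clusters over 20 replicates; the cycle correlation uses 12
clusters × ~300 genes with cycling fractions 0.05–0.7 coupled to survival
factors 1.0–0.1. The acceptance script reruns the same designs (10–25
replicates) and records the problem size next to every number it reports.

## Known limitations

* The G0/G1 boundary is a convention, not an inference; absolute G0
  fractions depend on `g0_quantile` even though the sign of the
  cycle/radiosensitivity correlation is stable across reasonable settings.
* The normal-approximation p-values are asymptotic; for cluster sizes
  between 9 and ~30 cells they are adequate for screening but not exact.
* The unirradiated ratio compares fractions, not absolute abundances; a
  global change in recovered cell numbers between conditions is invisible
  to it by construction.
* Edge intensity uses nonzero-expression rates; alternative intensity
  definitions (e.g. mean-expression products) can be recomputed from the
  retained per-edge statistics without rerunning the screen.
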