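# rili-scomm

Quantitative analysis of acute radiation-induced lung injury (RILI) from
single-cell transcriptomes: quality control and annotation, per-cluster
*in-vivo* radiosensitivity scoring from pre-/post-irradiation composition,
cell-cycle/radiosensitivity correlation, and ligand–receptor (L-R)
intercellular communication networks. A synthetic-data generator with
planted ground truth makes every stage testable offline, without access to
a sequencing run.

The package is aimed at computational biologists studying how thoracic
irradiation reshapes the lung's cellular ecosystem — which clusters are
depleted one day after exposure, how depletion relates to proliferative
state, and which ligand–receptor signals are switched on between surviving
populations.

## The statistics at the core

**Radiosensitivity as compositional change.** For cluster *k* with
condition-normalized cell fractions *f*pre,k and *f*post,k, the
*unirradiated ratio*

&nbsp;&nbsp;&nbsp;&nbsp;*u*ₖ = *f*pre,k / (*f*pre,k + *f*post,k)

is near 1 for clusters wiped out by irradiation (radiosensitive) and near 0
for clusters enriched afterwards. Enrichment/depletion per cluster is tested
with a Pearson χ² (1 df, no continuity correction) on the 2×2 table
(cluster vs rest) × (pre vs post), Bonferroni-adjusted across clusters.
Cells are assigned G0/G1/S/G2M phases from background-corrected S and G2M
program scores, and *u*ₖ is correlated (Pearson, two-sided t test) against
each cluster's G0 fraction.

**L-R communication networks.** For every ligand or receptor gene and every
cluster, a one-sided Mann–Whitney U test asks whether the gene is
overexpressed in the cluster against all remaining cells (exact permutation
enumeration when both groups have ≤ 8 cells; tie-corrected normal
approximation otherwise; p-values Bonferroni-adjusted over tested genes per
cluster). A directed edge *sender → receiver* exists for a database pair
when the ligand is significant in the sender and the receptor in the
receiver. Its **intensity** is the sum of the two expression rates
(fraction of cluster cells with nonzero normalized expression), and the
**communication strength** between two clusters is the number of
significant pairs between them. The post- vs pre-irradiation network keeps
an edge only when both genes are significantly upregulated after
irradiation within their clusters.

## Worked example

```python
from rili_scomm.simulate import (SimConfig, generate_dataset, plan_lr_edges,
                                 decoy_lr_pairs, build_lr_table)
from rili_scomm.qc import normalize_lognorm
from rili_scomm.radiosensitivity import cluster_condition_fractions
from rili_scomm.lr_network import overexpression_screen, significant_interactions

base = SimConfig(n_clusters=4, cells_per_cluster_pre=300,
                 depletion_factor=(1.0, 0.6, 0.3, 0.05), n_genes=300,
                 cycling_fraction=0.0, seed=0)
planted = plan_lr_edges(base, 2, 0.6)          # two planted L-R edges
cfg = SimConfig(**{**base.__dict__, "planted_lr_edges": planted})
ds = generate_dataset(cfg)

norm = normalize_lognorm(ds.adata)
norm.obs["cluster"] = norm.obs["true_cluster"]

table, _ = cluster_condition_fractions(norm.obs)
print(table[["cluster", "n_pre", "n_post", "unirradiated_ratio",
             "adj_p", "direction"]].round(4).to_string(index=False))
```

```
cluster  n_pre  n_post  unirradiated_ratio  adj_p     direction
     C1    300     300              0.3274 0.0000 enriched_post
     C2    300     178              0.4506 0.0568     unchanged
     C3    300      89              0.6213 0.0000 depleted_post
     C4    300      17              0.8957 0.0000 depleted_post
```

The planted survival factors (1.0, 0.6, 0.3, 0.05) reappear as a rising
unirradiated ratio: C4, which kept only 5% of its cells, scores 0.90 and is
flagged `depleted_post`; the fully surviving C1 is relatively enriched.
Screening the planted edges against 20 decoy pairs recovers exactly the
planted network:

```python
db = build_lr_table(planted, decoy_lr_pairs(base, 20, gene_offset=2))
genes = sorted(set(db.ligand) | set(db.receptor))
screen = overexpression_screen(norm, genes)
edges = significant_interactions(screen, db)
print(edges[["sender", "receiver", "ligand", "receptor", "intensity"]]
      .round(3).to_string(index=False))
```

```
sender receiver ligand receptor  intensity
    C1       C2  g0081    g0082      1.321
    C2       C1  g0083    g0084      1.372
```

The same stages are available from the shell:

```sh
rili-scomm run --config run.ini --outdir out \
    --stages simulate,qc,cluster,annotate,radsens,lrnet,report
```

Each stage writes TSV/JSON artifacts and appends to `out/manifest.json`
(config snapshot, input digests, seeds, counts), so a run can be reproduced
bit for bit from its manifest.

## Package data

* `rili_scomm/data/reference_markers.tsv` — canonical mouse-lung cell-type
  markers used by `assign_cell_types`.
* `rili_scomm/data/lr_pairs.tsv` — a small curated mouse L-R pair fixture
  (users may supply a full pair table via `--lr-db`).
* `rili_scomm/data/cycle_genes.tsv` — standard S/G2M proliferation program
  gene lists in mouse symbol casing.
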