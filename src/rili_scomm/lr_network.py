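"""Ligand-receptor intercellular communication networks.

The screen tests, for every ligand or receptor gene and every cluster,
whether the gene is overexpressed in that cluster against all remaining
cells (one-sided Mann-Whitney, cluster greater).  A directed interaction
edge sender -> receiver exists for a database pair whenever the ligand is
significant in the sender cluster and the receptor in the receiver
cluster; its *intensity* is the sum of the two expression rates (fraction
of the cluster's cells with nonzero normalized expression), and the
*communication strength* between two clusters is the number of significant
pairs between them.  The post- vs pre-irradiation network keeps an edge
only when both genes are significantly upregulated after irradiation
within their respective clusters.

Per-cluster p-values are Bonferroni-adjusted over the tested genes by
default; passing ``correction=None`` reproduces a raw per-test threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import rankdata

from ._stats import EXACT_MAX, bonferroni, mann_whitney_u, normal_p_from_u, tie_term
from .errors import FormatError, RiliError

__all__ = [
    "load_lr_pairs",
    "overexpression_screen",
    "significant_interactions",
    "communication_strength",
    "condition_upregulated_network",
    "export_circos_links",
    "CommunicationMatrix",
]

EDGE_COLUMNS = [
    "sender", "receiver", "ligand", "receptor",
    "ligand_p", "receptor_p", "ligand_rate", "receptor_rate", "intensity",
]


def load_lr_pairs(path) -> pd.DataFrame:
    """Read a ligand/receptor pair TSV into a unique, ordered pair table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    missing = {"ligand", "receptor"} - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks column(s): {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path} contains no pairs")
    bad = df["ligand"].isna() | df["receptor"].isna() | \
        (df["ligand"].str.strip() == "") | (df["receptor"].str.strip() == "")
    if bad.any():
        raise FormatError(f"{path}: {int(bad.sum())} rows with empty ligand/receptor")
    n_before = len(df)
    df = df[["ligand", "receptor"]].drop_duplicates(ignore_index=True)
    if len(df) < n_before:
        warnings.warn(
            f"{path}: collapsed {n_before - len(df)} duplicate pair rows",
            stacklevel=2,
        )
    return df


def _screen_gene(
    col: np.ndarray,
    masks: dict[str, np.ndarray],
    alternative: str = "greater",
) -> dict[str, float]:
    """One-vs-rest rank-test p per cluster for one gene over all cells.

    Shares the rank transform across clusters: the pooled sample of any
    one-vs-rest split is the full cell vector, so ranks and the tie term
    are computed once and the per-cluster p follows the same formulas as
    :func:`rili_scomm._stats.mann_whitney_u`.
    """
    ranks = rankdata(col)
    ties = tie_term(col)
    n = col.size
    out = {}
    for cluster, mask in masks.items():
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 <= EXACT_MAX and n2 <= EXACT_MAX:
            _, p = mann_whitney_u(col[mask], col[~mask], alternative)
        else:
            r1 = float(ranks[mask].sum())
            u = r1 - n1 * (n1 + 1) / 2.0
            p = normal_p_from_u(u, n1, n2, ties, alternative)
        out[cluster] = p
    return out


def overexpression_screen(
    adata: AnnData,
    genes,
    *,
    cluster_key: str = "cluster",
    alpha: float = 0.05,
    min_cells: int = 3,
    correction: str | None = "bonferroni",
) -> pd.DataFrame:
    """Per-(gene, cluster) overexpression records for the L-R screen.

    Returns one row per tested gene and cluster with the one-sided
    (cluster greater than rest) rank-test p-value, its Bonferroni
    adjustment over tested genes within the cluster (identity when
    ``correction=None``), the expression rate, the mean normalized
    expression, and the strict significance call ``adj_p < alpha``.
    """
    if adata.uns.get("layer") != "normalized":
        raise ValueError("overexpression_screen expects a normalized matrix")
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in adata.var_names]
    absent = sorted(set(genes) - set(present))
    if absent:
        warnings.warn(f"{len(absent)} screened genes absent from matrix",
                      stacklevel=2)
    if not present:
        return pd.DataFrame(
            columns=["gene", "cluster", "p_value", "adj_p", "rate",
                     "mean_expr", "significant"]
        )
    labels = adata.obs[cluster_key].astype(str)
    masks = {}
    for cluster in sorted(labels.unique()):
        mask = (labels == cluster).values
        if mask.sum() < min_cells or (~mask).sum() < 1:
            warnings.warn(f"cluster {cluster} below min_cells={min_cells}; "
                          "excluded from screen", stacklevel=2)
            continue
        masks[cluster] = mask
    if not masks:
        raise RiliError("no cluster passes min_cells")

    X = sp.csc_matrix(adata[:, present].X)
    m = len(present)
    rows = []
    for j, gene in enumerate(present):
        col = np.asarray(X[:, j].todense()).ravel()
        pvals = _screen_gene(col, masks, "greater")
        for cluster, mask in masks.items():
            p = pvals[cluster]
            adj = float(bonferroni(p, m)) if correction == "bonferroni" else p
            rate = float((col[mask] > 0).mean())
            rows.append((gene, cluster, p, adj, rate,
                         float(col[mask].mean()), adj < alpha))
    return pd.DataFrame(
        rows,
        columns=["gene", "cluster", "p_value", "adj_p", "rate", "mean_expr",
                 "significant"],
    )


def significant_interactions(
    screen: pd.DataFrame,
    db: pd.DataFrame,
    *,
    include_self: bool = True,
) -> pd.DataFrame:
    """Directed edges for every db pair significant at both ends.

    For each (ligand, receptor) pair, an edge sender -> receiver is emitted
    for every cluster where the ligand is significant crossed with every
    cluster where the receptor is significant (autocrine sender == receiver
    edges included unless ``include_self`` is False).
    """
    sig = screen[screen["significant"]]
    by_gene: dict[str, list[tuple[str, float, float]]] = {}
    for rec in sig.itertuples():
        by_gene.setdefault(rec.gene, []).append(
            (rec.cluster, rec.p_value, rec.rate)
        )
    rows = []
    for pair in db.itertuples():
        for s_cluster, lp, lrate in by_gene.get(pair.ligand, ()):
            for r_cluster, rp, rrate in by_gene.get(pair.receptor, ()):
                if not include_self and s_cluster == r_cluster:
                    continue
                rows.append((s_cluster, r_cluster, pair.ligand, pair.receptor,
                             lp, rp, lrate, rrate, lrate + rrate))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


@dataclass
class CommunicationMatrix:
    """Directed cluster x cluster counts of significant L-R pairs."""

    directed: pd.DataFrame

    @property
    def undirected(self) -> pd.DataFrame:
        """Both directions summed; autocrine pairs counted once."""
        und = self.directed + self.directed.T
        diag = np.diag(self.directed.to_numpy()).copy()
        und = und.copy()
        np.fill_diagonal(und.values, diag)
        return und

    @property
    def total(self) -> int:
        return int(self.directed.to_numpy().sum())


def communication_strength(
    edges: pd.DataFrame, clusters=None
) -> CommunicationMatrix:
    """Count significant pairs per directed (sender, receiver) cluster pair."""
    if clusters is None:
        clusters = sorted(
            set(edges["sender"]) | set(edges["receiver"])
        ) if len(edges) else []
    clusters = list(clusters)
    mat = pd.DataFrame(0, index=clusters, columns=clusters, dtype=int)
    for rec in edges.itertuples():
        mat.loc[rec.sender, rec.receiver] += 1
    return CommunicationMatrix(directed=mat)


def condition_upregulated_network(
    adata: AnnData,
    db: pd.DataFrame,
    *,
    cluster_key: str = "cluster",
    condition_key: str = "condition",
    pre_label: str = "pre",
    post_label: str = "post",
    alpha: float = 0.05,
    min_cells: int = 3,
    correction: str | None = "bonferroni",
    include_self: bool = True,
) -> pd.DataFrame:
    """Edges whose ligand and receptor are both upregulated post-irradiation.

    Within each cluster, every db gene is tested post vs pre (one-sided
    rank-sum, post greater) and called upregulated at ``adj_p < alpha``
    with a positive post-vs-pre log fold change; an edge survives when the
    ligand is upregulated in the sender and the receptor in the receiver.
    Rates are computed on post-irradiation cells.  Clusters lacking
    ``min_cells`` cells in either condition are excluded with a warning.
    """
    if adata.uns.get("layer") != "normalized":
        raise ValueError("condition_upregulated_network expects a normalized matrix")
    cond = adata.obs[condition_key].astype(str)
    for label in (pre_label, post_label):
        if not (cond == label).any():
            raise RiliError(f"condition {label!r} absent from dataset")
    genes = list(dict.fromkeys(
        list(db["ligand"]) + list(db["receptor"])
    ))
    present = [g for g in genes if g in adata.var_names]
    if not present:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    labels = adata.obs[cluster_key].astype(str)
    Xg = sp.csc_matrix(adata[:, present].X)
    m = len(present)
    up: dict[str, dict[str, tuple[float, float]]] = {}
    for cluster in sorted(labels.unique()):
        cmask = (labels == cluster).values
        post_mask = cmask & (cond == post_label).values
        pre_mask = cmask & (cond == pre_label).values
        if post_mask.sum() < min_cells or pre_mask.sum() < min_cells:
            warnings.warn(
                f"cluster {cluster} lacks {min_cells} cells in a condition; "
                "excluded from the condition network", stacklevel=2,
            )
            continue
        for j, gene in enumerate(present):
            col = np.asarray(Xg[:, j].todense()).ravel()
            post_vals = col[post_mask]
            pre_vals = col[pre_mask]
            _, p = mann_whitney_u(post_vals, pre_vals, "greater")
            adj = float(bonferroni(p, m)) if correction == "bonferroni" else p
            logfc = float(
                np.log(np.expm1(post_vals).mean() + 1)
                - np.log(np.expm1(pre_vals).mean() + 1)
            )
            if adj < alpha and logfc > 0:
                rate_post = float((post_vals > 0).mean())
                up.setdefault(gene, {})[cluster] = (p, rate_post)

    rows = []
    for pair in db.itertuples():
        for s_cluster, (lp, lrate) in up.get(pair.ligand, {}).items():
            for r_cluster, (rp, rrate) in up.get(pair.receptor, {}).items():
                if not include_self and s_cluster == r_cluster:
                    continue
                rows.append((s_cluster, r_cluster, pair.ligand, pair.receptor,
                             lp, rp, lrate, rrate, lrate + rrate))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def export_circos_links(
    edges: pd.DataFrame,
    strengths: CommunicationMatrix,
    path,
    *,
    allow_empty: bool = False,
) -> None:
    """Write a Circos-style link table plus the long-form edge TSV.

    ``path`` receives one ``sender<TAB>receiver<TAB>weight`` line per
    nonzero directed cluster pair (weight = significant-pair count); the
    full edge list goes to ``<path>.edges.tsv``.
    """
    if edges.empty and not allow_empty:
        raise ValueError("no edges to export (pass allow_empty=True to force)")
    path = Path(path)
    links = (
        strengths.directed.stack().rename("weight").reset_index()
    )
    links.columns = ["sender", "receiver", "weight"]
    links = links[links["weight"] > 0]
    links.to_csv(path, sep="\t", index=False)
    edges.to_csv(path.with_suffix(path.suffix + ".edges.tsv"),
                 sep="\t", index=False)
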