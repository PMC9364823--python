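"""Marker detection, cell-type assignment, condition DE, gene intersections.

One-vs-rest marker genes are screened with a two-sided Wilcoxon rank-sum
test and Bonferroni adjustment over tested genes; the reported fold change
is the natural log of the ratio of mean de-logged (expm1) normalized
expression between the cluster and the rest, each side offset by a
pseudocount of 1.  Defaults (avg_logFC > 1, adjusted p < 0.01) are the
screening thresholds used throughout the package.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from ._stats import bonferroni, mann_whitney_u
from .errors import FormatError

__all__ = [
    "find_markers",
    "condition_de",
    "assign_cell_types",
    "common_upregulated_genes",
    "load_reference_markers",
]


def _require_normalized(adata: AnnData, op: str):
    if adata.uns.get("layer") != "normalized":
        raise ValueError(f"{op} expects a normalized matrix")


def _group_stats(X: sp.csc_matrix, mask: np.ndarray):
    """(mean expm1 expression, nonzero rate) per gene for cells in ``mask``."""
    sub = X[mask]
    expm1 = sub.copy()
    expm1.data = np.expm1(expm1.data)
    mean = np.asarray(expm1.mean(axis=0)).ravel()
    rate = np.asarray((sub > 0).mean(axis=0)).ravel()
    return mean, rate


def _rank_table(
    X: sp.csc_matrix,
    in_mask: np.ndarray,
    genes: pd.Index,
    alternative: str,
) -> pd.DataFrame:
    """Per-gene rank-test p-values plus fold changes for one two-group split."""
    mean_in, rate_in = _group_stats(X, in_mask)
    mean_out, rate_out = _group_stats(X, ~in_mask)
    logfc = np.log(mean_in + 1) - np.log(mean_out + 1)
    pvals = np.empty(len(genes))
    for j in range(len(genes)):
        col = np.asarray(X[:, j].todense()).ravel()
        _, pvals[j] = mann_whitney_u(col[in_mask], col[~in_mask], alternative)
    return pd.DataFrame({
        "gene": genes,
        "avg_logFC": logfc,
        "p_value": pvals,
        "pct_in": rate_in,
        "pct_out": rate_out,
    })


def find_markers(
    adata: AnnData,
    target_cluster: str,
    *,
    cluster_key: str = "cluster",
    logfc_min: float = 1.0,
    adj_p_max: float = 0.01,
    genes=None,
    return_all: bool = False,
) -> pd.DataFrame:
    """One-vs-rest marker genes of ``target_cluster``.

    Returns genes with ``avg_logFC > logfc_min`` and Bonferroni-adjusted
    two-sided rank-sum ``adj_p < adj_p_max``, sorted by descending
    ``avg_logFC``; ``return_all`` skips the filter (the adjustment is still
    over all tested genes).
    """
    _require_normalized(adata, "find_markers")
    labels = adata.obs[cluster_key].astype(str)
    if target_cluster not in set(labels):
        raise ValueError(f"unknown cluster {target_cluster!r}")
    in_mask = (labels == target_cluster).values
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("need >= 3 cells in the cluster and in the rest")

    if genes is not None:
        genes = [g for g in genes if g in adata.var_names]
        view = adata[:, genes]
    else:
        view = adata
    X = sp.csc_matrix(view.X)
    table = _rank_table(X, in_mask, view.var_names, "two-sided")
    table["cluster"] = target_cluster
    table["adj_p"] = bonferroni(table["p_value"].values, len(table))
    table = table[["gene", "cluster", "avg_logFC", "p_value", "adj_p",
                   "pct_in", "pct_out"]]
    table = table.sort_values("avg_logFC", ascending=False, ignore_index=True)
    if return_all:
        return table
    keep = (table["avg_logFC"] > logfc_min) & (table["adj_p"] < adj_p_max)
    return table[keep].reset_index(drop=True)


def condition_de(
    adata: AnnData,
    target_cluster: str,
    *,
    cluster_key: str = "cluster",
    condition_key: str = "condition",
    pre_label: str = "pre",
    post_label: str = "post",
    p_max: float = 0.05,
    genes=None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Genes upregulated post- vs pre-irradiation within one cluster.

    One-sided (post greater) rank-sum test at raw ``p < p_max`` with a
    positive post-vs-pre fold change.
    """
    _require_normalized(adata, "condition_de")
    labels = adata.obs[cluster_key].astype(str)
    if target_cluster not in set(labels):
        raise ValueError(f"unknown cluster {target_cluster!r}")
    sub = adata[(labels == target_cluster).values]
    cond = sub.obs[condition_key].astype(str)
    post_mask = (cond == post_label).values
    pre_mask = (cond == pre_label).values
    if post_mask.sum() < 3 or pre_mask.sum() < 3:
        raise ValueError(
            f"cluster {target_cluster} needs >= 3 cells in each condition"
        )
    sub = sub[post_mask | pre_mask]
    if genes is not None:
        genes = [g for g in genes if g in sub.var_names]
        sub = sub[:, genes]
    X = sp.csc_matrix(sub.X)
    in_mask = (sub.obs[condition_key].astype(str) == post_label).values
    table = _rank_table(X, in_mask, sub.var_names, "greater")
    table["cluster"] = target_cluster
    table = table.rename(columns={"pct_in": "pct_post", "pct_out": "pct_pre"})
    table = table.sort_values("avg_logFC", ascending=False, ignore_index=True)
    if return_all:
        return table
    keep = (table["p_value"] < p_max) & (table["avg_logFC"] > 0)
    return table[keep].reset_index(drop=True)


def assign_cell_types(
    adata: AnnData,
    reference: dict[str, list[str]],
    *,
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Map each cluster to the reference type with the highest mean scaled
    expression of its marker set within the cluster.

    Scaled expression is the per-gene z-score across all cells.  A score
    tie goes to the lexicographically smallest type name and is flagged.
    """
    _require_normalized(adata, "assign_cell_types")
    if not reference or any(len(v) == 0 for v in reference.values()):
        raise ValueError("reference marker sets must be non-empty")
    present = {
        t: [g for g in gs if g in adata.var_names] for t, gs in reference.items()
    }
    if not any(present.values()):
        raise ValueError("no reference marker gene is present in the matrix")

    used = sorted({g for gs in present.values() for g in gs})
    M = np.asarray(adata[:, used].X.todense(), dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    Z = (M - mu) / np.where(sd > 0, sd, 1.0)
    zcols = {g: Z[:, j] for j, g in enumerate(used)}

    labels = adata.obs[cluster_key].astype(str)
    rows = []
    for cluster in sorted(labels.unique()):
        mask = (labels == cluster).values
        scores = {}
        for t, gs in present.items():
            if not gs:
                continue
            scores[t] = float(np.mean([zcols[g][mask].mean() for g in gs]))
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        rows.append((cluster, winners[0], best, len(winners) > 1))
    return pd.DataFrame(
        rows, columns=["cluster", "cell_type", "score", "tie"]
    ).set_index("cluster")


def common_upregulated_genes(de_lists) -> list[str]:
    """Exact intersection of per-cell-type upregulated gene lists, sorted."""
    de_lists = list(de_lists)
    if not de_lists:
        raise ValueError("need at least one gene list")
    common = set(de_lists[0])
    for lst in de_lists[1:]:
        common &= set(lst)
    return sorted(common)


def load_reference_markers(path=None) -> dict[str, list[str]]:
    """Load a (cell_type, gene) TSV; defaults to the packaged mouse-lung set."""
    if path is None:
        source = importlib.resources.files("rili_scomm.data").joinpath(
            "reference_markers.tsv"
        )
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(Path(path), sep="\t")
    if not {"cell_type", "gene"}.issubset(df.columns):
        raise FormatError("reference marker TSV needs cell_type and gene columns")
    return {
        t: list(g["gene"]) for t, g in df.groupby("cell_type", sort=True)
    }
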