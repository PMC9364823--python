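"""Per-cluster radiosensitivity from pre/post composition, and cell cycle.

Radiosensitivity is read off compositional change: for each cluster the
pre- and post-irradiation cell fractions (each normalized within its
condition) give the *unirradiated ratio* ``frac_pre / (frac_pre +
frac_post)`` -- near 1 for clusters depleted by irradiation (sensitive),
near 0 for clusters enriched afterwards.  Enrichment/depletion is tested
per cluster with a Pearson chi-square on the 2x2 (cluster vs rest) x
(pre vs post) table, Bonferroni-adjusted over clusters.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.stats import chi2_contingency, linregress

from ._stats import bonferroni
from .errors import RiliError

__all__ = [
    "cluster_condition_fractions",
    "composition_chi_square",
    "assign_cell_cycle_phase",
    "sensitivity_cycle_correlation",
    "CorrelationResult",
]


def composition_chi_square(
    n_pre_cluster: int,
    n_post_cluster: int,
    total_pre: int,
    total_post: int,
    *,
    yates: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square (1 df) for one cluster's pre/post enrichment.

    The 2x2 table contrasts (cluster, rest) against (pre, post); no
    continuity correction by default (counts here are typically in the
    thousands).
    """
    table = np.array(
        [
            [n_pre_cluster, total_pre - n_pre_cluster],
            [n_post_cluster, total_post - n_post_cluster],
        ],
        dtype=float,
    )
    if (table < 0).any():
        raise ValueError("cluster counts exceed condition totals")
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise ValueError("all marginals of the 2x2 table must be positive")
    res = chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def cluster_condition_fractions(
    annotations: pd.DataFrame,
    *,
    cluster_key: str = "cluster",
    condition_key: str = "condition",
    pre_label: str = "pre",
    post_label: str = "post",
    min_cells: int = 50,
    alpha: float = 0.05,
    yates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster composition table over clusters with > ``min_cells`` cells.

    Returns ``(included, excluded)``: the main table carries condition
    fractions (normalized over the included clusters), the unirradiated
    ratio, the per-cluster chi-square against the rest, Bonferroni-adjusted
    p-values, and a direction call at ``adj_p < alpha``; clusters at or
    below ``min_cells`` total cells are reported separately with raw counts
    only.
    """
    cond = annotations[condition_key].astype(str)
    labels = annotations[cluster_key].astype(str)
    counts = (
        pd.crosstab(labels, cond)
        .reindex(columns=[pre_label, post_label], fill_value=0)
    )
    if (counts[pre_label].sum() == 0) or (counts[post_label].sum() == 0):
        raise RiliError("both conditions must contain at least one cell")

    total = counts.sum(axis=1)
    included = counts[total > min_cells]
    excluded = counts[total <= min_cells].rename(
        columns={pre_label: "n_pre", post_label: "n_post"}
    )
    if included.empty:
        raise RiliError(f"no cluster exceeds min_cells={min_cells}")

    total_pre = int(included[pre_label].sum())
    total_post = int(included[post_label].sum())
    rows = []
    for cluster, row in included.iterrows():
        n_pre, n_post = int(row[pre_label]), int(row[post_label])
        chi2, p = composition_chi_square(
            n_pre, n_post, total_pre, total_post, yates=yates
        )
        frac_pre = n_pre / total_pre
        frac_post = n_post / total_post
        rows.append(
            (cluster, n_pre, n_post, frac_pre, frac_post,
             frac_pre / (frac_pre + frac_post), chi2, p)
        )
    out = pd.DataFrame(
        rows,
        columns=["cluster", "n_pre", "n_post", "frac_pre", "frac_post",
                 "unirradiated_ratio", "chi2_stat", "p_value"],
    )
    out["adj_p"] = bonferroni(out["p_value"].values, len(out))
    significant = out["adj_p"] < alpha
    out["direction"] = np.select(
        [significant & (out["frac_post"] < out["frac_pre"]),
         significant & (out["frac_post"] > out["frac_pre"])],
        ["depleted_post", "enriched_post"],
        default="unchanged",
    )
    return out, excluded.reset_index()


def assign_cell_cycle_phase(
    adata: AnnData,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    *,
    g0_quantile: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Call G0/G1/S/G2M per cell from S and G2M program scores.

    Each program score is the mean normalized expression of the gene set
    minus that of an expression-matched random background set (fixed
    ``seed``).  A cell is S when ``s_score > 0`` and ``s_score >=
    g2m_score``, G2M when ``g2m_score > 0`` and ``g2m_score > s_score``.
    Remaining (non-cycling) cells split into G0 and G1 by their combined
    program score: at or below the ``g0_quantile`` quantile of non-cycling
    cells -> G0 (quiescent), above -> G1.
    """
    if adata.uns.get("layer") != "normalized":
        raise ValueError("assign_cell_cycle_phase expects a normalized matrix")
    s_genes = [g for g in s_genes if g in adata.var_names]
    g2m_genes = [g for g in g2m_genes if g in adata.var_names]
    if not s_genes or not g2m_genes:
        raise ValueError("need >= 1 S gene and >= 1 G2M gene present in matrix")
    if not (0 <= g0_quantile <= 1):
        raise ValueError("g0_quantile must lie in [0, 1]")
    import scanpy as sc

    work = adata.copy()
    # scale the background-matching machinery down gracefully on small panels
    ctrl = int(max(5, min(50, work.n_vars // 4)))
    n_bins = int(max(2, min(25, work.n_vars // 6)))
    sc.tl.score_genes(work, s_genes, score_name="s_score",
                      ctrl_size=ctrl, n_bins=n_bins, random_state=seed)
    sc.tl.score_genes(work, g2m_genes, score_name="g2m_score",
                      ctrl_size=ctrl, n_bins=n_bins, random_state=seed)
    s = work.obs["s_score"].to_numpy(dtype=float)
    g2m = work.obs["g2m_score"].to_numpy(dtype=float)

    phase = np.full(adata.n_obs, "G1", dtype=object)
    phase[(s > 0) & (s >= g2m)] = "S"
    phase[(g2m > 0) & (g2m > s)] = "G2M"
    noncycling = (phase == "G1")
    combined = s + g2m
    if noncycling.any():
        threshold = float(np.quantile(combined[noncycling], g0_quantile))
        phase[noncycling & (combined <= threshold)] = "G0"
    return pd.DataFrame(
        {"barcode": adata.obs_names, "s_score": s, "g2m_score": g2m,
         "phase": phase}
    ).set_index("barcode")


class CorrelationResult(NamedTuple):
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def sensitivity_cycle_correlation(
    composition: pd.DataFrame,
    phase_by_cell: pd.DataFrame,
    *,
    cluster_key: str = "cluster",
    phase_key: str = "phase",
) -> CorrelationResult:
    """Pearson correlation of per-cluster unirradiated ratio vs G0 fraction.

    ``phase_by_cell`` must carry one row per cell with its cluster label
    and called phase; the G0 fraction is taken over all four phases.
    Returns r, the two-sided t-test p, and the least-squares line.
    """
    g0 = (
        phase_by_cell.assign(is_g0=phase_by_cell[phase_key].astype(str) == "G0")
        .groupby(cluster_key, observed=True)["is_g0"]
        .mean()
    )
    merged = composition.set_index("cluster").join(g0.rename("g0_fraction"),
                                                   how="inner")
    if len(merged) < 3:
        raise ValueError("need >= 3 clusters with both composition and phases")
    x = merged["unirradiated_ratio"].to_numpy(dtype=float)
    y = merged["g0_fraction"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in unirradiated ratio or G0 fraction")
    fit = linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue), p=float(fit.pvalue),
        slope=float(fit.slope), intercept=float(fit.intercept), n=len(merged),
    )
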