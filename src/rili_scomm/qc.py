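"""Reading 10x-style triplet data, quality control, normalization, clustering.

Quality-control semantics follow the strict-exclusion convention: a cell is
removed when it detects *fewer than* ``min_genes_per_cell`` or *more than*
``max_genes_per_cell`` genes, or when *more than* ``max_mito_fraction`` of
its UMIs come from mitochondrial genes; a cell sitting exactly on a bound is
retained.  Gene and cell masks are both computed on the input matrix and
applied in a single pass (no iteration to a fixpoint), matching the
create-then-filter behaviour of the standard toolkits.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .errors import EmptyResultError, FormatError

__all__ = [
    "QcThresholds",
    "QcSummary",
    "read_10x_triplet",
    "filter_cells_genes",
    "normalize_lognorm",
    "summarize_qc",
    "cluster_cells",
]

MITO_REGEX = r"(?i)^mt-"


@dataclass(frozen=True)
class QcThresholds:
    """Cell/gene retention bounds (defaults: 500-8000 genes, 15% mito, 3 cells)."""

    min_genes_per_cell: int = 500
    max_genes_per_cell: int = 8000
    max_mito_fraction: float = 0.15
    min_cells_per_gene: int = 3
    mito_regex: str = MITO_REGEX

    def __post_init__(self):
        if not (0 < self.min_genes_per_cell < self.max_genes_per_cell):
            raise ValueError("need 0 < min_genes_per_cell < max_genes_per_cell")
        if not (0 < self.max_mito_fraction < 1):
            raise ValueError("max_mito_fraction must be in (0, 1)")


@dataclass
class QcSummary:
    n_cells: int
    n_genes: int
    mean_genes_per_cell: float
    mean_umis_per_cell: float
    per_sample: pd.DataFrame | None = None


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"{stem}[.gz] not found in {directory}")


def _read_lines(path: Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_10x_triplet(directory) -> AnnData:
    """Read matrix.mtx(.gz) + features/barcodes(.tsv[.gz]) into an AnnData.

    The returned object is cells x genes with raw integer counts; a
    ``metadata.tsv`` with a ``barcode`` column, when present, is merged
    into ``obs``.  Header/entry mismatches and duplicate barcodes or gene
    symbols raise :class:`FormatError`.
    """
    directory = Path(directory)
    mtx = _find(directory, "matrix.mtx")
    try:
        with _open_maybe_gzip(mtx) as fh:
            X = scipy.io.mmread(fh)
    except Exception as exc:  # malformed header or truncated entries
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc

    genes = [line.split("\t")[1] if "\t" in line else line
             for line in _read_lines(_find(directory, "features.tsv"))]
    barcodes = _read_lines(_find(directory, "barcodes.tsv"))
    if X.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {X.shape} but features/barcodes declare "
            f"({len(genes)}, {len(barcodes)})"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate barcode in barcodes.tsv")
    if len(set(genes)) != len(genes):
        raise FormatError("duplicate gene symbol in features.tsv")

    adata = AnnData(
        X=sp.csr_matrix(X.T).astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["layer"] = "raw"

    meta_path = None
    for name in ("metadata.tsv", "metadata.tsv.gz"):
        if (directory / name).exists():
            meta_path = directory / name
            break
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "barcode" not in meta.columns:
            raise FormatError("metadata.tsv lacks a 'barcode' column")
        meta = meta.set_index("barcode")
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise FormatError(f"metadata.tsv missing {len(missing)} barcodes")
        for col in meta.columns:
            adata.obs[col] = meta.loc[adata.obs_names, col].values
    return adata


def _require_raw(adata: AnnData, op: str):
    if adata.uns.get("layer") == "normalized":
        raise ValueError(f"{op} expects raw counts, got a normalized matrix")


def filter_cells_genes(adata: AnnData, thresholds: QcThresholds | None = None) -> AnnData:
    """Apply the QC filters in one pass over the input matrix.

    Raises :class:`EmptyResultError` (with diagnostic counts attached) when
    no cell survives.
    """
    thresholds = thresholds or QcThresholds()
    _require_raw(adata, "filter_cells_genes")
    X = sp.csr_matrix(adata.X)

    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = np.array(
        [bool(re.match(thresholds.mito_regex, g)) for g in adata.var_names]
    )
    mito_counts = (
        np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        if mito_mask.any() else np.zeros(adata.n_obs)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    keep_cells = (
        (detected >= thresholds.min_genes_per_cell)
        & (detected <= thresholds.max_genes_per_cell)
        & (mito_frac <= thresholds.max_mito_fraction)
    )
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene

    if not keep_cells.any():
        raise EmptyResultError(
            "QC removed every cell",
            n_cells_in=adata.n_obs,
            n_low_genes=int((detected < thresholds.min_genes_per_cell).sum()),
            n_high_genes=int((detected > thresholds.max_genes_per_cell).sum()),
            n_high_mito=int((mito_frac > thresholds.max_mito_fraction).sum()),
        )
    out = adata[keep_cells, keep_genes].copy()
    out.uns["layer"] = "raw"
    out.uns["qc"] = {
        "cells_removed": int((~keep_cells).sum()),
        "genes_removed": int((~keep_genes).sum()),
    }
    return out


def normalize_lognorm(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Library-size normalization to ``scale`` counts per cell, then ln(1+x).

    Raw counts are kept in ``layers['counts']``; entry (c, g) becomes
    ``ln(1 + scale * count / total_counts(c))``.
    """
    _require_raw(adata, "normalize_lognorm")
    if scale <= 0:
        raise ValueError("scale must be positive")
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(
            f"{int((totals == 0).sum())} cells have zero total counts; run QC first"
        )
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    norm = sp.diags(scale / totals) @ X
    norm.data = np.log1p(norm.data)
    out.X = norm.tocsr()
    out.uns["layer"] = "normalized"
    return out


def summarize_qc(adata: AnnData, sample_key: str | None = "sample") -> QcSummary:
    """Cell/gene tallies: mean detected genes and mean UMIs per cell."""
    _require_raw(adata, "summarize_qc")
    X = sp.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    per_sample = None
    if sample_key is not None and sample_key in adata.obs:
        per_sample = (
            pd.DataFrame({
                "sample": adata.obs[sample_key].values,
                "genes": detected,
                "umis": totals,
            })
            .groupby("sample", observed=True)
            .agg(n_cells=("genes", "size"),
                 mean_genes=("genes", "mean"),
                 mean_umis=("umis", "mean"))
            .reset_index()
        )
    return QcSummary(
        n_cells=adata.n_obs,
        n_genes=adata.n_vars,
        mean_genes_per_cell=float(detected.mean()) if adata.n_obs else 0.0,
        mean_umis_per_cell=float(totals.mean()) if adata.n_obs else 0.0,
        per_sample=per_sample,
    )


def cluster_cells(
    adata: AnnData,
    resolution: float = 2.0,
    seed: int = 0,
    *,
    n_neighbors: int = 15,
    key: str = "cluster",
    external: str | pd.Series | None = None,
) -> pd.Series:
    """Graph clustering (PCA -> SNN graph -> Leiden) at ``resolution``.

    When ``external`` names an ``obs`` column (or supplies a Series of
    labels), those labels are passed through unmodified instead -- the
    pipeline's contribution lies downstream of cluster labels, so
    externally aligned clusterings are first-class inputs.
    Labels are written to ``obs[key]`` and returned.
    """
    if external is not None:
        labels = (adata.obs[external] if isinstance(external, str)
                  else pd.Series(external, index=adata.obs_names))
        adata.obs[key] = labels.astype(str).values
        return adata.obs[key]
    if adata.uns.get("layer") != "normalized":
        raise ValueError("cluster_cells expects a normalized matrix")
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to cluster")
    if adata.n_obs <= n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be < n_cells={adata.n_obs}"
        )
    import scanpy as sc

    work = adata.copy()
    n_comps = int(min(50, work.n_obs - 1, work.n_vars - 1))
    sc.pp.pca(work, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(work, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.leiden(
        work, resolution=resolution, random_state=seed, key_added=key,
        flavor="igraph", n_iterations=2, directed=False,
    )
    labels = "C" + (work.obs[key].astype(int) + 1).astype(str)
    adata.obs[key] = labels.values
    return adata.obs[key]
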