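"""Synthetic 10x-style count data with planted radiosensitivity structure.

The generator emulates the structure of a two-condition (pre/post thoracic
irradiation) mouse-lung single-cell experiment:

* a fixed number of clusters, each with disjoint marker-gene programs;
* post-irradiation cell numbers binomially thinned per cluster by a
  "survival" (depletion) factor in [0, 1] -- radiosensitivity acts on cell
  composition, not on expression;
* per-cluster fractions of cycling cells carrying an S- or G2M-phase
  gene program;
* mitochondrial genes ("mt-" prefix) fed by a per-cell Beta-distributed
  fraction of the cell's library, so the mitochondrial QC filter has
  something to bite on;
* planted ligand-receptor edges: the ligand's nonzero-expression rate is
  boosted in the sender cluster and the receptor's in the receiver
  cluster, either in both conditions or (for condition-specific edges)
  only in post-irradiation cells.

Counts follow a negative binomial per gene (gamma-Poisson mixture) with a
log-normal spread of baseline means across genes.  All randomness flows
from a single ``numpy.random.default_rng(seed)`` stream, so an identical
configuration reproduces a bit-identical dataset.
"""

from __future__ import annotations

import numbers
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .errors import ConfigurationError

__all__ = [
    "LREdgeSpec",
    "SimConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "write_10x_triplet",
    "plan_lr_edges",
    "decoy_lr_pairs",
    "build_lr_table",
]

STRAINS = ("C57BL/6N", "C3H/HeN")
_STRAIN_SHORT = {"C57BL/6N": "B6", "C3H/HeN": "C3H"}


@dataclass(frozen=True)
class LREdgeSpec:
    """A planted directed ligand->receptor interaction between two clusters."""

    sender: str
    receiver: str
    ligand: str
    receptor: str
    rate_boost: float

    def key(self) -> tuple[str, str, str, str]:
        return (self.sender, self.receiver, self.ligand, self.receptor)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a desk-scale version of the study design: 10 clusters
    over two conditions and two strains (four samples), depletion factors
    spanning resistant (1.0) to highly radiosensitive (0.05), overdispersed
    counts, ~5% mitochondrial content, and a 10-gene marker program per
    cluster.
    """

    n_clusters: int = 10
    cells_per_cluster_pre: int | Sequence[int] = 500
    # None: survival factors evenly spaced from resistant (1.0) down to
    # highly radiosensitive (0.05) across the clusters
    depletion_factor: float | Sequence[float] | None = None
    n_genes: int = 1000
    n_marker_genes_per_cluster: int = 10
    marker_log_effect: float = 2.0
    nb_mean: float = 0.3
    nb_dispersion: float = 0.5
    mito_gene_count: int = 13
    mito_fraction_mean: float = 0.05
    mito_concentration: float = 30.0
    cycling_fraction: float | Sequence[float] = 0.3
    s_gene_count: int = 20
    g2m_gene_count: int = 20
    planted_lr_edges: Sequence[LREdgeSpec] = ()
    planted_condition_lr_edges: Sequence[LREdgeSpec] = ()
    lr_boost_mean: float = 3.0
    seed: int = 0

    # --- derived vocabulary -------------------------------------------------

    @property
    def cluster_names(self) -> list[str]:
        return [f"C{k + 1}" for k in range(self.n_clusters)]

    @property
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        names = [f"g{j + 1:0{width}d}" for j in range(self.n_genes)]
        names += [f"mt-{j + 1}" for j in range(self.mito_gene_count)]
        return names

    def marker_genes(self) -> dict[str, list[str]]:
        names = self.gene_names
        nm = self.n_marker_genes_per_cluster
        return {
            c: names[k * nm: (k + 1) * nm]
            for k, c in enumerate(self.cluster_names)
        }

    def cycle_genes(self) -> tuple[list[str], list[str]]:
        names = self.gene_names
        start = self.n_clusters * self.n_marker_genes_per_cluster
        s = names[start: start + self.s_gene_count]
        g2m = names[start + self.s_gene_count:
                    start + self.s_gene_count + self.g2m_gene_count]
        return s, g2m

    def free_genes(self) -> list[str]:
        """Genes carrying no marker or cycle program (LR-plant candidates)."""
        start = (self.n_clusters * self.n_marker_genes_per_cluster
                 + self.s_gene_count + self.g2m_gene_count)
        return self.gene_names[start: self.n_genes]

    # --- validation ---------------------------------------------------------

    def _per_cluster(self, value, name: str, dtype=float) -> np.ndarray:
        if isinstance(value, numbers.Number):
            arr = np.full(self.n_clusters, value, dtype=dtype)
        else:
            arr = np.asarray(list(value), dtype=dtype)
        if arr.shape != (self.n_clusters,):
            raise ConfigurationError(
                f"{name} must be scalar or length {self.n_clusters}, "
                f"got shape {arr.shape}"
            )
        return arr

    def resolved(self) -> "SimConfig":
        """Validate and return a copy with per-cluster fields as arrays."""
        if self.n_clusters < 1 or self.n_genes < 1:
            raise ConfigurationError("n_clusters and n_genes must be positive")
        if self.mito_gene_count < 1:
            raise ConfigurationError("mito_gene_count must be >= 1")
        if not (0 <= self.mito_fraction_mean < 1):
            raise ConfigurationError("mito_fraction_mean must be in [0, 1)")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("nb_mean and nb_dispersion must be > 0")
        if self.marker_log_effect <= 0:
            raise ConfigurationError("marker_log_effect must be > 0")
        cells = self._per_cluster(self.cells_per_cluster_pre,
                                  "cells_per_cluster_pre", dtype=int)
        if (cells < 1).any():
            raise ConfigurationError("all cluster cell counts must be >= 1")
        depletion = self.depletion_factor
        if depletion is None:
            depletion = np.linspace(1.0, 0.05, self.n_clusters)
        depl = self._per_cluster(depletion, "depletion_factor")
        if ((depl < 0) | (depl > 1)).any():
            raise ConfigurationError("depletion factors must lie in [0, 1]")
        cyc = self._per_cluster(self.cycling_fraction, "cycling_fraction")
        if ((cyc < 0) | (cyc > 1)).any():
            raise ConfigurationError("cycling fractions must lie in [0, 1]")
        program = (self.n_clusters * self.n_marker_genes_per_cluster
                   + self.s_gene_count + self.g2m_gene_count)
        if program > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {program} program genes"
            )
        universe = set(self.gene_names)
        clusters = set(self.cluster_names)
        for edge in (*self.planted_lr_edges, *self.planted_condition_lr_edges):
            if edge.sender not in clusters or edge.receiver not in clusters:
                raise ConfigurationError(f"planted edge {edge} names an unknown cluster")
            if edge.ligand not in universe or edge.receptor not in universe:
                raise ConfigurationError(f"planted edge {edge} names an unknown gene")
            if not (0 < edge.rate_boost <= 1):
                raise ConfigurationError("rate_boost must lie in (0, 1]")
        return replace(self, cells_per_cluster_pre=cells,
                       depletion_factor=depl, cycling_fraction=cyc)


@dataclass
class GroundTruth:
    """The planted structure of a synthetic dataset; downstream test oracle."""

    depletion: dict[str, float]
    markers: dict[str, list[str]]
    s_genes: list[str]
    g2m_genes: list[str]
    cells: pd.DataFrame  # barcode-indexed: true_cluster, condition, true_phase
    planted_lr_edges: list[LREdgeSpec]
    planted_condition_lr_edges: list[LREdgeSpec]
    free_genes: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    """Counts plus annotations plus the ground truth that generated them."""

    adata: AnnData
    truth: GroundTruth

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars


def _nb_counts(rng, mean: np.ndarray, dispersion: float, n_cells: int):
    """Gamma-Poisson draws, one row per cell. ``mean`` is per gene."""
    lam = rng.gamma(dispersion, np.broadcast_to(mean / dispersion,
                                               (n_cells, mean.size)))
    return rng.poisson(lam)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one dataset under ``config``; same config => identical output."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)

    gene_names = cfg.gene_names
    n_plain = cfg.n_genes
    n_mito = cfg.mito_gene_count
    markers = cfg.marker_genes()
    s_genes, g2m_genes = cfg.cycle_genes()
    gene_index = {g: j for j, g in enumerate(gene_names)}
    s_idx = np.array([gene_index[g] for g in s_genes], dtype=int)
    g2m_idx = np.array([gene_index[g] for g in g2m_genes], dtype=int)

    base_mean = cfg.nb_mean * rng.lognormal(0.0, 0.5, n_plain)

    n_pre = np.asarray(cfg.cells_per_cluster_pre)
    n_post = rng.binomial(n_pre, np.asarray(cfg.depletion_factor))

    boost = np.exp(cfg.marker_log_effect)
    a = cfg.mito_fraction_mean * cfg.mito_concentration
    b = (1 - cfg.mito_fraction_mean) * cfg.mito_concentration

    blocks, obs_rows = [], []
    cell_counter = 0
    for k, cluster in enumerate(cfg.cluster_names):
        marker_idx = np.array([gene_index[g] for g in markers[cluster]], int)
        for condition, n_cells in (("pre", int(n_pre[k])), ("post", int(n_post[k]))):
            if n_cells == 0:
                continue
            mean_k = base_mean.copy()
            mean_k[marker_idx] *= boost
            counts = _nb_counts(rng, mean_k, cfg.nb_dispersion, n_cells)

            # cycling cells: redraw their phase-program genes at boosted mean
            cycling = rng.random(n_cells) < cfg.cycling_fraction[k]
            phase = np.where(rng.random(n_cells) < 0.5, "S", "G2M").astype(object)
            phase[~cycling] = "none"
            for label, idx in (("S", s_idx), ("G2M", g2m_idx)):
                rows = np.flatnonzero(phase == label)
                if rows.size and idx.size:
                    counts[np.ix_(rows, idx)] = _nb_counts(
                        rng, base_mean[idx] * boost, cfg.nb_dispersion, rows.size
                    )

            # planted ligand/receptor rate boosts
            for edge, post_only in (
                *[(e, False) for e in cfg.planted_lr_edges],
                *[(e, True) for e in cfg.planted_condition_lr_edges],
            ):
                if post_only and condition != "post":
                    continue
                for role_cluster, gene in (
                    (edge.sender, edge.ligand), (edge.receiver, edge.receptor)
                ):
                    if role_cluster != cluster:
                        continue
                    hit = rng.random(n_cells) < edge.rate_boost
                    n_hit = int(hit.sum())
                    if n_hit:
                        counts[hit, gene_index[gene]] += (
                            1 + rng.poisson(cfg.lr_boost_mean, n_hit)
                        )

            # mitochondrial content: per-cell Beta fraction of the library
            totals = counts.sum(axis=1)
            frac = rng.beta(a, b, n_cells) if a > 0 else np.zeros(n_cells)
            lam_mito = totals * frac / np.maximum(1 - frac, 1e-9) / n_mito
            mito = rng.poisson(np.repeat(lam_mito[:, None], n_mito, axis=1))

            strain = rng.choice(STRAINS, n_cells)
            for i in range(n_cells):
                obs_rows.append(
                    (f"cell{cell_counter:07d}",
                     f"{_STRAIN_SHORT[strain[i]]}_{condition}",
                     condition, strain[i], cluster, phase[i])
                )
                cell_counter += 1
            blocks.append(sp.csr_matrix(np.hstack([counts, mito])))

    if not blocks:
        raise ConfigurationError("configuration produced zero cells")
    X = sp.vstack(blocks, format="csr").astype(np.int64)
    obs = pd.DataFrame(
        obs_rows,
        columns=["barcode", "sample", "condition", "strain",
                 "true_cluster", "true_phase"],
    ).set_index("barcode")
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=gene_names))
    adata.uns["layer"] = "raw"

    truth = GroundTruth(
        depletion={c: float(cfg.depletion_factor[k])
                   for k, c in enumerate(cfg.cluster_names)},
        markers=markers,
        s_genes=s_genes,
        g2m_genes=g2m_genes,
        cells=obs.copy(),
        planted_lr_edges=list(cfg.planted_lr_edges),
        planted_condition_lr_edges=list(cfg.planted_condition_lr_edges),
        free_genes=cfg.free_genes(),
    )
    return SyntheticDataset(adata=adata, truth=truth)


# --------------------------------------------------------------------------
# planted-edge planning helpers (deterministic, used by tests and the CLI)
# --------------------------------------------------------------------------

def plan_lr_edges(
    config: SimConfig,
    n_edges: int,
    rate_boost: float,
    *,
    gene_offset: int = 0,
) -> list[LREdgeSpec]:
    """Lay out ``n_edges`` planted edges on distinct free genes.

    Sender/receiver clusters rotate deterministically; gene pairs are taken
    sequentially from the free-gene pool starting at ``gene_offset``.
    """
    free = config.free_genes()
    need = 2 * (gene_offset + n_edges)
    if need > len(free):
        raise ConfigurationError(
            f"need {need} free genes for planted edges, have {len(free)}"
        )
    clusters = config.cluster_names
    edges = []
    for i in range(n_edges):
        sender = clusters[i % len(clusters)]
        receiver = clusters[(i * 3 + 1) % len(clusters)]
        lig = free[2 * (gene_offset + i)]
        rec = free[2 * (gene_offset + i) + 1]
        edges.append(LREdgeSpec(sender, receiver, lig, rec, rate_boost))
    return edges


def decoy_lr_pairs(
    config: SimConfig, n_pairs: int, *, gene_offset: int = 0
) -> pd.DataFrame:
    """Ligand-receptor pairs over free genes with no planted effect."""
    free = config.free_genes()
    need = 2 * (gene_offset + n_pairs)
    if need > len(free):
        raise ConfigurationError(
            f"need {need} free genes for decoy pairs, have {len(free)}"
        )
    rows = [
        (free[2 * (gene_offset + i)], free[2 * (gene_offset + i) + 1])
        for i in range(n_pairs)
    ]
    return pd.DataFrame(rows, columns=["ligand", "receptor"])


def build_lr_table(
    planted: Sequence[LREdgeSpec], decoys: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Combine planted edges and decoy pairs into one L-R database table."""
    rows = [(e.ligand, e.receptor) for e in planted]
    df = pd.DataFrame(rows, columns=["ligand", "receptor"])
    if decoys is not None:
        df = pd.concat([df, decoys[["ligand", "receptor"]]], ignore_index=True)
    return df.drop_duplicates(ignore_index=True)


# --------------------------------------------------------------------------
# 10x-style triplet output
# --------------------------------------------------------------------------

def write_10x_triplet(dataset: SyntheticDataset | AnnData, directory) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv / metadata.tsv.

    The Matrix Market file is genes x cells with integer values; reading it
    back with :func:`rili_scomm.qc.read_10x_triplet` reproduces the matrix
    entry for entry.
    """
    adata = dataset.adata if isinstance(dataset, SyntheticDataset) else dataset
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ConfigurationError("refusing to write an empty dataset")
    if adata.obs_names.duplicated().any():
        raise ConfigurationError("barcodes must be unique")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    if not np.issubdtype(X.dtype, np.integer):
        if np.any(X.data != np.round(X.data)):
            raise ConfigurationError("raw counts must be integer-valued")
        X = X.astype(np.int64)
    scipy.io.mmwrite(os.fspath(directory / "matrix.mtx"), X, field="integer")
    with open(directory / "features.tsv", "w") as fh:
        fh.write("\n".join(adata.var_names) + "\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    meta = adata.obs.reset_index(names="barcode")
    meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)
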