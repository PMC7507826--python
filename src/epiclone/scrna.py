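"""Single-cell RNA-seq selections and statistics on raw UMI counts.

Implements the drug-inducibility filter (a gene counts as inducible when
no mock-treated cell has more than 2 UMIs of it), ranking of the most
upregulated inducible genes by mean UMI in treated cells, per-gene
upregulated-cell fractions at a UMI threshold, a seeded 2-D embedding of
cells, and hierarchical clustering of cells over the top genes. No
normalisation or log transform is applied anywhere: selections and
distances operate on raw deduplicated counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .simulate import InputError
from .tree import Dendrogram, hierarchical_cluster

logger = logging.getLogger(__name__)

UMI_INDUCIBLE_MAX = 2
UMI_UPREG_MIN = 3
TOP_K = 200


@dataclass
class UMICountMatrix:
    """Integer UMI counts, genes × cells, with a condition label per cell."""

    counts: pd.DataFrame
    condition: pd.Series  # per-cell: "mock" | "treated"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise InputError("gene symbols must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("UMI counts must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.columns)

    def zero_total_cells(self) -> list[str]:
        """Barcodes with zero total counts (retained, but worth flagging)."""
        totals = self.counts.sum(axis=0)
        return list(totals.index[totals == 0])


def select_inducible_genes(mock: UMICountMatrix, inducible_max: int = UMI_INDUCIBLE_MAX) -> list[str]:
    """Genes whose count never exceeds ``inducible_max`` in any mock cell.

    These are the genes a demethylating drug can induce from silence;
    anything already expressed in untreated cells is excluded.
    """
    if mock.counts.shape[1] < 1:
        raise InputError("mock matrix has no cells")
    keep = mock.counts.max(axis=1) <= inducible_max
    return sorted(mock.counts.index[keep])


def top_upregulated(treated: UMICountMatrix, inducible: list[str], k: int = TOP_K) -> list[str]:
    """The k inducible genes with highest mean UMI count in treated cells.

    Ties in mean are broken lexicographically by gene symbol.
    """
    if k > len(inducible):
        raise InputError(f"k={k} exceeds inducible set size {len(inducible)}")
    means = treated.counts.loc[sorted(inducible)].mean(axis=1)
    ranked = means.sort_values(ascending=False, kind="stable")  # index pre-sorted → lexicographic ties
    return list(ranked.index[:k])


def upregulated_cell_fraction(
    matrix: UMICountMatrix, gene: str, threshold: int = UMI_UPREG_MIN
) -> tuple[float, list[str]]:
    """Fraction of cells expressing ``gene`` at ≥ ``threshold`` UMIs.

    Returns the fraction and the qualifying cell barcodes.
    """
    if gene not in matrix.counts.index:
        raise InputError(f"unknown gene {gene!r}")
    row = matrix.counts.loc[gene]
    hits = row.index[row >= threshold]
    return len(hits) / matrix.counts.shape[1], list(hits)


def gene_panel_report(
    treated: UMICountMatrix, inducible: list[str], threshold: int = UMI_UPREG_MIN
) -> pd.DataFrame:
    """Per-gene mean UMI, upregulated-cell fraction and inducible flag."""
    inducible_set = set(inducible)
    means = treated.counts.mean(axis=1)
    fractions = (treated.counts >= threshold).mean(axis=1)
    return pd.DataFrame(
        {
            "mean_umi_treated": means,
            "upregulated_fraction": fractions,
            "inducible": [g in inducible_set for g in treated.counts.index],
        }
    )


def detected_genes_per_cell(matrix: UMICountMatrix, min_count: int = 1) -> pd.Series:
    """Genes detected per cell under an explicit count-threshold rule."""
    return (matrix.counts >= min_count).sum(axis=0)


def combine(mock: UMICountMatrix, treated: UMICountMatrix) -> UMICountMatrix:
    """Join mock and treated matrices on the union of genes (absent → 0)."""
    genes = sorted(set(mock.genes) | set(treated.genes))
    m = mock.counts.reindex(genes, fill_value=0)
    t = treated.counts.reindex(genes, fill_value=0)
    t = t.rename(columns={c: f"{c}-t" for c in t.columns if c in set(m.columns)})
    counts = pd.concat([m, t], axis=1)
    condition = pd.concat(
        [
            pd.Series("mock", index=m.columns),
            pd.Series("treated", index=t.columns),
        ]
    )
    return UMICountMatrix(counts=counts, condition=condition)


def embed_cells(
    matrix: UMICountMatrix,
    genes: list[str] | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """Seeded 2-D UMAP embedding of cells over the given gene panel.

    The contract is reproducibility under a fixed seed and preservation of
    biological separation (see :func:`embedding_purity`); coordinates
    themselves carry no meaning. A constant input matrix is flagged via a
    log warning, not an error.
    """
    import umap  # deferred: heavy import

    sub = matrix.counts if genes is None else matrix.counts.loc[genes]
    n_cells = sub.shape[1]
    if n_cells < 10:
        raise InputError(f"need ≥ 10 cells to embed, got {n_cells}")
    data = sub.to_numpy(dtype=float).T
    if np.all(data == data[0]):
        logger.warning("constant expression matrix: embedding is degenerate")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n_cells - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(data)
    return pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "condition": matrix.condition.reindex(sub.columns).to_numpy(),
        },
        index=sub.columns,
    )


def embedding_purity(embedding: pd.DataFrame, n_clusters: int = 2, seed: int = 0) -> float:
    """Cluster-purity of condition labels over a k-means split of the embedding.

    Purity is the weighted fraction of each cluster belonging to its
    majority condition; 1.0 means the embedding separates conditions
    perfectly, 0.5 (two balanced conditions) means no separation.
    """
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assign = km.fit_predict(embedding[["x", "y"]].to_numpy())
    labels = embedding["condition"].to_numpy()
    correct = 0
    for c in range(n_clusters):
        members = labels[assign == c]
        if members.size:
            correct += pd.Series(members).value_counts().iloc[0]
    return correct / len(labels)


def cluster_cells(matrix: UMICountMatrix, genes: list[str]) -> Dendrogram:
    """Hierarchically cluster cells over the given genes (raw counts,
    Euclidean distance, complete linkage, deterministic tie-breaking)."""
    return hierarchical_cluster(matrix.counts.loc[genes].T.astype(float))


# ---------------------------------------------------------------------------
# MTX triplet I/O (MatrixMarket integer coordinate + gene TSV + barcode TSV)

def read_mtx(matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path,
             condition: str = "treated") -> UMICountMatrix:
    mat = mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.int64)
    if dense.shape != (len(genes), len(barcodes)):
        raise InputError(
            f"matrix shape {dense.shape} does not match {len(genes)} genes × {len(barcodes)} barcodes"
        )
    counts = pd.DataFrame(dense, index=genes, columns=barcodes)
    return UMICountMatrix(counts=counts, condition=pd.Series(condition, index=barcodes))


def write_mtx(matrix: UMICountMatrix, matrix_path: str | Path, genes_path: str | Path,
              barcodes_path: str | Path) -> None:
    coo = sparse.coo_matrix(matrix.counts.to_numpy(dtype=np.int64))
    mmwrite(str(matrix_path), coo, field="integer")
    pd.Series(matrix.genes).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(matrix.barcodes).to_csv(barcodes_path, sep="\t", header=False, index=False)
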