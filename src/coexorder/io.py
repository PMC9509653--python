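"""Reading and writing expression matrices, trait tables, gene lists;
sample-outlier detection; Cytoscape network export.

File conventions: expression/trait tables are UTF-8 TSV or CSV with a header
row and the identifiers in the first column; gene lists are plain text, one
identifier per line; Cytoscape edge/node attribute files are tab-delimited.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .datamodel import ExpressionMatrix, GeneSet, KeyGeneList, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_trait_table",
    "write_trait_table",
    "align_samples",
    "detect_sample_outliers",
    "export_cytoscape",
    "write_gene_list",
    "read_gene_list",
    "read_key_genes",
]


def read_expression_matrix(
    path,
    orientation: str = "genes_in_rows",
    delimiter: str | None = None,
    drop_missing_genes: bool = False,
) -> ExpressionMatrix:
    """Load an expression matrix from a delimited text file.

    Parameters
    ----------
    orientation:
        ``genes_in_rows`` (GEO series-matrix convention) or
        ``samples_in_rows``; the returned matrix is always genes x samples.
    delimiter:
        Field delimiter; inferred from the file extension when omitted
        (``.csv`` -> comma, otherwise tab).
    drop_missing_genes:
        If True, genes (rows after orientation) containing missing values are
        dropped with a logged warning instead of raising.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_in_rows":
        df = df.T
    for axis, what in ((df.index, "gene"), (df.columns, "sample")):
        counts = axis.value_counts()
        dups = counts[counts > 1].index.tolist()
        if dups:
            raise ValueError(f"duplicate {what} identifiers in {path}: {sorted(dups)}")
    non_numeric = df.apply(
        lambda col: pd.to_numeric(col, errors="coerce"), axis=0
    )
    introduced = non_numeric.isna() & df.notna()
    if introduced.to_numpy().any():
        r, c = np.argwhere(introduced.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    df = non_numeric
    if df.isna().to_numpy().any():
        if not drop_missing_genes:
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}; "
                "pass drop_missing_genes=True to drop such genes"
            )
        bad = df.index[df.isna().any(axis=1)]
        logger.warning("dropping %d genes with missing values", len(bad))
        df = df.drop(index=bad)
    return ExpressionMatrix(df)


def write_expression_matrix(em: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    em.data.to_csv(path, sep=delimiter)


def read_trait_table(path, delimiter: str | None = None) -> TraitTable:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df)


def write_trait_table(tt: TraitTable, path, delimiter: str | None = None) -> None:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    tt.data.to_csv(path, sep=delimiter)


def align_samples(em: ExpressionMatrix, tt: TraitTable) -> tuple[ExpressionMatrix, TraitTable]:
    """Restrict matrix and trait table to their shared samples, same order.

    The order of the expression matrix is kept for the shared samples;
    dropped samples are logged.
    """
    shared = [s for s in em.sample_ids if s in set(tt.sample_ids)]
    if not shared:
        raise ValueError("expression matrix and trait table share no samples")
    dropped = sorted((set(em.sample_ids) | set(tt.sample_ids)) - set(shared))
    if dropped:
        logger.warning("dropping samples absent from one table: %s", dropped)
    return em.subset_samples(shared), tt.subset_samples(shared)


def detect_sample_outliers(
    em: ExpressionMatrix, height_cutoff: float
) -> tuple[list[str], np.ndarray]:
    """Flag outlying samples from an average-linkage Euclidean dendrogram.

    Samples are clustered on the Euclidean distance between their expression
    profiles. Cutting the tree at ``height_cutoff`` yields branches; any
    branch that separates above the cutoff and contains fewer than half of
    the samples is flagged as outlying. The cutoff is dataset-specific and
    must always be supplied.

    Returns the flagged sample ids and the merge heights of the dendrogram.
    """
    if height_cutoff <= 0:
        raise ValueError("height_cutoff must be positive")
    if em.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    X = em.values.T  # samples x genes
    Z = linkage(X, method="average", metric="euclidean")
    heights = Z[:, 2].copy()
    labels = fcluster(Z, t=height_cutoff, criterion="distance")
    n = em.n_samples
    outliers: list[str] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) < n / 2 and len(np.unique(labels)) > 1:
            outliers.extend(em.sample_ids[i] for i in members)
    if len(outliers) == n:  # everything flagged means nothing separates
        outliers = []
    return sorted(outliers), heights


def export_cytoscape(
    weights: pd.DataFrame,
    threshold: float,
    edge_path,
    node_path,
    attributes: Mapping[str, Mapping[str, str]] | pd.DataFrame | None = None,
) -> tuple[int, int]:
    """Write tab-delimited Cytoscape edge and node attribute files.

    ``weights`` is a symmetric gene x gene weight matrix (adjacency or
    topological overlap) restricted to the genes of interest. One edge row is
    emitted per unordered pair with weight strictly above ``threshold``;
    direction is always ``undirected`` (unsigned symmetric networks).
    ``attributes`` maps attribute name -> {gene: value} (or a DataFrame with
    genes as index) and is written into the node file.

    Returns (number of edge rows, number of node rows).
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    genes = list(weights.index)
    if list(weights.columns) != genes:
        raise ValueError("weight matrix must be square with matching ids")
    W = weights.to_numpy(dtype=float)
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("weight matrix must be symmetric")
    if W.min() < 0 or W.max() > 1 + 1e-12:
        raise ValueError("weights must lie in [0, 1]")
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = W[iu, ju] > threshold
    edges = pd.DataFrame(
        {
            "fromNode": [genes[i] for i in iu[keep]],
            "toNode": [genes[j] for j in ju[keep]],
            "weight": W[iu[keep], ju[keep]],
            "direction": "undirected",
        }
    )
    edges.to_csv(edge_path, sep="\t", index=False)

    nodes = pd.DataFrame(index=pd.Index(genes, name="nodeName"))
    if attributes is not None:
        attr_df = (
            attributes
            if isinstance(attributes, pd.DataFrame)
            else pd.DataFrame(attributes)
        )
        nodes = nodes.join(attr_df, how="left")
    nodes.reset_index().to_csv(node_path, sep="\t", index=False)
    return len(edges), len(nodes)


def write_gene_list(gs: GeneSet | Iterable[str], path) -> None:
    """Write one gene identifier per line (sorted for a plain GeneSet)."""
    genes = sorted(gs.genes) if isinstance(gs, GeneSet) else list(gs)
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list; blank lines are skipped with a log note."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    genes = [ln.strip() for ln in lines if ln.strip()]
    if len(genes) < len(lines):
        logger.info("skipped %d blank lines in %s", len(lines) - len(genes), path)
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return GeneSet(name or Path(path).stem, genes)


def read_key_genes(path, source: str = "") -> KeyGeneList:
    """Read a curated key-gene list (one id per line, order preserved)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    genes = [ln.strip() for ln in lines if ln.strip()]
    if not genes:
        raise ValueError(f"key gene list {path} is empty")
    return KeyGeneList(tuple(genes), source=source or str(path))
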