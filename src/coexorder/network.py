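"""Unsigned weighted co-expression networks: correlation, soft-thresholded
adjacency, connectivity, scale-free topology diagnostics, and topological
overlap.

The network is unsigned: the co-expression similarity between genes m and n
is |cor_mn| (Pearson), and the adjacency is a_mn = |cor_mn|^beta for an
integer soft-threshold power beta. No distinction is made between positively
and negatively correlated gene pairs, so both co-activation and mutual
inhibition contribute connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

__all__ = [
    "ScaleFreeFit",
    "pearson_correlation",
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "soft_threshold_scan",
    "pick_soft_threshold",
    "tom",
]


@dataclass(frozen=True)
class ScaleFreeFit:
    """Scale-free topology diagnostics at one soft-threshold power.

    ``signed_r2`` is -sign(slope) * R^2 of the regression of log10 p(k) on
    log10 k over the connectivity bins: positive only when frequency decays
    with connectivity, as a scale-free network requires.
    """

    beta: int | None
    signed_r2: float
    slope: float
    slope_r2: float
    mean_k: float
    median_k: float
    max_k: float


def pearson_correlation(em: ExpressionMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlation across samples.

    Zero-variance genes are dropped with a warning before computing.
    """
    if em.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    em, dropped = em.drop_zero_variance_genes()
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "dropped %d zero-variance genes before correlation", len(dropped)
        )
    C = np.corrcoef(em.values)
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=em.gene_ids, columns=em.gene_ids)


def adjacency(cor: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta; the diagonal is stored as 1 but is
    never counted in connectivity sums."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = np.abs(cor.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Per-gene connectivity k_i = sum_{j != i} a_ij."""
    A = adj.to_numpy(dtype=float)
    k = A.sum(axis=1) - np.diag(A)
    return pd.Series(k, index=adj.index, name="k")


def scale_free_fit(k, n_bins: int = 10, beta: int | None = None) -> ScaleFreeFit:
    """Log-log regression diagnostic of scale-free topology.

    Connectivities (k > 0 only) are split into ``n_bins`` equal-width bins;
    for each non-empty bin the mean connectivity and the fraction of genes
    p(k) are computed, and log10 p(k) is regressed on log10 mean-k by
    ordinary least squares. The signed fit index is -sign(slope) * R^2.
    """
    karr = np.asarray(k, dtype=float)
    karr = karr[karr > 0]
    if karr.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes with k > 0")
    mean_k = float(karr.mean())
    median_k = float(np.median(karr))
    max_k = float(karr.max())
    if karr.min() == karr.max():
        raise ValueError("constant connectivity: degenerate single bin")
    edges = np.linspace(karr.min(), karr.max(), n_bins + 1)
    idx = np.clip(np.digitize(karr, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        frac = mask.mean()
        if frac <= 0:
            continue
        xs.append(np.log10(karr[mask].mean()))
        ys.append(np.log10(frac))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} usable bins; need >= 3")
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    signed = float(-np.sign(slope) * r2)
    return ScaleFreeFit(beta, signed, float(slope), float(r2), mean_k, median_k, max_k)


def soft_threshold_scan(
    em: ExpressionMatrix,
    betas: Iterable[int] = range(1, 21),
    n_bins: int = 10,
    cor: pd.DataFrame | None = None,
) -> list[ScaleFreeFit]:
    """Scale-free diagnostics across candidate soft-threshold powers.

    The correlation matrix is computed once and powered per beta (pass a
    precomputed ``cor`` to reuse it). Returns one :class:`ScaleFreeFit` per
    requested beta.
    """
    if cor is None:
        cor = pearson_correlation(em)
    absC = np.abs(cor.to_numpy(dtype=float))
    np.fill_diagonal(absC, 0.0)  # exclude self from connectivity
    fits = []
    for beta in betas:
        if beta < 1:
            raise ValueError("beta must be >= 1")
        k = (absC**beta).sum(axis=1)
        fits.append(scale_free_fit(k, n_bins=n_bins, beta=int(beta)))
    return fits


@dataclass(frozen=True)
class ThresholdChoice:
    beta: int
    fit: ScaleFreeFit
    rule: str


def pick_soft_threshold(scan: Sequence[ScaleFreeFit], r2_cut: float = 0.8) -> ThresholdChoice:
    """Choose the soft-threshold power from a scan.

    In order of importance: the smallest beta whose signed R^2 reaches
    ``r2_cut``; otherwise the beta maximizing signed R^2 (ties broken toward
    the smaller beta, which preserves higher mean connectivity). The returned
    record states which rule fired.
    """
    if not scan:
        raise ValueError("empty scan")
    fits = sorted(scan, key=lambda f: f.beta)
    for f in fits:
        if f.signed_r2 >= r2_cut:
            return ThresholdChoice(f.beta, f, f"first beta with signed R^2 >= {r2_cut}")
    best = max(fits, key=lambda f: (f.signed_r2, -f.beta))
    return ThresholdChoice(
        best.beta, best, f"no beta reached signed R^2 >= {r2_cut}; maximum signed R^2"
    )


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu * a_uj; the diagonal is 1. Values lie in
    [0, 1] and combine direct adjacency with shared-neighbor strength.
    """
    A = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # with zero diagonal, u = i and u = j terms vanish
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A) / denom
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    T = (T + T.T) / 2.0  # enforce exact symmetry against FP noise
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)
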