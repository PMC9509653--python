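"""Module detection: hierarchical clustering of topological-overlap
dissimilarity, minimum-size tree cutting, module eigengenes, and merging of
modules with similar eigengenes.

Modules are labeled with the conventional color vocabulary (turquoise, blue,
brown, ... by decreasing size); genes not assigned to any module carry the
``grey`` label. The :class:`WGCNA` estimator bundles the full network ->
modules pipeline in scikit-learn style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .datamodel import ExpressionMatrix
from . import network as net

logger = logging.getLogger(__name__)

__all__ = [
    "MODULE_COLORS",
    "GREY",
    "ModulePartition",
    "EigengeneMatrix",
    "cluster_genes",
    "cut_tree_min_size",
    "refine_modules_by_membership",
    "module_eigengenes",
    "merge_close_modules",
    "WGCNA",
]

#: ordered color vocabulary consumed by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
)
GREY = "grey"


class ModulePartition:
    """Assignment of every gene to exactly one module color (or grey)."""

    def __init__(self, labels: pd.Series, min_size: int | None = None):
        self.labels = labels.astype(str)
        self.labels.name = "module"
        self.min_size = min_size

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def modules(self) -> list[str]:
        """Non-grey module colors, largest first."""
        sizes = self.sizes()
        return [c for c in sizes.index if c != GREY]

    def sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        grey = counts.pop(GREY) if GREY in counts.index else 0
        counts = counts.sort_values(ascending=False, kind="stable")
        if grey:
            counts[GREY] = grey
        return counts

    def genes_in(self, color: str) -> list[str]:
        return list(self.labels.index[self.labels == color])

    def __len__(self) -> int:
        return len(self.modules)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ModulePartition({len(self)} modules, {len(self.labels)} genes)"


@dataclass(frozen=True)
class EigengeneMatrix:
    """Per-module eigengene profiles (modules x samples), unit variance,
    sign-aligned with the module mean expression; plus variance explained."""

    profiles: pd.DataFrame
    variance_explained: pd.Series

    @property
    def modules(self) -> list[str]:
        return list(self.profiles.index)


def _assign_colors(labels: pd.Series, min_size: int | None = None) -> pd.Series:
    """Map arbitrary non-grey cluster ids to the ordered color list by
    decreasing size (ties broken by first appearance)."""
    non_grey = labels[labels != GREY]
    order: dict = {}
    for lab in non_grey:
        order.setdefault(lab, len(order))
    counts = non_grey.value_counts()
    ranked = sorted(counts.index, key=lambda c: (-counts[c], order[c]))
    mapping = {
        lab: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"M{i + 1}")
        for i, lab in enumerate(ranked)
    }
    mapping[GREY] = GREY
    return labels.map(mapping)


def cluster_genes(diss: pd.DataFrame):
    """Average-linkage (UPGMA) tree of a gene dissimilarity matrix
    (typically 1 - TOM). Returns a scipy linkage matrix."""
    D = diss.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("dissimilarity diagonal must be zero")
    condensed = squareform(D, checks=False)
    return linkage(condensed, method="average")


def cut_tree_min_size(
    Z, diss: pd.DataFrame, min_size: int = 30, top_exclusion: float = 0.005
) -> ModulePartition:
    """Adaptive fixed-height cut with a minimum module size.

    Every distinct merge height is a candidate cut; at each cut, branches
    with at least ``min_size`` genes become modules and the rest is grey.
    The cut maximizing the number of qualifying modules wins (ties: the
    lower height). Candidate heights within ``top_exclusion`` of the root
    are excluded: in that terminal agglomeration band unrelated genes chain
    into spuriously large clusters, so cuts there detect noise, not modules.
    The result is a set of module CORES; in the full pipeline a membership
    refinement step (:func:`refine_modules_by_membership`) completes them.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    gene_ids = list(diss.index)
    heights = np.unique(Z[:, 2])
    cap = (1.0 - top_exclusion) * heights.max()
    candidates = heights[heights <= cap]
    if candidates.size == 0:
        candidates = heights[:1]
    best_labels = None
    best_count = 0
    for h in candidates:
        labels = fcluster(Z, t=h, criterion="distance")
        counts = np.bincount(labels)
        qualifying = int((counts[1:] >= min_size).sum())
        if qualifying > best_count:
            best_count = qualifying
            best_labels = labels
    out = pd.Series(GREY, index=pd.Index(gene_ids, name="gene"))
    if best_labels is not None:
        counts = np.bincount(best_labels)
        for lab in np.flatnonzero(counts >= min_size):
            if lab == 0:
                continue
            out.iloc[np.flatnonzero(best_labels == lab)] = f"c{lab}"
    return ModulePartition(_assign_colors(out), min_size=min_size)


def refine_modules_by_membership(
    em: ExpressionMatrix,
    part: ModulePartition,
    kme_min: float = 0.7,
    min_size: int | None = None,
    max_iter: int = 5,
) -> ModulePartition:
    """Iterative module-membership refinement.

    Each iteration recomputes module eigengenes, assigns every gene to the
    module whose eigengene it correlates with most strongly (|kME|), greys
    genes whose best |kME| falls below ``kme_min``, and dissolves modules
    that drop under the minimum size. Converges in a few iterations; the
    fixed point has modules that are both complete (high-membership genes
    recovered from grey) and pure (weak and spurious members removed).
    """
    if not (0 < kme_min < 1):
        raise ValueError("kme_min must lie in (0, 1)")
    min_size = min_size if min_size is not None else (part.min_size or 2)
    labels = part.labels.copy()
    X = em.values
    Xc = X - X.mean(axis=1, keepdims=True)
    Xnorm = np.sqrt((Xc**2).sum(axis=1))
    Xnorm[Xnorm == 0] = 1.0
    for _ in range(max_iter):
        current = ModulePartition(labels, min_size)
        if not current.modules:
            return current
        megs = module_eigengenes(em, current)
        kme = {}
        for color in megs.modules:
            me = megs.profiles.loc[color].to_numpy()
            mec = me - me.mean()
            kme[color] = (Xc @ mec) / (Xnorm * np.sqrt((mec**2).sum()))
        kdf = pd.DataFrame(kme, index=em.gene_ids).abs()
        best = kdf.idxmax(axis=1)
        bestv = kdf.max(axis=1)
        new = pd.Series(GREY, index=labels.index, name="module")
        strong = bestv >= kme_min
        new[strong] = best[strong]
        sizes = new.value_counts()
        for color in sizes.index:
            if color != GREY and sizes[color] < min_size:
                new[new == color] = GREY
        if new.equals(labels):
            break
        labels = new
    return ModulePartition(_assign_colors(labels), min_size)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengenes(em: ExpressionMatrix, part: ModulePartition) -> EigengeneMatrix:
    """First-principal-component summary profile of each module.

    Genes are standardized across samples; the eigengene is the leading
    right singular vector of the module's gene x sample block, sign-aligned
    so it correlates non-negatively with the module mean profile (falling
    back to the first gene when the mean is degenerate), and scaled to unit
    variance. The fraction of variance explained is reported per module.
    """
    profiles = {}
    varexp = {}
    for color in part.modules:
        genes = part.genes_in(color)
        if len(genes) < 2:
            raise ValueError(f"module {color!r} has fewer than 2 genes")
        X = _standardize(em.subset_genes(genes).values)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        me = Vt[0]
        varexp[color] = float(S[0] ** 2 / (S**2).sum())
        ref = X.mean(axis=0)
        c = np.dot(me, ref)
        if abs(c) < 1e-10:
            c = np.dot(me, X[0])
        if c < 0:
            me = -me
        sd = me.std(ddof=1)
        if sd > 0:
            me = me / sd
        profiles[color] = me
    prof = pd.DataFrame(profiles, index=em.sample_ids).T
    prof.index.name = "module"
    return EigengeneMatrix(prof, pd.Series(varexp, name="variance_explained"))


def merge_close_modules(
    em: ExpressionMatrix,
    part: ModulePartition,
    megs: EigengeneMatrix | None = None,
    cut: float = 0.25,
) -> tuple[ModulePartition, EigengeneMatrix]:
    """Iteratively merge modules whose eigengenes are highly correlated.

    Modules are clustered (average linkage) under the signed eigengene
    dissimilarity 1 - cor(ME_a, ME_b); clusters joined below ``cut`` are
    merged (i.e. eigengene correlation > 1 - cut), eigengenes are recomputed,
    and the process repeats until stable. Only positively correlated modules
    can merge. Colors are reassigned by the new sizes.
    """
    if not (0 < cut < 1):
        raise ValueError("cut must lie in (0, 1)")
    labels = part.labels.copy()
    if megs is None:
        megs = module_eigengenes(em, ModulePartition(labels, part.min_size))
    while True:
        mods = ModulePartition(labels, part.min_size).modules
        if len(mods) < 2:
            break
        ME = megs.profiles.loc[mods]
        corr = np.corrcoef(ME.to_numpy())
        D = 1.0 - corr
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        Z = linkage(squareform(D, checks=False), method="average")
        groups = fcluster(Z, t=np.nextafter(cut, 0.0), criterion="distance")
        if len(np.unique(groups)) == len(mods):
            break
        remap = {}
        for grp in np.unique(groups):
            members = [mods[i] for i in np.flatnonzero(groups == grp)]
            target = members[0]  # largest, since mods is size-ordered
            for m in members:
                remap[m] = target
        labels = labels.map(lambda c: remap.get(c, c))
        megs = module_eigengenes(em, ModulePartition(labels, part.min_size))
    merged = ModulePartition(_assign_colors(labels), part.min_size)
    megs = module_eigengenes(em, merged)
    return merged, megs


class WGCNA(ClusterMixin, BaseEstimator):
    """Weighted gene co-expression network analysis as a gene-clustering
    estimator.

    ``fit(X)`` takes a genes x samples matrix (rows are the items being
    clustered). The pipeline: Pearson correlation -> soft-threshold scan and
    selection -> unsigned adjacency -> topological overlap -> average-linkage
    clustering -> minimum-size tree cut -> membership refinement ->
    eigengene merge.

    Parameters
    ----------
    beta : int or "auto"
        Soft-threshold power; "auto" scans ``betas`` and applies the
        signed-R^2 selection rule.
    betas : iterable of int
        Candidate powers for the scan (default 1..20).
    r2_cut : float
        Signed R^2 target for power selection.
    min_module_size : int
        Smallest allowed module (default 30).
    merge_cut : float
        Eigengene dissimilarity below which modules merge (default 0.25).

    Attributes
    ----------
    labels_ : ndarray of module color labels per gene ("grey" = unassigned)
    partition_ : :class:`ModulePartition`
    eigengenes_ : :class:`EigengeneMatrix`
    beta_ : selected power;  scan_ : list of :class:`ScaleFreeFit`
    fit_ : :class:`ScaleFreeFit` at the selected power
    tom_ : topological overlap DataFrame;  adjacency_ : adjacency DataFrame
    """

    def __init__(
        self,
        beta="auto",
        betas=tuple(range(1, 21)),
        r2_cut: float = 0.8,
        min_module_size: int = 30,
        merge_cut: float = 0.25,
        refine_kme: float = 0.7,
        n_bins: int = 10,
    ):
        self.beta = beta
        self.betas = betas
        self.r2_cut = r2_cut
        self.min_module_size = min_module_size
        self.merge_cut = merge_cut
        self.refine_kme = refine_kme
        self.n_bins = n_bins

    def fit(self, X, y=None):
        em = self._as_matrix(X)
        cor = net.pearson_correlation(em)
        em = em.subset_genes(list(cor.index))  # zero-variance genes dropped
        self.scan_ = net.soft_threshold_scan(
            em, betas=self.betas, n_bins=self.n_bins, cor=cor
        )
        if self.beta == "auto":
            choice = net.pick_soft_threshold(self.scan_, r2_cut=self.r2_cut)
            self.beta_ = choice.beta
            self.fit_ = choice.fit
            self.selection_rule_ = choice.rule
        else:
            self.beta_ = int(self.beta)
            matches = [f for f in self.scan_ if f.beta == self.beta_]
            self.fit_ = matches[0] if matches else None
            self.selection_rule_ = "user-specified beta"
        self.adjacency_ = net.adjacency(cor, self.beta_)
        self.tom_ = net.tom(self.adjacency_)
        D = 1.0 - self.tom_.to_numpy()
        np.fill_diagonal(D, 0.0)
        diss = pd.DataFrame(D, index=self.tom_.index, columns=self.tom_.columns)
        Z = cluster_genes(diss)
        self.dendrogram_ = Z
        part = cut_tree_min_size(Z, diss, min_size=self.min_module_size)
        if part.modules:
            part = refine_modules_by_membership(
                em, part, kme_min=self.refine_kme, min_size=self.min_module_size
            )
        if part.modules:
            megs = module_eigengenes(em, part)
            part, megs = merge_close_modules(em, part, megs, cut=self.merge_cut)
            self.eigengenes_ = megs
        else:
            logger.warning("no module reached min_module_size; all genes grey")
            self.eigengenes_ = EigengeneMatrix(
                pd.DataFrame(columns=em.sample_ids), pd.Series(dtype=float)
            )
        self.partition_ = part
        self.gene_ids_ = em.gene_ids
        self.labels_ = part.labels.to_numpy()
        return self

    @staticmethod
    def _as_matrix(X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(X)
        X = np.asarray(X, dtype=float)
        return ExpressionMatrix(
            pd.DataFrame(
                X,
                index=[f"g{i}" for i in range(X.shape[0])],
                columns=[f"s{i}" for i in range(X.shape[1])],
            )
        )

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
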