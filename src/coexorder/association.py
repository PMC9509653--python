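"""Module-trait association and gene-level filtering.

Selection proceeds in three steps, each with explicit thresholds collected in
:class:`ModuleSelectionCriteria`:

1. module selection: eigengene-trait Pearson correlation with |r| > r_min
   and p < p_max (correlation t-test, n - 2 df);
2. module screen: within each candidate module, gene-wise |module
   membership| (kME) must correlate positively and significantly with
   gene-wise |trait significance| (GS);
3. gene filter: |GS| > gs_min and |kME| > kme_min (strict inequalities).

GS is primarily the gene-trait correlation; its -log10 p twin (GS_logp) and
the intramodular connectivity kIM (raw and max-normalized) are computed and
reported alongside, and both filters can be switched to the alternative
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, GeneSet
from .modules import EigengeneMatrix, GREY, ModulePartition

__all__ = [
    "ModuleSelectionCriteria",
    "module_trait_correlation",
    "select_trait_modules",
    "gene_scores",
    "mm_gs_module_screen",
    "filter_module_genes",
    "intersect_with_degs",
]


@dataclass(frozen=True)
class ModuleSelectionCriteria:
    """Thresholds of the module and gene selection cascade.

    p_max defaults to 0.001; relax to 0.01 for small-sample designs.
    """

    r_min: float = 0.5
    p_max: float = 0.001
    mmgs_r_min: float = 0.5
    mmgs_p_max: float = 0.05
    gs_min: float = 0.2
    kme_min: float = 0.8
    gs_definition: str = "cor"  # or "logp"
    membership: str = "kme"  # or "kim_norm"

    def __post_init__(self):
        for name in ("r_min", "mmgs_r_min", "gs_min", "kme_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("p_max", "mmgs_p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.gs_definition not in ("cor", "logp"):
            raise ValueError("gs_definition must be 'cor' or 'logp'")
        if self.membership not in ("kme", "kim_norm"):
            raise ValueError("membership must be 'kme' or 'kim_norm'")


def _cor_test(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of Y with x, plus two-sided p from the
    correlation t-test with n - 2 df."""
    n = x.size
    xc = x - x.mean()
    xs = np.sqrt((xc**2).sum())
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ys = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / (ys * xs)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def module_trait_correlation(megs: EigengeneMatrix, trait) -> pd.DataFrame:
    """Eigengene-trait Pearson correlation and p-value per module."""
    y = np.asarray(trait, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 samples")
    if np.all(y == y[0]):
        raise ValueError("trait is constant")
    ME = megs.profiles.to_numpy(dtype=float)
    if ME.shape[1] != y.size:
        raise ValueError("trait not aligned with eigengene samples")
    r, p = _cor_test(y, ME)
    return pd.DataFrame({"r": r, "p": p}, index=megs.profiles.index)


def select_trait_modules(
    mtr: pd.DataFrame,
    criteria: ModuleSelectionCriteria = ModuleSelectionCriteria(),
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Modules with |r| > r_min and p < p_max.

    When a gene-score table is supplied, module significance (MS; mean |GS|
    of the module's genes) is attached for ranking.
    """
    sel = mtr[(mtr["r"].abs() > criteria.r_min) & (mtr["p"] < criteria.p_max)].copy()
    if scores is not None and "module" in scores.columns:
        ms = (
            scores.assign(absgs=scores["GS_cor"].abs())
            .groupby("module")["absgs"]
            .mean()
        )
        sel["MS"] = [ms.get(m, np.nan) for m in sel.index]
        sel = sel.sort_values("MS", ascending=False)
    else:
        sel = sel.reindex(sel["r"].abs().sort_values(ascending=False).index)
    return sel


def gene_scores(
    em: ExpressionMatrix,
    trait,
    megs: EigengeneMatrix,
    adj: pd.DataFrame,
    part: ModulePartition,
) -> pd.DataFrame:
    """Per-gene trait-significance and membership scores.

    Columns: module, GS_cor, GS_p, GS_logp, kME (to the gene's own module;
    NaN for grey), kME_<color> per module, kIM, kIM_norm.
    """
    y = np.asarray(trait, dtype=float)
    X = em.values
    gs_r, gs_p = _cor_test(y, X)
    out = pd.DataFrame(
        {
            "module": part.labels.reindex(em.gene_ids).to_numpy(),
            "GS_cor": gs_r,
            "GS_p": gs_p,
            "GS_logp": -np.log10(np.clip(gs_p, 1e-300, None)),
        },
        index=pd.Index(em.gene_ids, name="gene"),
    )
    # kME to every module eigengene
    for color in megs.modules:
        me = megs.profiles.loc[color].to_numpy(dtype=float)
        r, _ = _cor_test(me, X)
        out[f"kME_{color}"] = r
    own = np.full(len(out), np.nan)
    for i, (g, color) in enumerate(zip(out.index, out["module"])):
        col = f"kME_{color}"
        if col in out.columns:
            own[i] = out.at[g, col]
    out["kME"] = own

    # intramodular connectivity
    A = adj.reindex(index=em.gene_ids, columns=em.gene_ids).to_numpy(dtype=float)
    kim = np.full(len(out), np.nan)
    labels = out["module"].to_numpy()
    for color in part.modules:
        idx = np.flatnonzero(labels == color)
        if idx.size == 0:
            continue
        sub = A[np.ix_(idx, idx)]
        kim[idx] = sub.sum(axis=1) - np.diag(sub)
    out["kIM"] = kim
    out["kIM_norm"] = np.nan
    for color in part.modules:
        idx = np.flatnonzero(labels == color)
        mx = np.nanmax(kim[idx]) if idx.size else np.nan
        if mx and mx > 0:
            out.iloc[idx, out.columns.get_loc("kIM_norm")] = kim[idx] / mx
    return out


def mm_gs_module_screen(
    scores: pd.DataFrame,
    modules,
    criteria: ModuleSelectionCriteria = ModuleSelectionCriteria(),
) -> tuple[list[str], pd.DataFrame]:
    """Retain modules whose |kME| and |GS| rankings agree.

    Per candidate module (>= 10 genes), the Pearson correlation between
    gene-wise |kME| and |GS| is computed; the module is retained iff
    r >= mmgs_r_min and p < mmgs_p_max.
    """
    rows = {}
    retained = []
    for color in modules:
        sub = scores[scores["module"] == color]
        if len(sub) < 10:
            raise ValueError(f"module {color!r} has fewer than 10 genes")
        mm = sub["kME"].abs().to_numpy()
        gs = sub["GS_cor"].abs().to_numpy()
        r, p = stats.pearsonr(mm, gs)
        keep = (r >= criteria.mmgs_r_min) and (p < criteria.mmgs_p_max)
        rows[color] = {"mmgs_r": r, "mmgs_p": p, "retained": keep}
        if keep:
            retained.append(color)
    return retained, pd.DataFrame(rows).T


def filter_module_genes(
    scores: pd.DataFrame,
    retained_modules,
    criteria: ModuleSelectionCriteria = ModuleSelectionCriteria(),
    name: str = "module_genes",
) -> GeneSet:
    """Genes of retained modules passing the GS and membership filters
    (strict inequalities)."""
    gs_col = "GS_cor" if criteria.gs_definition == "cor" else "GS_logp"
    mm_col = "kME" if criteria.membership == "kme" else "kIM_norm"
    mask = (
        scores["module"].isin(list(retained_modules))
        & (scores[gs_col].abs() > criteria.gs_min)
        & (scores[mm_col].abs() > criteria.kme_min)
    )
    return GeneSet(name, set(scores.index[mask.fillna(False)]))


def intersect_with_degs(gs: GeneSet, degs: GeneSet, scores: pd.DataFrame | None = None):
    """Intersect a co-expression gene set with a DEG set.

    Returns (GeneSet, per-module counts Series or None). Logs a warning on an
    empty intersection.
    """
    inter = GeneSet(f"{gs.name}&{degs.name}", gs.genes & degs.genes)
    if not inter.genes:
        import logging

        logging.getLogger(__name__).warning(
            "intersection of %s and %s is empty", gs.name, degs.name
        )
    per_module = None
    if scores is not None:
        members = scores.loc[scores.index.isin(inter.genes), "module"]
        per_module = members.value_counts().sort_values(ascending=False)
    return inter, per_module
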