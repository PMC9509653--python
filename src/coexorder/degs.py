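"""Two-group differential expression with empirical-Bayes moderated t
statistics and Benjamini-Hochberg FDR control.

The model is the standard moderated t construction: per gene g, an ordinary
two-group contrast yields the mean difference, the pooled within-group
variance s2_g with d = n - 2 residual degrees of freedom; the gene-wise
variances are shrunk toward a prior (d0, s02) estimated by moment matching
on log s2 across genes, giving

    s2~_g = (d0 * s02 + d * s2_g) / (d0 + d)
    t~_g  = diff_g / (s~_g * sqrt(1/n1 + 1/n2)),   t~_g ~ t(d0 + d)

Setting ``prior_df=0`` disables shrinkage (ordinary pooled t, used as the
oracle route in tests); ``prior_df=inf`` shrinks fully to the prior variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .datamodel import ExpressionMatrix, GeneSet

__all__ = [
    "GeneStats",
    "EBayesParams",
    "fit_group_contrast",
    "ebayes_moderate",
    "bh_adjust",
    "call_degs",
    "deg_table",
    "stage_degs",
    "ModeratedTTest",
]


@dataclass(frozen=True)
class GeneStats:
    """Per-gene two-group contrast ingredients."""

    gene_ids: tuple
    effect: np.ndarray  # difference of group means (group1 - group0)
    s2: np.ndarray  # pooled within-group variance
    df: int  # residual degrees of freedom, n - 2
    n0: int
    n1: int


@dataclass(frozen=True)
class EBayesParams:
    """Prior degrees of freedom and prior variance of the moderated model."""

    d0: float
    s02: float


def fit_group_contrast(em: ExpressionMatrix, groups) -> GeneStats:
    """Per-gene difference of group means and pooled within-group variance.

    ``groups`` is a binary 0/1 vector aligned to the matrix samples; both
    groups need at least two samples.
    """
    g = np.asarray(groups)
    if g.shape != (em.n_samples,):
        raise ValueError("groups must align with the matrix samples")
    if not set(np.unique(g).tolist()) <= {0, 1}:
        raise ValueError("groups must be coded 0/1")
    X = em.values
    m0, m1 = X[:, g == 0], X[:, g == 1]
    n0, n1 = m0.shape[1], m1.shape[1]
    if n0 < 2 or n1 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n0} and {n1})")
    effect = m1.mean(axis=1) - m0.mean(axis=1)
    ss = ((m0 - m0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (m1 - m1.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n0 + n1 - 2
    return GeneStats(tuple(em.gene_ids), effect, ss / df, df, n0, n1)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _estimate_prior(s2: np.ndarray, df: int) -> EBayesParams:
    """Moment matching of a scaled inverse chi-square prior on log s2."""
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all gene variances are zero; prior is unidentifiable")
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) if e.size > 1 else 0.0
    evar = evar - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return EBayesParams(d0, s02)


def ebayes_moderate(
    gstats: GeneStats, prior_df: float | None = None, prior_s2: float | None = None
) -> tuple[EBayesParams, np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values.

    ``prior_df=None`` estimates (d0, s02) from the ensemble of gene variances;
    ``prior_df=0`` is the ordinary-t passthrough; ``prior_df=inf`` uses the
    prior variance alone.
    """
    s2 = np.asarray(gstats.s2, dtype=float)
    if gstats.df < 1:
        raise ValueError("need residual df >= 1")
    if prior_df is None:
        if s2.size < 2:
            raise ValueError("prior estimation needs >= 2 genes")
        params = _estimate_prior(s2, gstats.df)
    else:
        if prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if prior_df == 0:
            params = EBayesParams(0.0, 1.0)  # prior variance unused
        else:
            if prior_s2 is None:
                prior_s2 = _estimate_prior(s2, gstats.df).s02
            if prior_s2 <= 0:
                raise ValueError("prior_s2 must be positive")
            params = EBayesParams(float(prior_df), float(prior_s2))

    d0, s02 = params.d0, params.s02
    d = gstats.df
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / gstats.n0 + 1.0 / gstats.n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, gstats.effect / se, np.where(gstats.effect == 0, 0.0, np.inf))
        t = np.where((se == 0) & (gstats.effect < 0), -np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return params, t, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j: rank(j) >= rank(i)} min(1, m/rank(j) * p_(j)),
    with stable ranks for ties.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def deg_table(
    em: ExpressionMatrix, groups, alpha: float = 0.05, prior_df: float | None = None
) -> pd.DataFrame:
    """Full per-gene DE table: effect, moderated t, raw and adjusted p, flag."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    gstats = fit_group_contrast(em, groups)
    _, t, p = ebayes_moderate(gstats, prior_df=prior_df)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "effect": gstats.effect,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "de": p_adj < alpha,
        },
        index=pd.Index(gstats.gene_ids, name="gene"),
    )


def call_degs(
    table: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = True, name: str = "degs"
) -> GeneSet:
    """Genes significant at level alpha (strict inequality, adjusted p by
    default; ``use_adjusted=False`` applies the threshold to raw p)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    col = "p_adj" if use_adjusted else "p"
    return GeneSet(name, set(table.index[table[col] < alpha]))


def stage_degs(
    em: ExpressionMatrix,
    traits,
    trait: str = "sex",
    stage: str | None = None,
    stage_column: str = "stage",
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, GeneSet]:
    """DE between the two trait groups within one developmental stage.

    Subsets the samples to ``stage`` (all samples when None), fits the
    contrast, and returns the table plus the DEG set at ``alpha``.
    """
    tt = traits
    if stage is not None:
        keep = [s for s, g in zip(tt.sample_ids, tt.column(stage_column)) if g == stage]
        if not keep:
            raise ValueError(f"no samples at stage {stage!r}")
        em = em.subset_samples(keep)
        tt = tt.subset_samples(keep)
    groups = tt.binary_trait(trait)
    table = deg_table(em, groups, alpha=alpha, prior_df=prior_df)
    name = f"degs_{stage}" if stage else "degs"
    return table, call_degs(table, alpha=alpha, name=name)


class ModeratedTTest(BaseEstimator):
    """Feature-wise moderated two-group t-test (scikit-learn style).

    Parameters
    ----------
    alpha:
        FDR level used by :meth:`significant` and ``de_``.
    prior_df:
        None to estimate the prior degrees of freedom from the data,
        0 for the ordinary pooled t, ``np.inf`` for full shrinkage.

    Attributes (after :meth:`fit` on X of shape (n_samples, n_features))
    ----------
    effect_, t_, pvalue_, qvalue_ : ndarray per feature
    prior_df_, prior_s2_ : estimated empirical-Bayes hyperparameters
    de_ : boolean mask of features with qvalue_ < alpha
    """

    def __init__(self, alpha: float = 0.05, prior_df: float | None = None):
        self.alpha = alpha
        self.prior_df = prior_df

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n_samples, n_features) with aligned y")
        em = ExpressionMatrix(
            pd.DataFrame(
                X.T,
                index=[f"f{i}" for i in range(X.shape[1])],
                columns=[f"s{i}" for i in range(X.shape[0])],
            )
        )
        gstats = fit_group_contrast(em, y)
        params, t, p = ebayes_moderate(gstats, prior_df=self.prior_df)
        self.effect_ = gstats.effect
        self.t_ = t
        self.pvalue_ = p
        self.qvalue_ = bh_adjust(p)
        self.prior_df_ = params.d0
        self.prior_s2_ = params.s02
        self.de_ = self.qvalue_ < self.alpha
        self.n_features_in_ = X.shape[1]
        return self

    def significant(self, alpha: float | None = None) -> np.ndarray:
        """Indices of features significant at the (adjusted) level."""
        a = self.alpha if alpha is None else alpha
        return np.flatnonzero(self.qvalue_ < a)
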