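"""End-to-end orchestration of the four analysis orderings and their
comparison.

The four methods share the same ingredients and differ only in what is
filtered when:

* method 1 - differential expression alone (DEGs at the configured stage);
* method 2 - co-expression network on the full matrix, trait-module
  selection and hub/significance gene filters, no DEG filter;
* method 3 - DEG filter FIRST, network built on the DEG submatrix (its own
  soft threshold re-selected), then the same module/gene filters;
* method 4 - the method-2 network and filters first, THEN intersection with
  the same DEG list.

Everything downstream of the inputs is deterministic, so identical inputs
and configuration reproduce identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from . import degs as de
from . import netstats
from .datamodel import ExpressionMatrix, GeneSet, KeyGeneList, TraitTable
from .io import align_samples, detect_sample_outliers
from .modules import WGCNA
from .network import ScaleFreeFit, soft_threshold_scan, pick_soft_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "MethodConfig",
    "MethodResult",
    "run_method",
    "run_all_methods",
    "jaccard_index",
    "key_gene_recall",
    "fit_grid",
    "identify_early_biomarkers",
    "compare",
    "ComparisonReport",
]


@dataclass(frozen=True)
class MethodConfig:
    """Configuration shared by the four methods.

    ``deg_stage`` names the stage whose male/female contrast defines the DEG
    list; the default (None) contrasts the trait across all samples, which
    suits designs where the trait acts at every stage - restrict to one
    stage to define stage-specific DEG lists. ``outlier_cutoff`` enables
    dendrogram-based sample removal when set. ``prefilter`` switches method
    3 to the other pre-filters in common use (top-variance / top-expressed
    fraction).
    """

    method: int = 4
    trait: str = "sex"
    stage_column: str = "stage"
    deg_stage: str | None = None
    deg_alpha: float = 0.05
    betas: tuple = tuple(range(1, 21))
    r2_cut: float = 0.8
    min_module_size: int = 30
    merge_cut: float = 0.25
    criteria: assoc.ModuleSelectionCriteria = field(
        default_factory=assoc.ModuleSelectionCriteria
    )
    edge_threshold: float = 0.2
    outlier_cutoff: float | None = None
    prefilter: str = "degs"
    prefilter_fraction: float = 0.25

    def __post_init__(self):
        if self.method not in (1, 2, 3, 4):
            raise ValueError("method must be 1, 2, 3 or 4")
        if self.prefilter not in ("degs", "top_var_fraction", "top_expr_fraction"):
            raise ValueError(f"unknown prefilter {self.prefilter!r}")


@dataclass
class MethodResult:
    """Everything a method produced, with provenance of applied filters."""

    method: int
    genes: GeneSet
    universe: frozenset
    degs: GeneSet | None = None
    beta: int | None = None
    fit: ScaleFreeFit | None = None
    scan: list | None = None
    module_count: int = 0
    partition: object | None = None
    eigengenes: object | None = None
    module_trait: pd.DataFrame | None = None
    selected_modules: list = field(default_factory=list)
    retained_modules: list = field(default_factory=list)
    scores: pd.DataFrame | None = None
    coexpressed_genes: GeneSet | None = None
    per_module_counts: pd.Series | None = None
    top_module: str | None = None
    top_module_stats: netstats.TopologyStats | None = None
    provenance: list = field(default_factory=list)

    @property
    def trait_module_count(self) -> int:
        return len(self.selected_modules)


def _deg_set(em: ExpressionMatrix, tt: TraitTable, cfg: MethodConfig):
    table, genes = de.stage_degs(
        em,
        tt,
        trait=cfg.trait,
        stage=cfg.deg_stage,
        stage_column=cfg.stage_column,
        alpha=cfg.deg_alpha,
    )
    return table, genes


def _prefilter_genes(em: ExpressionMatrix, degset: GeneSet, cfg: MethodConfig) -> GeneSet:
    if cfg.prefilter == "degs":
        return degset
    frac = cfg.prefilter_fraction
    n_keep = max(1, int(round(frac * em.n_genes)))
    stat = (
        em.data.var(axis=1, ddof=1)
        if cfg.prefilter == "top_var_fraction"
        else em.data.mean(axis=1)
    )
    keep = stat.sort_values(ascending=False).index[:n_keep]
    return GeneSet(cfg.prefilter, set(keep))


def _network_branch(em: ExpressionMatrix, tt: TraitTable, cfg: MethodConfig) -> MethodResult:
    """The shared network pipeline: scan -> modules -> trait selection ->
    MM-GS screen -> gene filters. Used directly by method 2, on the DEG
    submatrix by method 3, and as the first stage of method 4."""
    provenance = []
    if cfg.outlier_cutoff is not None:
        outliers, _ = detect_sample_outliers(em, cfg.outlier_cutoff)
        if outliers:
            keep = [s for s in em.sample_ids if s not in set(outliers)]
            em = em.subset_samples(keep)
            tt = tt.subset_samples(keep)
            provenance.append(f"removed outlier samples {outliers}")
    model = WGCNA(
        beta="auto",
        betas=cfg.betas,
        r2_cut=cfg.r2_cut,
        min_module_size=cfg.min_module_size,
        merge_cut=cfg.merge_cut,
    ).fit(em)
    provenance.append(f"selected beta={model.beta_} ({model.selection_rule_})")
    provenance.append(
        f"{len(model.partition_.modules)} modules of >= {cfg.min_module_size} genes"
    )
    result = MethodResult(
        method=cfg.method,
        genes=GeneSet("empty", set()),
        universe=frozenset(em.gene_ids),
        beta=model.beta_,
        fit=model.fit_,
        scan=model.scan_,
        module_count=len(model.partition_.modules),
        provenance=provenance,
    )
    result.partition = model.partition_
    result.eigengenes = model.eigengenes_
    if not model.partition_.modules:
        logger.warning("no modules detected; empty gene set")
        return result

    trait_vec = tt.binary_trait(cfg.trait)
    mtr = assoc.module_trait_correlation(model.eigengenes_, trait_vec)
    result.module_trait = mtr
    em_used = em.subset_genes(model.gene_ids_)
    scores = assoc.gene_scores(
        em_used, trait_vec, model.eigengenes_, model.adjacency_, model.partition_
    )
    result.scores = scores
    selected = assoc.select_trait_modules(mtr, cfg.criteria, scores=scores)
    result.selected_modules = list(selected.index)
    provenance.append(
        f"{len(selected)} trait modules at |r|>{cfg.criteria.r_min}, "
        f"p<{cfg.criteria.p_max}: {list(selected.index)}"
    )
    if not len(selected):
        logger.warning("no module passed trait selection; empty gene set")
        return result
    retained, screen = assoc.mm_gs_module_screen(scores, selected.index, cfg.criteria)
    result.retained_modules = retained
    provenance.append(f"MM-GS screen retained {retained}")
    filtered = assoc.filter_module_genes(
        scores, retained, cfg.criteria, name=f"method{cfg.method}_coexpressed"
    )
    provenance.append(
        f"gene filters |GS|>{cfg.criteria.gs_min}, |kME|>{cfg.criteria.kme_min}: "
        f"{len(filtered)} genes"
    )
    result.coexpressed_genes = filtered
    result.genes = filtered
    members = scores.loc[scores.index.isin(filtered.genes), "module"]
    result.per_module_counts = members.value_counts().sort_values(ascending=False)

    if result.selected_modules:
        by_abs_r = mtr.loc[result.selected_modules, "r"].abs().sort_values(ascending=False)
        top = by_abs_r.index[0]
        result.top_module = top
        mod_genes = model.partition_.genes_in(top)
        sub_adj = model.adjacency_.loc[mod_genes, mod_genes]
        g = netstats.threshold_network(sub_adj, cfg.edge_threshold)
        if g.number_of_nodes() >= 2:
            result.top_module_stats = netstats.topology_stats(g)
    return result


def run_method(
    em: ExpressionMatrix, tt: TraitTable, cfg: MethodConfig
) -> MethodResult:
    """Run one of the four methods end to end on an aligned dataset."""
    em, tt = align_samples(em, tt)
    needs_degs = cfg.method in (1, 3, 4)
    deg_table_, degset = (None, None)
    if needs_degs:
        deg_table_, degset = _deg_set(em, tt, cfg)

    if cfg.method == 1:
        res = MethodResult(
            method=1,
            genes=degset,
            universe=frozenset(em.gene_ids),
            degs=degset,
            provenance=[
                f"DEGs at {cfg.deg_stage or 'all stages'} (adjusted p < {cfg.deg_alpha}): "
                f"{len(degset)} genes"
            ],
        )
        return res

    if cfg.method == 3:
        pre = _prefilter_genes(em, degset, cfg)
        if not pre.genes:
            raise ValueError("prefilter produced an empty gene list: nothing to network")
        sub = em.subset_genes(pre.genes)
        res = _network_branch(sub, tt, cfg)
        res.method = 3
        res.degs = degset
        res.universe = frozenset(em.gene_ids)  # report against the input universe
        res.provenance.insert(0, f"prefilter {cfg.prefilter}: {len(pre)} genes kept")
        return res

    res = _network_branch(em, tt, cfg)
    res.method = cfg.method
    if cfg.method == 4:
        res.degs = degset
        if res.coexpressed_genes is not None:
            inter, per_module = assoc.intersect_with_degs(
                res.coexpressed_genes, degset, res.scores
            )
            res.genes = GeneSet("method4_co_degs", inter.genes)
            res.per_module_counts = per_module
            res.provenance.append(
                f"intersected with {len(degset)} DEGs: {len(res.genes)} genes"
            )
    return res


def run_all_methods(
    em: ExpressionMatrix, tt: TraitTable, cfg: MethodConfig = MethodConfig()
) -> dict[int, MethodResult]:
    """Run methods 1-4, computing the shared full-matrix network only once."""
    em, tt = align_samples(em, tt)
    deg_table_, degset = _deg_set(em, tt, cfg)

    results: dict[int, MethodResult] = {}
    results[1] = MethodResult(
        method=1,
        genes=degset,
        universe=frozenset(em.gene_ids),
        degs=degset,
        provenance=[f"DEGs: {len(degset)} genes"],
    )

    cfg2 = _with(cfg, method=2)
    res2 = _network_branch(em, tt, cfg2)
    res2.method = 2
    results[2] = res2

    cfg3 = _with(cfg, method=3)
    pre = _prefilter_genes(em, degset, cfg3)
    if pre.genes:
        res3 = _network_branch(em.subset_genes(pre.genes), tt, cfg3)
        res3.method = 3
        res3.degs = degset
        res3.universe = frozenset(em.gene_ids)
        res3.provenance.insert(0, f"prefilter {cfg.prefilter}: {len(pre)} genes kept")
    else:
        # the strict single-method API raises here; in a batch run the
        # degenerate outcome is itself a result worth reporting
        logger.warning("method 3 prefilter kept no genes: nothing to network")
        res3 = MethodResult(
            method=3,
            genes=GeneSet("method3_empty", set()),
            universe=frozenset(em.gene_ids),
            degs=degset,
            provenance=["prefilter kept no genes; no network built"],
        )
    results[3] = res3

    res4 = MethodResult(
        method=4,
        genes=res2.genes,
        universe=res2.universe,
        degs=degset,
        beta=res2.beta,
        fit=res2.fit,
        scan=res2.scan,
        module_count=res2.module_count,
        module_trait=res2.module_trait,
        selected_modules=list(res2.selected_modules),
        retained_modules=list(res2.retained_modules),
        scores=res2.scores,
        coexpressed_genes=res2.coexpressed_genes,
        top_module=res2.top_module,
        top_module_stats=res2.top_module_stats,
        provenance=list(res2.provenance),
    )
    res4.partition = res2.partition
    res4.eigengenes = res2.eigengenes
    if res2.coexpressed_genes is not None:
        inter, per_module = assoc.intersect_with_degs(
            res2.coexpressed_genes, degset, res2.scores
        )
        res4.genes = GeneSet("method4_co_degs", inter.genes)
        res4.per_module_counts = per_module
        res4.provenance.append(
            f"intersected with {len(degset)} DEGs: {len(res4.genes)} genes"
        )
    results[4] = res4
    return results


def _with(cfg: MethodConfig, **kw) -> MethodConfig:
    from dataclasses import replace

    return replace(cfg, **kw)


def small_sample_config(**overrides) -> MethodConfig:
    """Method configuration for small designs (roughly 12-20 samples).

    Two module-selection thresholds are relaxed relative to the large-sample
    defaults, for power reasons that follow from the sample size alone:
    the trait-module p-value threshold is 0.01 (the value used in practice
    for datasets below the ~15-sample network recommendation), and the
    MM-GS screen threshold is 0.3 - with ~20 samples the sampling noise of
    gene-wise trait-significance estimates (se ~ 0.1) caps the attainable
    membership/significance correlation of even a perfectly coherent module
    well below 1, so the large-sample 0.5 cut rejects genuine modules.
    """
    criteria = assoc.ModuleSelectionCriteria(p_max=0.01, mmgs_r_min=0.3)
    kw = dict(criteria=criteria)
    kw.update(overrides)
    return MethodConfig(**kw)


def jaccard_index(a: GeneSet, b: GeneSet) -> float:
    """Jaccard similarity of two gene sets, as a percentage."""
    union = a.genes | b.genes
    if not union:
        raise ValueError("both gene sets are empty")
    return 100.0 * len(a.genes & b.genes) / len(union)


def key_gene_recall(
    gs: GeneSet, key: KeyGeneList
) -> tuple[float, list[str], list[str]]:
    """Percentage of curated key genes present in a gene set, with the
    explicit found / missing lists."""
    found = [g for g in key if g in gs.genes]
    missing = [g for g in key if g not in gs.genes]
    return 100.0 * len(found) / len(key), found, missing


def fit_grid(
    em: ExpressionMatrix,
    subset: GeneSet,
    betas: Sequence[int] = tuple(range(1, 21)),
    r2_cut: float = 0.8,
) -> pd.DataFrame:
    """Scale-free fit table for the full matrix and a subset matrix.

    One row per (matrix, beta) with signed R^2, mean connectivity, slope and
    slope R^2; each matrix's selected beta is marked. This is the machine
    behind threshold-robustness comparisons of the two orderings.
    """
    rows = []
    for tag, matrix in (("full", em), ("subset", em.subset_genes(subset.genes))):
        scan = soft_threshold_scan(matrix, betas=betas)
        chosen = pick_soft_threshold(scan, r2_cut=r2_cut).beta
        for f in scan:
            rows.append(
                {
                    "matrix": tag,
                    "beta": f.beta,
                    "signed_r2": f.signed_r2,
                    "mean_k": f.mean_k,
                    "slope": f.slope,
                    "slope_r2": f.slope_r2,
                    "selected": f.beta == chosen,
                }
            )
    return pd.DataFrame(rows)


def identify_early_biomarkers(
    result: MethodResult,
    early_degs: GeneSet,
    key: KeyGeneList | None = None,
) -> pd.DataFrame:
    """Candidate biomarkers of the EARLY stage.

    Genes that passed module selection and the GS/membership filters
    (``result.coexpressed_genes``) and are also differentially expressed at
    the first stage, ranked by |kME|; curated key genes are flagged.
    """
    if result.coexpressed_genes is None or result.scores is None:
        raise ValueError("result carries no network gene list (run method 2 or 4)")
    if not early_degs.genes:
        logger.warning("early DEG list is empty; no biomarker candidates")
        return pd.DataFrame(columns=["module", "kME", "GS_cor", "is_key"])
    cand = sorted(result.coexpressed_genes.genes & early_degs.genes)
    if not cand:
        return pd.DataFrame(columns=["module", "kME", "GS_cor", "is_key"])
    sub = result.scores.loc[cand, ["module", "kME", "GS_cor"]].copy()
    sub["is_key"] = [g in set(key.genes) if key else False for g in sub.index]
    sub = sub.reindex(sub["kME"].abs().sort_values(ascending=False).index)
    sub.insert(0, "rank", np.arange(1, len(sub) + 1))
    return sub


@dataclass
class ComparisonReport:
    summary: pd.DataFrame
    jaccard: pd.DataFrame
    winners: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": json.loads(self.summary.to_json(orient="index")),
                "jaccard": json.loads(self.jaccard.to_json(orient="index")),
                "winners": self.winners,
            },
            indent=2,
            sort_keys=True,
        )


def compare(
    results: dict[int, MethodResult] | Sequence[MethodResult],
    key: KeyGeneList | None = None,
) -> ComparisonReport:
    """Assemble the cross-method report: per-method summaries, pairwise
    Jaccard percentages, key-gene recall, and per-criterion winner flags."""
    if isinstance(results, dict):
        res_list = [results[k] for k in sorted(results)]
    else:
        res_list = list(results)
    if len(res_list) < 2:
        raise ValueError("need at least two method results to compare")
    universes = {r.universe for r in res_list}
    if len(universes) > 1:
        sizes = sorted(len(u) for u in universes)
        raise ValueError(f"results come from different gene universes (sizes {sizes})")

    rows = {}
    for r in res_list:
        name = f"method{r.method}"
        row = {
            "n_genes": len(r.genes),
            "pct_of_universe": 100.0 * len(r.genes) / len(r.universe),
            "beta": r.beta,
            "signed_r2": r.fit.signed_r2 if r.fit else np.nan,
            "mean_k": r.fit.mean_k if r.fit else np.nan,
            "slope": r.fit.slope if r.fit else np.nan,
            "module_count": r.module_count,
            "trait_module_count": r.trait_module_count,
            "top_module": r.top_module,
        }
        if r.top_module_stats is not None:
            for k, v in r.top_module_stats.as_dict().items():
                row[f"top_{k}"] = v
        if key is not None:
            recall, found, _ = key_gene_recall(r.genes, key)
            row["key_gene_recall"] = recall
            row["key_genes_found"] = len(found)
        rows[name] = row
    summary = pd.DataFrame(rows).T

    names = [f"method{r.method}" for r in res_list]
    jac = pd.DataFrame(100.0, index=names, columns=names)
    for i, a in enumerate(res_list):
        for j, b in enumerate(res_list):
            if i < j:
                try:
                    v = jaccard_index(a.genes, b.genes)
                except ValueError:
                    v = np.nan
                jac.iloc[i, j] = jac.iloc[j, i] = v

    winners = {}
    by_method = {r.method: r for r in res_list}
    if 3 in by_method and 4 in by_method:
        r3, r4 = by_method[3], by_method[4]
        if r3.fit and r4.fit:
            winners["signed_r2"] = "method4" if r4.fit.signed_r2 > r3.fit.signed_r2 else "method3"
        winners["module_count"] = "method4" if r4.module_count >= r3.module_count else "method3"
        if key is not None:
            rec3, _, _ = key_gene_recall(r3.genes, key)
            rec4, _, _ = key_gene_recall(r4.genes, key)
            winners["key_gene_recall"] = "method4" if rec4 >= rec3 else "method3"
    return ComparisonReport(summary, jac, winners)
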