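import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexorder as cx
from coexorder.association import (
    ModuleSelectionCriteria,
    filter_module_genes,
    gene_scores,
    intersect_with_degs,
    mm_gs_module_screen,
    module_trait_correlation,
    select_trait_modules,
)
from coexorder.modules import EigengeneMatrix, ModulePartition


def _megs(profiles: dict, samples=None):
    df = pd.DataFrame(profiles).T
    if samples is not None:
        df.columns = samples
    df.index.name = "module"
    return EigengeneMatrix(df, pd.Series(1.0, index=df.index))


class TestModuleTraitCorrelation:
    def test_identity_and_orthogonal(self):
        trait = np.array([0, 0, 0, 1, 1, 1])
        aligned = (trait - trait.mean()) / trait.std()
        orth = np.array([1.0, -1.0, 0.0, 0.0, 1.0, -1.0])
        mtr = module_trait_correlation(
            _megs({"turquoise": aligned, "blue": orth}), trait
        )
        assert np.isclose(mtr.loc["turquoise", "r"], 1.0)
        assert abs(mtr.loc["blue", "r"]) < 1e-10

    def test_p_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n = 12
        trait = np.array([0, 1] * 6)
        me = rng.normal(size=n)
        mtr = module_trait_correlation(_megs({"m": me}), trait)
        r = mtr.loc["m", "r"]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_expected = 2 * stats.t.sf(abs(t), n - 2)
        assert abs(mtr.loc["m", "p"] - p_expected) < 1e-10

    def test_p_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(1)
        n = 20
        trait = rng.integers(0, 2, size=n)
        trait[:2] = [0, 1]
        for _ in range(5):
            me = rng.normal(size=n)
            mtr = module_trait_correlation(_megs({"m": me}), trait)
            r_ref, p_ref = stats.pearsonr(me, trait)
            assert abs(mtr.loc["m", "r"] - r_ref) < 1e-10
            assert abs(mtr.loc["m", "p"] - p_ref) < 1e-10

    def test_constant_trait_errors(self):
        with pytest.raises(ValueError):
            module_trait_correlation(_megs({"m": np.arange(5.0)}), np.ones(5))


class TestSelectTraitModules:
    def _mtr(self, rows):
        return pd.DataFrame(rows, columns=["r", "p"], index=[f"m{i}" for i in range(len(rows))])

    def test_threshold_selection(self):
        mtr = self._mtr([(0.95, 1e-10), (-0.79, 1e-5), (0.3, 1e-8)])
        sel = select_trait_modules(mtr, ModuleSelectionCriteria())
        assert set(sel.index) == {"m0", "m1"}

    def test_p_boundary_rejected(self):
        mtr = self._mtr([(0.9, 0.002)])
        sel = select_trait_modules(mtr, ModuleSelectionCriteria(p_max=0.001))
        assert len(sel) == 0

    def test_module_significance_ranking_attached(self):
        mtr = self._mtr([(0.9, 1e-8), (0.8, 1e-6)])
        scores = pd.DataFrame(
            {
                "module": ["m0"] * 3 + ["m1"] * 3,
                "GS_cor": [0.2, 0.3, 0.1, 0.8, 0.9, 0.7],
            },
            index=[f"g{i}" for i in range(6)],
        )
        sel = select_trait_modules(mtr, scores=scores)
        assert list(sel.index) == ["m1", "m0"]  # ranked by MS
        assert np.isclose(sel.loc["m1", "MS"], 0.8)


class TestGeneScores:
    @staticmethod
    def _setup():
        rng = np.random.default_rng(3)
        n = 12
        trait = np.array([0] * 6 + [1] * 6)
        u = trait * 2.0 + rng.normal(size=n)
        X = np.vstack(
            [
                trait.astype(float),  # g0 identical to trait
                2 * u + rng.normal(0, 0.3, n),
                1.5 * u + rng.normal(0, 0.3, n),
                u + rng.normal(0, 0.3, n),
                rng.normal(size=(6, n)),
            ]
        )
        ids = [f"g{i}" for i in range(10)]
        em = cx.ExpressionMatrix(
            pd.DataFrame(X, index=ids, columns=[f"s{i}" for i in range(n)])
        )
        labels = pd.Series(
            ["turquoise"] * 4 + ["grey"] * 6, index=ids
        )
        part = ModulePartition(labels, min_size=2)
        megs = cx.module_eigengenes(em, part)
        cor = cx.pearson_correlation(em)
        adj = cx.adjacency(cor, 2)
        return em, trait, megs, adj, part

    def test_identity_gene_has_unit_gs(self):
        em, trait, megs, adj, part = self._setup()
        sc = gene_scores(em, trait, megs, adj, part)
        assert np.isclose(sc.loc["g0", "GS_cor"], 1.0)
        assert sc.loc["g0", "GS_logp"] > 10

    def test_gs_logp_arithmetic(self):
        em, trait, megs, adj, part = self._setup()
        sc = gene_scores(em, trait, megs, adj, part)
        np.testing.assert_allclose(
            sc["GS_logp"], -np.log10(np.clip(sc["GS_p"], 1e-300, None)), atol=1e-10
        )

    def test_kim_matches_loop_oracle(self):
        em, trait, megs, adj, part = self._setup()
        sc = gene_scores(em, trait, megs, adj, part)
        A = adj.to_numpy()
        member_idx = [0, 1, 2, 3]
        for i in member_idx:
            expected = sum(A[i, j] for j in member_idx if j != i)
            assert np.isclose(sc["kIM"].iloc[i], expected, atol=1e-12)
        assert np.isclose(sc["kIM_norm"].iloc[:4].max(), 1.0)
        assert sc["kIM"].iloc[4:].isna().all()

    def test_kme_of_eigengene_proxy_gene(self):
        """A gene that duplicates the eigengene profile has |kME| = 1."""
        n = 10
        rng = np.random.default_rng(4)
        base = rng.normal(size=(4, n))
        em0 = cx.ExpressionMatrix(
            pd.DataFrame(base, index=[f"g{i}" for i in range(4)],
                         columns=[f"s{i}" for i in range(n)])
        )
        part0 = ModulePartition(
            pd.Series(["turquoise"] * 4, index=em0.gene_ids), min_size=2
        )
        megs = cx.module_eigengenes(em0, part0)
        proxy = megs.profiles.loc["turquoise"].to_numpy()
        X = np.vstack([base, proxy])
        em = cx.ExpressionMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(5)],
                         columns=[f"s{i}" for i in range(n)])
        )
        part = ModulePartition(
            pd.Series(["turquoise"] * 5, index=em.gene_ids), min_size=2
        )
        trait = np.array([0, 1] * 5)
        cor = cx.pearson_correlation(em)
        sc = gene_scores(em, trait, megs, cx.adjacency(cor, 2), part)
        assert abs(sc.loc["g4", "kME_turquoise"]) > 0.999


class TestMMGSScreen:
    @staticmethod
    def _scores(kme, gs, module="turquoise"):
        n = len(kme)
        return pd.DataFrame(
            {"module": [module] * n, "kME": kme, "GS_cor": gs},
            index=[f"g{i}" for i in range(n)],
        )

    def test_coherent_module_retained(self):
        rng = np.random.default_rng(0)
        kme = rng.uniform(0.3, 0.95, 40)
        gs = 0.7 * kme + rng.normal(0, 0.05, 40)
        retained, table = mm_gs_module_screen(
            self._scores(kme, gs), ["turquoise"], ModuleSelectionCriteria()
        )
        assert retained == ["turquoise"]
        assert table.loc["turquoise", "mmgs_r"] > 0.5

    def test_anticorrelated_module_discarded(self):
        rng = np.random.default_rng(1)
        kme = rng.uniform(0.3, 0.95, 40)
        gs = -0.7 * kme + 0.9 + rng.normal(0, 0.05, 40)
        retained, _ = mm_gs_module_screen(
            self._scores(kme, gs), ["turquoise"], ModuleSelectionCriteria()
        )
        assert retained == []

    def test_weak_correlation_discarded_despite_tiny_p(self):
        rng = np.random.default_rng(2)
        n = 5000  # huge module: p is tiny even at r ~ 0.25
        kme = rng.uniform(0.3, 0.95, n)
        gs = 0.25 * (kme - kme.mean()) / kme.std() * 0.2 + rng.normal(0, 0.2, n) + 0.5
        scores = self._scores(np.abs(kme), np.abs(gs))
        retained, table = mm_gs_module_screen(
            scores, ["turquoise"], ModuleSelectionCriteria(mmgs_r_min=0.5)
        )
        assert table.loc["turquoise", "mmgs_p"] < 0.05
        assert retained == []

    def test_small_module_rejected(self):
        sc = self._scores(np.linspace(0.3, 0.9, 5), np.linspace(0.1, 0.5, 5))
        with pytest.raises(ValueError):
            mm_gs_module_screen(sc, ["turquoise"])


class TestFilterModuleGenes:
    @staticmethod
    def _scores():
        return pd.DataFrame(
            {
                "module": ["turquoise"] * 4 + ["blue"],
                "GS_cor": [0.5, 0.5, 0.2, -0.6, 0.9],
                "GS_logp": [3.0, 3.0, 1.0, 4.0, 9.0],
                "kME": [0.9, 0.7, 0.9, -0.85, 0.95],
                "kIM_norm": [1.0, 0.5, 0.9, 0.95, 1.0],
            },
            index=["a", "b", "c", "d", "e"],
        )

    def test_threshold_combinations(self):
        got = filter_module_genes(self._scores(), ["turquoise"])
        # a passes; b fails kME; c fails GS boundary (strict); d passes via
        # absolute values; e is outside retained modules
        assert got.genes == frozenset({"a", "d"})

    def test_boundary_gs_exactly_dropped(self):
        sc = self._scores()
        assert "c" not in filter_module_genes(sc, ["turquoise"]).genes

    def test_monotone_in_thresholds(self):
        sc = self._scores()
        base = filter_module_genes(sc, ["turquoise", "blue"]).genes
        tighter = filter_module_genes(
            sc, ["turquoise", "blue"], ModuleSelectionCriteria(gs_min=0.55, kme_min=0.9)
        ).genes
        assert tighter <= base

    def test_alternative_definitions_available(self):
        sc = self._scores()
        crit = ModuleSelectionCriteria(gs_definition="logp", gs_min=0.2, kme_min=0.8,
                                       membership="kim_norm")
        got = filter_module_genes(sc, ["turquoise"], crit)
        assert got.genes == frozenset({"a", "c", "d"})


class TestIntersectWithDegs:
    def test_identity_and_disjoint(self):
        a = cx.GeneSet("a", {"x", "y"})
        inter, _ = intersect_with_degs(a, cx.GeneSet("b", {"x", "y"}))
        assert inter.genes == a.genes
        empty, _ = intersect_with_degs(a, cx.GeneSet("c", {"z"}))
        assert len(empty) == 0

    def test_subset_property_and_counts(self):
        a = cx.GeneSet("a", {"x", "y", "z"})
        b = cx.GeneSet("b", {"y", "z", "w"})
        scores = pd.DataFrame(
            {"module": ["turquoise", "blue", "blue", "grey"]},
            index=["x", "y", "z", "w"],
        )
        inter, counts = intersect_with_degs(a, b, scores)
        assert inter.genes <= a.genes and inter.genes <= b.genes
        assert counts["blue"] == 2
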