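import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import coexorder as cx
from coexorder.degs import (
    ModeratedTTest,
    bh_adjust,
    call_degs,
    deg_table,
    ebayes_moderate,
    fit_group_contrast,
)


def _em(X):
    return cx.ExpressionMatrix(
        pd.DataFrame(
            X,
            index=[f"g{i}" for i in range(X.shape[0])],
            columns=[f"s{i}" for i in range(X.shape[1])],
        )
    )


class TestGroupContrast:
    def test_constant_groups(self):
        em = _em(np.array([[1.0, 1.0, 3.0, 3.0]]))
        gs = fit_group_contrast(em, [0, 0, 1, 1])
        assert gs.effect[0] == 2.0 and gs.s2[0] == 0.0 and gs.df == 2

    def test_identical_groups_zero_effect(self):
        em = _em(np.array([[1.0, 2.0, 1.0, 2.0]]))
        gs = fit_group_contrast(em, [0, 0, 1, 1])
        assert gs.effect[0] == 0.0

    def test_pooled_variance_matches_textbook(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=8)
        em = _em(x[None, :])
        gs = fit_group_contrast(em, [0, 0, 0, 0, 1, 1, 1, 1])
        g0, g1 = x[:4], x[4:]
        sp2 = (((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()) / 6
        assert np.isclose(gs.s2[0], sp2, atol=1e-12)
        assert np.isclose(gs.effect[0], g1.mean() - g0.mean(), atol=1e-12)

    def test_small_group_errors(self):
        em = _em(np.ones((1, 3)))
        with pytest.raises(ValueError):
            fit_group_contrast(em, [0, 1, 1])


class TestEBayes:
    def test_zero_effects_give_zero_t_unit_p(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(size=(20, 8))
        X = np.hstack([noise[:, :4], noise[:, :4]])  # group means identical
        gs = fit_group_contrast(_em(X), [0, 0, 0, 0, 1, 1, 1, 1])
        _, t, p = ebayes_moderate(gs)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, 1.0, atol=1e-12)

    def test_passthrough_equals_ordinary_t(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 10))
        groups = np.array([0] * 5 + [1] * 5)
        gs = fit_group_contrast(_em(X), groups)
        _, t, p = ebayes_moderate(gs, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(X[:, 5:].T, X[:, :5].T, equal_var=True)
        np.testing.assert_allclose(t, t_ref, atol=1e-10)
        np.testing.assert_allclose(p, p_ref, atol=1e-10)

    def test_infinite_prior_limit(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 10))
        groups = np.array([0] * 5 + [1] * 5)
        gs = fit_group_contrast(_em(X), groups)
        s02 = 2.0
        _, t, p = ebayes_moderate(gs, prior_df=np.inf, prior_s2=s02)
        expected_t = gs.effect / np.sqrt(s02 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(t, expected_t, atol=1e-12)
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(expected_t)), atol=1e-12)

    def test_shrinkage_lies_between_gene_and_prior_variance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 12)) * rng.uniform(0.3, 3.0, size=(200, 1))
        gs = fit_group_contrast(_em(X), [0] * 6 + [1] * 6)
        params, t, _ = ebayes_moderate(gs)
        s2_post = (params.d0 * params.s02 + gs.df * gs.s2) / (params.d0 + gs.df)
        lo = np.minimum(gs.s2, params.s02)
        hi = np.maximum(gs.s2, params.s02)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_zero_variance_gene_gets_finite_t(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 8))
        X[0] = [1, 1, 1, 1, 2, 2, 2, 2]  # s2 == 0, nonzero effect
        gs = fit_group_contrast(_em(X), [0] * 4 + [1] * 4)
        _, t, p = ebayes_moderate(gs)
        assert np.isfinite(t[0]) and 0 < p[0] < 1

    def test_all_zero_variance_unidentifiable(self):
        X = np.tile([1.0, 1.0, 2.0, 2.0], (5, 1))
        gs = fit_group_contrast(_em(X), [0, 0, 1, 1])
        with pytest.raises(ValueError):
            ebayes_moderate(gs)

    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: limma's moderated t on the same matrix."""
        rng = np.random.default_rng(42)
        G, n = 80, 10
        X = rng.normal(size=(G, n)) * rng.uniform(0.5, 2, size=(G, 1))
        X[:10, 5:] += 1.5
        em = _em(X)
        gs = fit_group_contrast(em, [0] * 5 + [1] * 5)
        params, t, p = ebayes_moderate(gs)
        expr = tmp_path / "expr.csv"
        pd.DataFrame(X).to_csv(expr)
        script = tmp_path / "ref.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'x <- as.matrix(read.csv("{expr}", row.names=1))\n'
            "design <- cbind(Intercept=1, grp=c(rep(0,5),rep(1,5)))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            'write.csv(data.frame(t=fit$t[,"grp"], p=fit$p.value[,"grp"]),'
            f' "{tmp_path / "out.csv"}")\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        np.testing.assert_allclose(t, ref["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(p, ref["p"].to_numpy(), atol=1e-8)


def brute_force_bh(p):
    """Literal step-up definition used as the oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p[i] * m / rank))
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=400)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=120),
           st.integers(0, 2**31 - 1))
    def test_matches_brute_force_property(self, base, seed):
        rng = np.random.default_rng(seed)
        p = np.array(base) if rng.uniform() < 0.5 else rng.uniform(size=len(base))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_rank_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDegs:
    def test_strict_inequality_boundary(self):
        table = pd.DataFrame(
            {"p_adj": [0.04, 0.05, 0.06], "p": [0.01, 0.02, 0.03]},
            index=["a", "b", "c"],
        )
        assert call_degs(table, alpha=0.05).genes == frozenset({"a"})

    def test_near_one_alpha_calls_everything(self):
        table = pd.DataFrame({"p_adj": [0.5, 0.9], "p": [0.3, 0.8]}, index=["a", "b"])
        assert len(call_degs(table, alpha=0.999)) == 2

    def test_raw_p_variant(self):
        table = pd.DataFrame({"p_adj": [0.5], "p": [0.01]}, index=["a"])
        assert len(call_degs(table, use_adjusted=False)) == 1

    def test_invalid_alpha(self):
        table = pd.DataFrame({"p_adj": [0.5], "p": [0.1]}, index=["a"])
        with pytest.raises(ValueError):
            call_degs(table, alpha=1.5)

    def test_planted_gene_sensitivity_on_fixture(self):
        """High-loading trait-module genes are recovered at FDR 0.05."""
        sens = []
        for seed in range(10):
            em, tt, gt = cx.generate(cx.default_paper_like_spec(seed))
            _, degs = cx.stage_degs(em, tt, trait="sex")
            strong = gt.table[
                (gt.table.module == "M1")
                & ~gt.table.is_connector
                & (gt.table.loading > 2.0)
            ].index
            sens.append(np.mean([g in degs.genes for g in strong]))
        assert np.mean(sens) >= 0.8


class TestPermutationInvariance:
    def test_table_unchanged_under_joint_permutation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 10))
        groups = np.array([0, 1] * 5)
        em = _em(X)
        t1 = deg_table(em, groups)
        perm = rng.permutation(10)
        em2 = em.subset_samples([f"s{i}" for i in perm])
        t2 = deg_table(em2, groups[perm])
        pd.testing.assert_frame_equal(t1, t2)


class TestModeratedTTestEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = ModeratedTTest(alpha=0.1)
        assert clone(est).get_params()["alpha"] == 0.1
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 40))
        X[6:, :5] += 3.0
        y = np.array([0] * 6 + [1] * 6)
        est.fit(X, y)
        assert est.t_.shape == (40,)
        assert set(est.significant(0.05)) >= set(range(5))

    def test_matches_functional_route(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 25))
        y = np.array([0] * 5 + [1] * 5)
        est = ModeratedTTest().fit(X, y)
        table = deg_table(_em(X.T), y)
        np.testing.assert_allclose(est.t_, table["t"].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(est.qvalue_, table["p_adj"].to_numpy(), atol=1e-12)
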