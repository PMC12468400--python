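"""Attribution: IG axioms, GradientSHAP convergence, tree Shapley against an
independent permutation-enumeration oracle, ranking, enrichment."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, pearsonr

from resistnet.attribution import (
    AttributionResult,
    compare_rankings,
    gradient_shap,
    integrated_gradients,
    ora_enrich,
    rank_genes,
    shapley_exact_tree,
    tree_shap,
)
from resistnet.trees import Tree, TreeEnsemble, train_forest


# --------------------------------------------------------------------------
# independent oracle: permutation-average Shapley over a recursive
# conditional-expectation value function (distinct code path from the
# package's bitmask enumeration and from the polynomial algorithm)
# --------------------------------------------------------------------------
def oracle_cond_exp(tree: Tree, weights, x, fixed: frozenset, head: int, node=0):
    f = tree.feature[node]
    if f < 0:
        return tree.value[node, head]
    l, r = tree.left[node], tree.right[node]
    if f in fixed:
        nxt = l if x[f] <= tree.threshold[node] else r
        return oracle_cond_exp(tree, weights, x, fixed, head, nxt)
    wl, wr = weights[l], weights[r]
    if wl + wr == 0:
        wl, wr = tree.weight[l], tree.weight[r]
    return (
        wl * oracle_cond_exp(tree, weights, x, fixed, head, l)
        + wr * oracle_cond_exp(tree, weights, x, fixed, head, r)
    ) / (wl + wr)


def oracle_weights(tree: Tree, background):
    w = np.zeros(tree.n_nodes)
    for row in background:
        node = 0
        while True:
            w[node] += 1
            f = tree.feature[node]
            if f < 0:
                break
            node = tree.left[node] if row[f] <= tree.threshold[node] else tree.right[node]
    return w


def oracle_shapley(ens: TreeEnsemble, x, head, background):
    n = ens.n_features
    weights = [oracle_weights(t, background) for t in ens.trees]
    scale = 1.0 / len(ens.trees) if ens.aggregation == "mean" else 1.0

    def v(fixed):
        return scale * sum(
            oracle_cond_exp(t, w, x, frozenset(fixed), head)
            for t, w in zip(ens.trees, weights)
        )

    phi = np.zeros(n)
    perms = list(permutations(range(n)))
    for order in perms:
        fixed = set()
        prev = v(fixed)
        for f in order:
            fixed.add(f)
            cur = v(fixed)
            phi[f] += cur - prev
            prev = cur
    return phi / len(perms)


def random_ensemble(rng, n_features, n_trees=5, depth=3, aggregation="mean"):
    def grow(d):
        nodes = []

        def add(depth_left):
            idx = len(nodes)
            if depth_left == 0 or rng.uniform() < 0.3:
                nodes.append(dict(feature=-1, threshold=0.0, left=-1, right=-1,
                                  value=rng.normal(size=2), weight=0.0))
                return idx
            nodes.append(dict(feature=int(rng.integers(0, n_features)),
                              threshold=float(rng.normal()), left=-1, right=-1,
                              value=np.zeros(2), weight=0.0))
            nodes[idx]["left"] = add(depth_left - 1)
            nodes[idx]["right"] = add(depth_left - 1)
            return idx

        add(d)
        return Tree(
            feature=[n["feature"] for n in nodes],
            threshold=[n["threshold"] for n in nodes],
            left=[n["left"] for n in nodes],
            right=[n["right"] for n in nodes],
            value=[n["value"] for n in nodes],
            weight=np.ones(len(nodes)),
        )

    trees = [grow(depth) for _ in range(n_trees)]
    return TreeEnsemble(trees, aggregation, [f"f{i}" for i in range(n_features)])


# --------------------------------------------------------------------------
# gradient methods
# --------------------------------------------------------------------------
def linear_model_fn(w):
    w = np.asarray(w, dtype=float)

    def fn(X, head):
        X = np.atleast_2d(X)
        sign = 1.0 if head == 1 else -1.0
        return sign * X @ w, sign * np.tile(w, (X.shape[0], 1))

    return fn


class TestIntegratedGradients:
    def test_linear_model_exact_for_any_steps(self, rng):
        w = rng.normal(size=4)
        X = rng.normal(size=(6, 4))
        for n_steps in (8, 33):
            res = integrated_gradients(linear_model_fn(w), X, head=1, n_steps=n_steps)
            expected = (X - X.mean(axis=0)) * w
            assert np.abs(res.per_sample - expected).max() < 1e-12
            assert res.completeness_residual.max() < 1e-9

    def test_input_at_baseline_gives_zero(self, rng):
        w = rng.normal(size=3)
        base = rng.normal(size=3)
        res = integrated_gradients(linear_model_fn(w), base[None, :], baseline=base)
        assert np.allclose(res.per_sample, 0.0)

    def test_completeness_on_fixture_model(self, desk_model, zmatrix):
        X = zmatrix.X[:16]
        res = integrated_gradients(desk_model.head_logit_and_grad, X, head=1, n_steps=256)
        f_x, _ = desk_model.head_logit_and_grad(X, 1)
        f_b, _ = desk_model.head_logit_and_grad(X.mean(axis=0)[None, :], 1)
        scale = np.abs(f_x - f_b[0])
        assert (res.completeness_residual < 0.01 * np.maximum(scale, 1e-9)).all()

    def test_min_steps_enforced(self, rng):
        with pytest.raises(ValueError):
            integrated_gradients(linear_model_fn(np.ones(2)), rng.normal(size=(3, 2)), n_steps=4)

    def test_head_anticorrelation_on_softmax_pair(self, desk_model, zmatrix):
        X = zmatrix.values.iloc[:64]
        sens = integrated_gradients(desk_model.head_logit_and_grad, X, head=0, n_steps=32)
        res = integrated_gradients(desk_model.head_logit_and_grad, X, head=1, n_steps=32)
        r, _ = pearsonr(sens.signed_aggregate, res.signed_aggregate)
        assert r < 0


class TestGradientShap:
    def test_linear_model_matches_closed_form(self, rng):
        w = rng.normal(size=3)
        X = rng.normal(size=(5, 3))
        res = gradient_shap(linear_model_fn(w), X, head=1, n_baseline_samples=64,
                            n_alpha_samples=8, noise_sd=0.05, seed=0)
        expected = (X - X.mean(axis=0)) * w
        # Monte-Carlo error shrinks with draws; bound well above 1/sqrt(512)
        assert np.abs(res.per_sample - expected).max() < 0.05

    def test_zero_noise_converges_to_ig(self, desk_model, zmatrix):
        X = zmatrix.X[:8]
        ig = integrated_gradients(desk_model.head_logit_and_grad, X, head=1, n_steps=256)
        gs = gradient_shap(desk_model.head_logit_and_grad, X, head=1,
                           n_baseline_samples=1, n_alpha_samples=512, noise_sd=0.0, seed=1)
        denom = np.abs(ig.per_sample).max()
        assert np.abs(gs.per_sample - ig.per_sample).max() / denom < 0.05

    def test_seeded_determinism(self, rng):
        w = rng.normal(size=3)
        X = rng.normal(size=(4, 3))
        a = gradient_shap(linear_model_fn(w), X, seed=9)
        b = gradient_shap(linear_model_fn(w), X, seed=9)
        assert np.array_equal(a.per_sample, b.per_sample)


class TestTreeShapley:
    def test_single_stump_puts_all_value_on_its_feature(self, rng):
        t = Tree(feature=[1, -1, -1], threshold=[0.0, 0, 0], left=[1, -1, -1],
                 right=[2, -1, -1], value=[[0, 0], [1, 0], [0, 1]], weight=[4, 2, 2])
        e = TreeEnsemble([t], "mean", ["f0", "f1", "f2"])
        bg = rng.normal(size=(20, 3))
        x = np.array([0.0, 1.0, 0.0])
        phi = shapley_exact_tree(e, x, head=1, background=bg)
        assert phi[0] == phi[2] == 0.0
        fx = e.raw_predict(x)[0, 1]
        ef = e.raw_predict(bg)[:, 1].mean()
        assert abs(phi[1] - (fx - ef)) < 1e-12

    def test_symmetric_trees_get_equal_attributions(self):
        def mk(f):
            return Tree(feature=[f, -1, -1], threshold=[0.0, 0, 0], left=[1, -1, -1],
                        right=[2, -1, -1], value=[[0, 0], [0, 0], [0, 1]], weight=[4, 2, 2])

        e = TreeEnsemble([mk(0), mk(1)], "mean", ["f0", "f1"])
        bg = np.array([[-1.0, -1.0], [1.0, 1.0], [-1.0, 1.0], [1.0, -1.0]])
        phi = shapley_exact_tree(e, np.array([1.0, 1.0]), head=1, background=bg)
        assert abs(phi[0] - phi[1]) < 1e-12

    def test_exact_matches_permutation_oracle_on_random_ensembles(self, rng):
        for i in range(30):
            nf = int(rng.integers(2, 4))
            e = random_ensemble(rng, nf, n_trees=int(rng.integers(1, 6)),
                                aggregation="mean" if i % 2 else "logit_sum")
            bg = rng.normal(size=(12, nf))
            x = rng.normal(size=nf)
            mine = shapley_exact_tree(e, x, head=i % 2, background=bg)
            ref = oracle_shapley(e, x, i % 2, bg)
            assert np.abs(mine - ref).max() < 1e-9

    def test_null_player_gets_zero(self, rng):
        # feature 2 never used by any tree
        e = random_ensemble(rng, 2)
        e2 = TreeEnsemble(e.trees, e.aggregation, ["f0", "f1", "f2"])
        bg = rng.normal(size=(10, 3))
        phi = shapley_exact_tree(e2, rng.normal(size=3), head=1, background=bg)
        assert phi[2] == 0.0

    def test_polynomial_matches_exact_on_random_ensembles(self, rng):
        for i in range(40):
            nf = int(rng.integers(2, 7))
            e = random_ensemble(rng, nf, n_trees=int(rng.integers(1, 6)), depth=4,
                                aggregation="mean" if i % 2 else "logit_sum")
            bg = rng.normal(size=(15, nf))
            X = rng.normal(size=(2, nf))
            poly = tree_shap(e, X, head=i % 2, background=bg)
            for si in range(2):
                exact = shapley_exact_tree(e, X[si], head=i % 2, background=bg)
                assert np.abs(poly.per_sample[si] - exact).max() < 1e-6

    def test_polynomial_additivity_over_trees(self, rng):
        e = random_ensemble(rng, 4, n_trees=2, aggregation="logit_sum")
        bg = rng.normal(size=(10, 4))
        x = rng.normal(size=(1, 4))
        both = tree_shap(e, x, head=1, background=bg).per_sample[0]
        singles = [
            tree_shap(TreeEnsemble([t], "logit_sum", e.feature_names), x, head=1,
                      background=bg).per_sample[0]
            for t in e.trees
        ]
        assert np.abs(both - (singles[0] + singles[1])).max() < 1e-9

    def test_degenerate_background_equal_to_x_gives_zeros(self, rng):
        e = random_ensemble(rng, 3)
        x = rng.normal(size=3)
        bg = np.tile(x, (5, 1))
        phi = shapley_exact_tree(e, x, head=0, background=bg)
        assert np.abs(phi).max() < 1e-12

    def test_exact_mode_feature_limit(self, rng):
        e = random_ensemble(rng, 2)
        e17 = TreeEnsemble(e.trees, e.aggregation, [f"f{i}" for i in range(17)])
        with pytest.raises(ValueError, match="16"):
            shapley_exact_tree(e17, np.zeros(17), background=rng.normal(size=(3, 17)))

    def test_empty_background_rejected(self, rng):
        e = random_ensemble(rng, 3)
        with pytest.raises(ValueError):
            tree_shap(e, np.zeros((1, 3)), background=np.empty((0, 3)))

    def test_forest_recovers_planted_feature_ranking(self, rng):
        X = rng.normal(size=(300, 6))
        y = (X[:, 4] + 0.3 * rng.normal(size=300) > 0).astype(int)
        e = train_forest(X, y, n_estimators=20, max_depth=4, seed=0)
        res = tree_shap(e, X[:40], head=1, background=X[:100])
        assert int(np.argmax(res.aggregate)) == 4


class TestRankingAndSets:
    def ar(self, names, scores):
        return AttributionResult(
            method="IG", head="resistance",
            per_sample=np.asarray(scores, dtype=float)[None, :],
            baseline=np.zeros(len(names)), feature_names=names,
        )

    def test_topk_sorting(self):
        r = rank_genes(self.ar(["gA", "gB", "gC"], [3, 1, 2]), K=2)
        assert r.genes == ["gA", "gC"]

    def test_k_larger_than_gene_count(self):
        r = rank_genes(self.ar(["a", "b"], [1, 2]), K=100)
        assert len(r.genes) == 2

    def test_ties_broken_lexicographically(self):
        r = rank_genes(self.ar(["b", "a", "c"], [1, 1, 1]), K=3)
        assert r.genes == ["a", "b", "c"]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rank_genes(self.ar(["a"], [1]), K=0)

    def test_compare_rankings(self):
        r1 = rank_genes(self.ar(["a", "b", "c"], [3, 2, 1]), K=3)
        r2 = rank_genes(self.ar(["b", "c", "d"], [3, 2, 1]), K=3)
        out = compare_rankings(r1, r2)
        assert out["intersection"] == ["b", "c"]
        assert out["union"] == ["a", "b", "c", "d"]
        assert list(out["jaccard"].values())[0] == 0.5
        ident = compare_rankings(r1, r1)
        assert ident["intersection"] == ident["union"]

    def test_ora_combinatorial_value(self):
        # overlap 5 of set 5 with query 5 in universe 20: p = 1/C(20,5)
        sets = {"s": ["g1", "g2", "g3", "g4", "g5"]}
        out = ora_enrich(["g1", "g2", "g3", "g4", "g5"], sets, universe=20)
        from math import comb

        assert abs(out["p"].iloc[0] - 1 / comb(20, 5)) < 1e-12
        assert out["q"].iloc[0] == out["p"].iloc[0]  # BH with m=1

    def test_ora_matches_hypergeom_oracle(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sets = {"a": universe[:10], "b": universe[5:20]}
        query = universe[:8]
        out = ora_enrich(query, sets, universe=universe).set_index("set")
        for name, members in sets.items():
            k = len(set(query) & set(members))
            p = hypergeom.sf(k - 1, 50, len(members), len(query))
            assert abs(out.loc[name, "p"] - p) < 1e-12

    def test_ora_rejects_query_outside_universe(self):
        with pytest.raises(ValueError):
            ora_enrich(["zz"], {"s": ["a"]}, universe=["a", "b"])
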