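"""Per-gene attribution for the sensitivity and resistance heads.

Three families:

* Integrated Gradients — midpoint-rule path integral from a per-feature
  mean baseline to the input; the completeness residual
  |sum_i IG_i - (F(x) - F(x'))| is reported per sample so users can judge
  (and raise) the step count.
* GradientSHAP — Monte-Carlo expectation of (x - x') grad F over sampled
  baselines (mean + Gaussian noise) and uniform path positions.
* Tree Shapley — for the neutral TreeEnsemble: an exact coalition
  enumeration (<= 16 features) and the polynomial path-dependent algorithm,
  both marginalizing absent features by the trees' weighted-path
  expectation (covers recomputed from an explicit background when given).

Attribution targets the pre-softmax logit of the chosen head for gradient
methods, and the pre-link ensemble output for trees. Head 0 = sensitivity,
head 1 = resistance.

Ranking keeps the top-K genes by mean absolute per-sample score;
over-representation of a ranked list against GMT gene sets uses the
hypergeometric upper tail with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .trees import Tree, TreeEnsemble

__all__ = [
    "AttributionResult",
    "RankedGenes",
    "integrated_gradients",
    "gradient_shap",
    "shapley_exact_tree",
    "tree_shap",
    "rank_genes",
    "compare_rankings",
    "ora_enrich",
]

HEAD_NAMES = ("sensitivity", "resistance")


@dataclass
class AttributionResult:
    method: str  # "IG" | "GS" | "TS"
    head: str  # "sensitivity" | "resistance"
    per_sample: np.ndarray  # samples x features
    baseline: np.ndarray
    feature_names: list[str]
    completeness_residual: np.ndarray | None = None

    @property
    def aggregate(self) -> np.ndarray:
        """Per-feature mean |score| (the ranking statistic)."""
        return np.abs(self.per_sample).mean(axis=0)

    @property
    def signed_aggregate(self) -> np.ndarray:
        return self.per_sample.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.feature_names,
                "method": self.method,
                "head": self.head,
                "mean_abs_score": self.aggregate,
                "mean_score": self.signed_aggregate,
            }
        )


def _head_index(head) -> int:
    if isinstance(head, str):
        return HEAD_NAMES.index(head)
    return int(head)


def _feature_names(X, n) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"f{i}" for i in range(n)]


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(X, dtype=float))


# --------------------------------------------------------------------------
# gradient methods
# --------------------------------------------------------------------------
def integrated_gradients(
    model_fn,
    X,
    head=1,
    n_steps: int = 64,
    baseline: np.ndarray | None = None,
) -> AttributionResult:
    """IG_i = (x_i - x'_i) * (1/m) sum_k dF/dx_i at x' + a_k (x - x'),
    with midpoints a_k = (k + 1/2)/m.

    ``model_fn(X, head) -> (values, grads)`` supplies the head logit and
    its input gradient (e.g. ``ResVAEClassifier.head_logit_and_grad``).
    """
    if n_steps < 8:
        raise ValueError("n_steps must be >= 8")
    h = _head_index(head)
    Xa = _as_array(X)
    names = _feature_names(X, Xa.shape[1])
    base = Xa.mean(axis=0) if baseline is None else np.asarray(baseline, dtype=float)
    diff = Xa - base
    grad_sum = np.zeros_like(Xa)
    for k in range(n_steps):
        alpha = (k + 0.5) / n_steps
        _, g = model_fn(base + alpha * diff, h)
        grad_sum += g
    scores = diff * grad_sum / n_steps
    f_x, _ = model_fn(Xa, h)
    f_b, _ = model_fn(base[None, :], h)
    residual = np.abs(scores.sum(axis=1) - (f_x - f_b[0]))
    return AttributionResult(
        method="IG",
        head=HEAD_NAMES[h],
        per_sample=scores,
        baseline=base,
        feature_names=names,
        completeness_residual=residual,
    )


def gradient_shap(
    model_fn,
    X,
    head=1,
    n_baseline_samples: int = 16,
    n_alpha_samples: int = 8,
    noise_sd: np.ndarray | float | None = None,
    seed: int = 0,
) -> AttributionResult:
    """Monte-Carlo E_{x'} E_{a~U(0,1)} [(x - x') dF/dx at x' + a(x - x')].

    Baselines are the per-feature mean perturbed by N(0, noise_sd^2);
    ``noise_sd`` defaults to 0.1 of each feature's sd.
    """
    if n_baseline_samples < 1 or n_alpha_samples < 1:
        raise ValueError("sample counts must be >= 1")
    h = _head_index(head)
    Xa = _as_array(X)
    names = _feature_names(X, Xa.shape[1])
    mean = Xa.mean(axis=0)
    if noise_sd is None:
        noise_sd = 0.1 * Xa.std(axis=0)
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), mean.shape)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(Xa)
    n_draws = n_baseline_samples * n_alpha_samples
    for _ in range(n_baseline_samples):
        base = mean + noise_sd * rng.standard_normal(mean.shape)
        diff = Xa - base
        for _ in range(n_alpha_samples):
            alpha = rng.uniform()
            _, g = model_fn(base + alpha * diff, h)
            acc += diff * g
    return AttributionResult(
        method="GS",
        head=HEAD_NAMES[h],
        per_sample=acc / n_draws,
        baseline=mean,
        feature_names=names,
    )


# --------------------------------------------------------------------------
# tree Shapley
# --------------------------------------------------------------------------
def _background_weights(tree: Tree, background: np.ndarray | None) -> np.ndarray:
    """Per-node cover: counts of background rows reaching each node, or the
    stored training weights when no background is given."""
    if background is None:
        return tree.weight
    w = np.zeros(tree.n_nodes)
    idx = np.zeros(len(background), dtype=np.int64)
    w[0] = len(background)
    stack = [(0, np.arange(len(background)))]
    while stack:
        node, rows = stack.pop()
        if tree.feature[node] < 0 or len(rows) == 0:
            continue
        go_left = background[rows, tree.feature[node]] <= tree.threshold[node]
        l, r = tree.left[node], tree.right[node]
        w[l] = go_left.sum()
        w[r] = (~go_left).sum()
        stack.append((l, rows[go_left]))
        stack.append((r, rows[~go_left]))
    return w


def _cond_exp(tree: Tree, w: np.ndarray, x: np.ndarray, mask: int, head: int) -> float:
    """Weighted-path expectation of the tree output given features in
    ``mask`` fixed at x's values."""

    def rec(node: int) -> float:
        f = tree.feature[node]
        if f < 0:
            return tree.value[node, head]
        l, r = tree.left[node], tree.right[node]
        if (mask >> f) & 1:
            return rec(l if x[f] <= tree.threshold[node] else r)
        wl, wr = w[l], w[r]
        if wl + wr <= 0:  # unreachable by background: fall back to training cover
            wl, wr = tree.weight[l], tree.weight[r]
        return (wl * rec(l) + wr * rec(r)) / (wl + wr)

    return rec(0)


def shapley_exact_tree(
    e: TreeEnsemble,
    x,
    head=1,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration (<= 16 features).

    Absent features are marginalized by the weighted-path expectation with
    covers taken from ``background`` (or the stored training covers). The
    values satisfy efficiency: their sum equals F(x) - E_background[F] on
    the pre-link output.
    """
    n = e.n_features
    if n > 16:
        raise ValueError("exact mode supports at most 16 features; use tree_shap")
    h = _head_index(head)
    x = np.asarray(x, dtype=float).ravel()
    bg = None if background is None else np.atleast_2d(np.asarray(background, float))
    weights = [_background_weights(t, bg) for t in e.trees]
    scale = 1.0 / len(e.trees) if e.aggregation == "mean" else 1.0

    v = np.zeros(1 << n)
    for mask in range(1 << n):
        v[mask] = scale * sum(
            _cond_exp(t, w, x, mask, h) for t, w in zip(e.trees, weights)
        )
    phi = np.zeros(n)
    fact = [factorial(k) for k in range(n + 1)]
    denom = fact[n]
    for mask in range(1 << n):
        s = bin(mask).count("1")
        coef = fact[s] * fact[n - s - 1] / denom
        for i in range(n):
            if not (mask >> i) & 1:
                phi[i] += coef * (v[mask | (1 << i)] - v[mask])
    return phi


def _tree_shap_single(tree: Tree, w: np.ndarray, x: np.ndarray, head: int,
                      n_features: int) -> np.ndarray:
    """Path-dependent polynomial Shapley for one tree (Lundberg-style
    path extension/unwinding)."""
    phi = np.zeros(n_features)

    def extend(path, pz, po, pi):
        # path: list of [feature, zero_fraction, one_fraction, pweight]
        depth = len(path)
        path = [row[:] for row in path]
        path.append([pi, pz, po, 1.0 if depth == 0 else 0.0])
        for i in range(depth - 1, -1, -1):
            path[i + 1][3] += po * path[i][3] * (i + 1) / (depth + 1)
            path[i][3] = pz * path[i][3] * (depth - i) / (depth + 1)
        return path

    def unwind(path, index):
        depth = len(path) - 1
        one = path[index][2]
        zero = path[index][1]
        next_one = path[depth][3]
        path = [row[:] for row in path]
        for i in range(depth - 1, -1, -1):
            if one != 0:
                tmp = path[i][3]
                path[i][3] = next_one * (depth + 1) / ((i + 1) * one)
                next_one = tmp - path[i][3] * zero * (depth - i) / (depth + 1)
            elif zero != 0:
                path[i][3] = path[i][3] * (depth + 1) / (zero * (depth - i))
            else:
                path[i][3] = 0.0
        for i in range(index, depth):
            path[i][:3] = path[i + 1][:3]
        return path[:-1]

    def unwound_sum(path, index):
        depth = len(path) - 1
        one = path[index][2]
        zero = path[index][1]
        total = 0.0
        next_one = path[depth][3]
        for i in range(depth - 1, -1, -1):
            if one != 0:
                tmp = next_one * (depth + 1) / ((i + 1) * one)
                total += tmp
                next_one = path[i][3] - tmp * zero * (depth - i) / (depth + 1)
            elif zero != 0:
                total += path[i][3] / (zero * (depth - i) / (depth + 1))
        return total

    def recurse(node, path, pz, po, pi):
        path = extend(path, pz, po, pi)
        f = tree.feature[node]
        if f < 0:
            leaf = tree.value[node, head]
            for i in range(1, len(path)):
                s = unwound_sum(path, i)
                phi[path[i][0]] += s * (path[i][2] - path[i][1]) * leaf
            return
        l, r = tree.left[node], tree.right[node]
        hot, cold = (l, r) if x[f] <= tree.threshold[node] else (r, l)
        if w[l] + w[r] <= 0:  # unreachable by background: training-cover fallback
            denom = tree.weight[l] + tree.weight[r]
            frac_hot = tree.weight[hot] / denom
            frac_cold = tree.weight[cold] / denom
        else:
            denom = w[l] + w[r]
            frac_hot = w[hot] / denom
            frac_cold = w[cold] / denom
        iz, io = 1.0, 1.0
        k = next((i for i in range(1, len(path)) if path[i][0] == f), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            path = unwind(path, k)
        recurse(hot, path, iz * frac_hot, io, f)
        recurse(cold, path, iz * frac_cold, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def tree_shap(
    e: TreeEnsemble,
    X,
    head=1,
    background: np.ndarray | None = None,
) -> AttributionResult:
    """Polynomial-time path-dependent Shapley over the whole ensemble.

    Agrees with :func:`shapley_exact_tree` for the same cover source.
    ``background=None`` uses the training covers stored in the trees; an
    explicit background must be non-empty.
    """
    h = _head_index(head)
    Xa = _as_array(X)
    names = e.feature_names
    if background is not None:
        bg = np.atleast_2d(np.asarray(background, float))
        if bg.size == 0:
            raise ValueError("background must be non-empty")
    else:
        bg = None
    weights = [_background_weights(t, bg) for t in e.trees]
    scale = 1.0 / len(e.trees) if e.aggregation == "mean" else 1.0
    out = np.zeros_like(Xa)
    for si in range(Xa.shape[0]):
        x = Xa[si]
        for t, w in zip(e.trees, weights):
            out[si] += _tree_shap_single(t, w, x, h, e.n_features)
    out *= scale
    base = (bg.mean(axis=0) if bg is not None else np.full(e.n_features, np.nan))
    return AttributionResult(
        method="TS",
        head=HEAD_NAMES[h],
        per_sample=out,
        baseline=base,
        feature_names=list(names),
    )


# --------------------------------------------------------------------------
# ranking, comparison, enrichment
# --------------------------------------------------------------------------
@dataclass
class RankedGenes:
    genes: list[str]
    scores: list[float]
    K: int
    method: str
    head: str

    def __post_init__(self):
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")


def rank_genes(a: AttributionResult, K: int = 100) -> RankedGenes:
    """Top-K genes by mean |score|, ties broken lexicographically."""
    if K < 1:
        raise ValueError("K must be >= 1")
    agg = a.aggregate
    order = sorted(range(len(agg)), key=lambda i: (-agg[i], a.feature_names[i]))[:K]
    return RankedGenes(
        genes=[a.feature_names[i] for i in order],
        scores=[float(agg[i]) for i in order],
        K=K,
        method=a.method,
        head=a.head,
    )


def compare_rankings(*lists: RankedGenes) -> dict:
    """Intersection, union, and pairwise Jaccard across ranked lists."""
    if len(lists) < 2:
        raise ValueError("need at least two rankings")
    sets = [set(r.genes) for r in lists]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    jaccard = {}
    for (i, a), (j, b) in combinations(enumerate(sets), 2):
        u = len(a | b)
        jaccard[(lists[i].method, lists[j].method)] = len(a & b) / u if u else 1.0
    return {"intersection": sorted(inter), "union": sorted(union), "jaccard": jaccard}


def ora_enrich(genes, gene_sets: dict[str, list[str]], universe) -> pd.DataFrame:
    """Over-representation per gene set: hypergeometric upper-tail p and
    BH-adjusted q.

    ``universe`` is either the universe size or an explicit gene list (gene
    sets are then intersected with it). The query must lie in the universe.
    """
    query = set(genes)
    if not query:
        raise ValueError("empty gene list")
    if isinstance(universe, int):
        M = universe
        members = {name: set(g) for name, g in gene_sets.items()}
    else:
        uni = set(universe)
        if not uni:
            raise ValueError("empty universe")
        if not query <= uni:
            raise ValueError("query genes must be contained in the universe")
        M = len(uni)
        members = {name: set(g) & uni for name, g in gene_sets.items()}
    rows = []
    for name, mem in members.items():
        k = len(query & mem)
        p = float(hypergeom.sf(k - 1, M, len(mem), len(query)))
        rows.append({"set": name, "overlap": k, "set_size": len(mem), "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p").reset_index(drop=True)
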