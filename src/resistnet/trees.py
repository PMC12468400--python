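"""Language-neutral decision-tree ensembles for the two baseline learners.

Random forests are fitted with scikit-learn and boosted trees with xgboost,
but both are exported into the neutral :class:`TreeEnsemble` structure and
every downstream computation (prediction, exact and polynomial Shapley)
runs on that structure alone, so attribution correctness is testable
independent of either library.

Conventions: ``x <= threshold`` routes left (xgboost's strict-less splits
are converted bit-exactly via nextafter); leaves carry a value for both
heads — class frequencies (sensitive, resistant) for forests and margin
contributions (-v, +v) for boosting, aggregated by mean or by
sum-then-sigmoid respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "Tree",
    "TreeEnsemble",
    "gini",
    "logistic_loss",
    "train_forest",
    "train_boosted",
    "ensemble_predict",
]

SCHEMA_VERSION = "resistnet-trees-1"


def gini(counts) -> float:
    """Gini impurity 1 - sum_c p_c^2 from per-class counts."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("node has no samples")
    p = counts / total
    return float(1.0 - (p**2).sum())


def logistic_loss(y, y_hat, floor: float = 1e-15) -> float:
    """Binary cross entropy -[y log p + (1-y) log(1-p)], averaged."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    p = np.clip(np.atleast_1d(np.asarray(y_hat, dtype=float)), floor, 1 - floor)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


@dataclass
class Tree:
    """One rooted binary tree in flat-array form.

    ``feature[i] == -1`` marks a leaf; internal nodes route
    ``x[feature] <= threshold`` to ``left``. ``value`` is (n_nodes, 2):
    per-head outputs, meaningful at leaves. ``weight`` is the training
    sample weight reaching each node (the cover used by path-dependent
    Shapley marginalization).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        self.feature = np.asarray(self.feature, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        internal = self.feature >= 0
        if ((self.left[internal] < 0) | (self.right[internal] < 0)).any():
            raise ValueError("internal nodes must have two children")

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def leaf_index(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            f = self.feature[node[active]]
            t = self.threshold[node[active]]
            go_left = X[active, f] <= t
            nxt = np.where(go_left, self.left[node[active]], self.right[node[active]])
            node[active] = nxt
            active = self.feature[node] >= 0
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.leaf_index(X)]


@dataclass
class TreeEnsemble:
    """Trees plus an aggregation rule.

    aggregation "mean": average per-head leaf values (forest probabilities).
    aggregation "logit_sum": sum per-head leaf margins (+ base_margin on the
    resistant head, mirrored on the sensitive head); ``predict`` applies the
    sigmoid, ``raw_predict`` returns margins.
    """

    trees: list[Tree]
    aggregation: str
    feature_names: list[str]
    base_margin: float = 0.0
    train_trace: list[float] | None = None

    def __post_init__(self):
        if not self.trees:
            raise ValueError("ensemble needs at least one tree")
        if self.aggregation not in {"mean", "logit_sum"}:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def raw_predict(self, X) -> np.ndarray:
        """Pre-link per-head outputs: mean leaf values for forests,
        summed margins (plus base) for boosting. Shape (n, 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError("feature count mismatch")
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        acc = np.zeros((X.shape[0], 2))
        for tree in self.trees:
            acc += tree.predict(X)
        if self.aggregation == "mean":
            return acc / len(self.trees)
        return acc + np.array([-self.base_margin, self.base_margin])

    def predict(self, X) -> np.ndarray:
        raw = self.raw_predict(X)
        if self.aggregation == "mean":
            return raw
        return expit(raw)

    # ------------------------------------------------------------- serialise
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "aggregation": self.aggregation,
            "base_margin": self.base_margin,
            "feature_names": self.feature_names,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                    "weight": t.weight.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TreeEnsemble":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unknown ensemble schema")
        trees = [Tree(**{k: np.asarray(v) for k, v in t.items()}) for t in payload["trees"]]
        return cls(
            trees=trees,
            aggregation=payload["aggregation"],
            feature_names=payload["feature_names"],
            base_margin=payload["base_margin"],
        )


# --------------------------------------------------------------------------
# exporters
# --------------------------------------------------------------------------
def _export_sklearn_tree(t) -> Tree:
    counts = t.value[:, 0, :]  # (n_nodes, 2) weighted class counts/fractions
    probs = counts / counts.sum(axis=1, keepdims=True)
    return Tree(
        feature=t.feature,  # sklearn uses -2 for leaves; normalise below
        threshold=t.threshold,
        left=t.children_left,
        right=t.children_right,
        value=probs,
        weight=t.weighted_n_node_samples,
    )


def train_forest(
    features,
    labels,
    n_estimators: int = 100,
    max_depth: int = 10,
    min_samples_split: int = 2,
    min_samples_leaf: int = 1,
    max_features: float = 0.8,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> TreeEnsemble:
    """Gini-split random forest, exported to the neutral structure.

    One forest provides both heads through its two-class leaf frequencies.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input")
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        min_samples_split=min_samples_split,
        min_samples_leaf=min_samples_leaf,
        max_features=max_features,
        criterion="gini",
        random_state=seed,
    ).fit(X, y)
    trees = []
    for est in rf.estimators_:
        t = _export_sklearn_tree(est.tree_)
        t.feature = np.where(t.left < 0, -1, t.feature)
        trees.append(t)
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return TreeEnsemble(trees=trees, aggregation="mean", feature_names=names)


def _parse_xgb_node(node: dict, store: dict) -> int:
    idx = node["nodeid"]
    store.setdefault("nodes", {})[idx] = node
    if "children" in node:
        for child in node["children"]:
            _parse_xgb_node(child, store)
    return idx


def _export_xgb_tree(dump: dict) -> Tree:
    store: dict = {}
    _parse_xgb_node(dump, store)
    nodes = store["nodes"]
    ids = sorted(nodes)
    remap = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    feature = np.full(n, -1, dtype=np.int64)
    threshold = np.zeros(n)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    value = np.zeros((n, 2))
    weight = np.zeros(n)
    for nid in ids:
        d = nodes[nid]
        i = remap[nid]
        weight[i] = d.get("cover", 0.0)
        if "leaf" in d:
            v = float(d["leaf"])
            value[i] = (-v, v)
        else:
            feature[i] = int(str(d["split"]).lstrip("f"))
            # xgboost routes x < t left; our convention is x <= t
            threshold[i] = np.nextafter(float(d["split_condition"]), -np.inf)
            left[i] = remap[d["yes"]]
            right[i] = remap[d["no"]]
    return Tree(feature, threshold, left, right, value, weight)


def train_boosted(
    features,
    labels,
    n_estimators: int = 100,
    max_depth: int = 6,
    learning_rate: float = 0.1,
    subsample: float = 1.0,
    colsample: float = 1.0,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> TreeEnsemble:
    """Gradient-boosted trees under the binary logistic loss (xgboost),
    exported to the neutral structure with margin aggregation.

    The per-round training log-loss trace is attached as ``train_trace``.
    """
    import xgboost as xgb

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input")
    clf = xgb.XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        subsample=subsample,
        colsample_bytree=colsample,
        objective="binary:logistic",
        base_score=0.5,
        random_state=seed,
        eval_metric="logloss",
        tree_method="exact",
        n_jobs=1,
    )
    clf.fit(X, y, eval_set=[(X, y)], verbose=False)
    trace = [float(v) for v in clf.evals_result()["validation_0"]["logloss"]]
    dumps = clf.get_booster().get_dump(dump_format="json", with_stats=True)
    trees = [_export_xgb_tree(json.loads(d)) for d in dumps]
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return TreeEnsemble(
        trees=trees,
        aggregation="logit_sum",
        feature_names=names,
        base_margin=0.0,  # logit(base_score=0.5)
        train_trace=trace,
    )


def ensemble_predict(e: TreeEnsemble, x) -> np.ndarray:
    """Per-head scores for one vector or a batch (thin wrapper)."""
    return e.predict(x)
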