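"""Expression preprocessing: log transform, per-gene z-scoring, gene-ID
harmonization, ComBat batch correction, response binarization, and SMOTE.

The central container is :class:`ExpressionMatrix`, a samples x genes frame
tagged with a gene-ID namespace and a normalization state that may only
advance ``raw_tpm -> log_tpm -> zscored``. Numeric steps are also exposed as
sklearn-style transformers so they compose with pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ExpressionMatrix",
    "log_transform",
    "zscore_genes",
    "harmonize_genes",
    "combat_correct",
    "binarize_response",
    "smote_oversample",
    "Log2Transformer",
    "GeneZScorer",
    "SMOTESampler",
    "ComBat",
]

_STATES = ("raw_tpm", "log_tpm", "zscored")


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with provenance tags.

    Invariants: unique sample IDs, finite values, and a state that only
    moves forward along raw_tpm -> log_tpm -> zscored.
    """

    values: pd.DataFrame
    namespace: str = "symbol"  # "symbol" | "ensembl"
    state: str = "raw_tpm"

    def __post_init__(self):
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.namespace not in {"symbol", "ensembl"}:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.columns]

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def _advance(self, values: pd.DataFrame, state: str) -> "ExpressionMatrix":
        if _STATES.index(state) < _STATES.index(self.state):
            raise ValueError(f"state cannot move back from {self.state} to {state}")
        return replace(self, values=values, state=state)


# --------------------------------------------------------------------------
# sklearn-style transformers
# --------------------------------------------------------------------------
class Log2Transformer(BaseEstimator, TransformerMixin):
    """x -> log2(x + 1); the standard TPM compression."""

    def fit(self, X, y=None):
        X = check_array(X)
        if (X < 0).any():
            raise ValueError("log2(x+1) requires non-negative input")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if (X < 0).any():
            raise ValueError("log2(x+1) requires non-negative input")
        return np.log2(X + 1.0)


class GeneZScorer(BaseEstimator, TransformerMixin):
    """Per-gene standardization z = (x - mu) / (sigma + eps).

    Population standard deviation; the additive ``eps`` guards constant
    genes, which map to exactly zero.
    """

    def __init__(self, eps: float = 1e-8):
        self.eps = eps

    def fit(self, X, y=None):
        X = check_array(X)
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if X.shape[0] < 2:
            raise ValueError("z-scoring needs at least 2 samples")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0) + self.eps
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return (X - self.mean_) / self.scale_


class SMOTESampler(BaseEstimator):
    """Synthetic minority oversampling: x_new = x + u (x_nn - x), u~U(0,1),
    x_nn one of the k nearest minority neighbours by Euclidean distance.

    ``k_neighbors`` is clipped to (minority size - 1) for tiny classes.
    Originals are preserved; classes are balanced exactly.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = check_array(X)
        y = np.asarray(y)
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE here handles binary labels only")
        minority = classes[np.argmin(counts)]
        n_min, n_maj = counts.min(), counts.max()
        n_new = n_maj - n_min
        if n_new == 0:
            return X.copy(), y.copy()
        if n_min < 2:
            raise ValueError("minority class needs >= 2 samples")
        k = min(self.k_neighbors, n_min - 1)
        Xm = X[y == minority]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
        rng = np.random.default_rng(self.random_state)
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(0, k, size=n_new)
        u = rng.uniform(0.0, 1.0, size=n_new)
        neigh = idx[base, pick + 1]
        X_new = Xm[base] + u[:, None] * (Xm[neigh] - Xm[base])
        X_out = np.vstack([X, X_new])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


class ComBat(BaseEstimator):
    """Location/scale batch correction under the additive-multiplicative
    model x_ij = alpha_j + beta_bj + gamma_bj * eps_ij, with parametric
    empirical-Bayes shrinkage of the per-batch effects across genes
    (normal prior on locations, inverse-gamma on scales).

    ``parametric_eb=False`` skips shrinkage and removes the raw per-batch
    location/scale estimates (also the fallback for very few genes, where
    moment-based hyperpriors are unstable).
    """

    def __init__(self, parametric_eb: bool = True, max_iter: int = 100, tol: float = 1e-8):
        self.parametric_eb = parametric_eb
        self.max_iter = max_iter
        self.tol = tol

    def fit_transform(self, X, batches):
        X = check_array(X)
        batches = np.asarray(batches)
        if len(batches) != X.shape[0]:
            raise ValueError("one batch label per sample required")
        levels, inverse = np.unique(batches, return_inverse=True)
        if len(levels) == 1:
            return X.copy()
        n_b = np.bincount(inverse)
        if (n_b < 2).any():
            raise ValueError("every batch needs >= 2 samples for scale correction")
        N, G = X.shape
        B = len(levels)

        batch_mean = np.vstack([X[inverse == b].mean(axis=0) for b in range(B)])
        stand_mean = (n_b[:, None] / N * batch_mean).sum(axis=0)
        resid = X - batch_mean[inverse]
        var_pooled = (resid**2).sum(axis=0) / N
        var_pooled = np.maximum(var_pooled, 1e-12)
        sd = np.sqrt(var_pooled)
        Z = (X - stand_mean) / sd

        gamma_hat = np.vstack([Z[inverse == b].mean(axis=0) for b in range(B)])
        delta_hat = np.vstack([Z[inverse == b].var(axis=0, ddof=1) for b in range(B)])
        delta_hat = np.maximum(delta_hat, 1e-12)

        use_eb = self.parametric_eb and G >= 5
        if use_eb:
            gamma_star, delta_star = self._eb_shrink(Z, inverse, n_b, gamma_hat, delta_hat)
        else:
            gamma_star, delta_star = gamma_hat, delta_hat

        Z_adj = (Z - gamma_star[inverse]) / np.sqrt(delta_star[inverse])
        return Z_adj * sd + stand_mean

    def _eb_shrink(self, Z, inverse, n_b, gamma_hat, delta_hat):
        B, G = gamma_hat.shape
        gamma_bar = gamma_hat.mean(axis=1)
        t2 = gamma_hat.var(axis=1, ddof=1)
        d_mean = delta_hat.mean(axis=1)
        d_var = delta_hat.var(axis=1, ddof=1)
        # inverse-gamma hyperpriors by moment matching
        a_prior = (2 * d_var + d_mean**2) / np.maximum(d_var, 1e-12)
        b_prior = (d_mean * d_var + d_mean**3) / np.maximum(d_var, 1e-12)

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for b in range(B):
            Zb = Z[inverse == b]
            n = n_b[b]
            g, d = gamma_hat[b].copy(), delta_hat[b].copy()
            for _ in range(self.max_iter):
                g_new = (n * t2[b] * gamma_hat[b] + d * gamma_bar[b]) / (n * t2[b] + d)
                sse = ((Zb - g_new) ** 2).sum(axis=0)
                d_new = (b_prior[b] + 0.5 * sse) / (n / 2 + a_prior[b] - 1)
                change = max(np.abs(g_new - g).max(), np.abs(d_new - d).max())
                g, d = g_new, d_new
                if change < self.tol:
                    break
            gamma_star[b], delta_star[b] = g, np.maximum(d, 1e-12)
        return gamma_star, delta_star


# --------------------------------------------------------------------------
# ExpressionMatrix-level operations
# --------------------------------------------------------------------------
def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) compression; raw_tpm -> log_tpm."""
    if m.state != "raw_tpm":
        raise ValueError(f"log_transform expects raw_tpm input, got {m.state}")
    t = Log2Transformer().fit(m.X)
    values = pd.DataFrame(t.transform(m.X), index=m.values.index, columns=m.values.columns)
    return m._advance(values, "log_tpm")


def zscore_genes(m: ExpressionMatrix, eps: float = 1e-8) -> ExpressionMatrix:
    """Per-gene standardization with sigma + eps denominator; log_tpm -> zscored."""
    if m.state != "log_tpm":
        raise ValueError(f"zscore_genes expects log_tpm input, got {m.state}")
    z = GeneZScorer(eps=eps).fit(m.X)
    values = pd.DataFrame(z.transform(m.X), index=m.values.index, columns=m.values.columns)
    return m._advance(values, "zscored")


def harmonize_genes(
    m: ExpressionMatrix,
    mapping: pd.DataFrame,
    target_gene_order: list[str],
    target_namespace: str = "symbol",
) -> ExpressionMatrix:
    """Convert gene IDs to the target namespace, average duplicates,
    zero-impute missing genes, and reorder columns to ``target_gene_order``.

    Ensembl IDs are matched with version suffixes stripped. Genes without a
    mapping entry are dropped (they cannot be expressed in the target
    namespace).
    """
    if m.namespace == target_namespace:
        renamed = m.values.copy()
    else:
        if m.namespace == "ensembl":
            lut = dict(zip(mapping["ensembl"], mapping["symbol"]))
            keys = [str(g).split(".")[0] for g in m.gene_ids]
        else:
            lut = dict(zip(mapping["symbol"], mapping["ensembl"]))
            keys = [str(g) for g in m.gene_ids]
        keep = [i for i, k in enumerate(keys) if k in lut]
        if not keep:
            raise ValueError("gene mapping covers no gene of the matrix")
        renamed = m.values.iloc[:, keep].copy()
        renamed.columns = [lut[keys[i]] for i in keep]
    collapsed = renamed.T.groupby(level=0).mean().T
    present = [g for g in target_gene_order if g in collapsed.columns]
    if not present:
        raise ValueError("no overlap between matrix genes and target gene order")
    out = collapsed.reindex(columns=target_gene_order, fill_value=0.0)
    return replace(m, values=out, namespace=target_namespace)


def combat_correct(
    m: ExpressionMatrix,
    batches,
    parametric_eb: bool = True,
) -> ExpressionMatrix:
    """Remove per-gene location/scale batch effects; state unchanged."""
    if m.state == "raw_tpm":
        raise ValueError("ComBat runs on log_tpm or zscored data")
    if isinstance(batches, dict):
        batches = [batches[s] for s in m.sample_ids]
    corrected = ComBat(parametric_eb=parametric_eb).fit_transform(m.X, batches)
    values = pd.DataFrame(corrected, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values)


def binarize_response(table: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Label records sensitive when auc <= threshold, resistant otherwise."""
    auc = table["auc"].to_numpy(dtype=float)
    if np.isnan(auc).any():
        raise ValueError("all auc values must be set")
    if ((auc < 0) | (auc > 1)).any():
        raise ValueError("auc metric must lie in [0, 1]")
    out = table.copy()
    out["label"] = np.where(auc <= threshold, "sensitive", "resistant")
    return out


def smote_oversample(features, labels, k: int = 5, seed: int = 0):
    """Balance binary classes by SMOTE interpolation; thin wrapper."""
    return SMOTESampler(k_neighbors=k, random_state=seed).fit_resample(features, labels)
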