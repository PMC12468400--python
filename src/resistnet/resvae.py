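"""Residual variational autoencoder with dual sensitivity/resistance heads.

The model couples three parts on a shared latent space:

* an encoder of residual MLP blocks producing the posterior (mu, log sigma^2),
* a mirrored decoder reconstructing the (z-scored) expression input, and
* a linear two-logit classification head (index 0 = sensitive,
  index 1 = resistant, softmax-coupled).

Training minimizes ``L_CE + beta*L_REC + L_KLD (+ theta*L_COD)`` jointly by
AdamW, where L_REC is mean squared reconstruction error, L_KLD the Gaussian
KL to the standard-normal prior, and L_COD a cosine distillation loss
aligning the student latent with a frozen teacher's. The composite
``L_total = beta*L_REC + L_KLD + theta*L_COD`` is logged per epoch next to
its parts, so the decomposition is checkable to machine precision.

Defaults suit full-scale expression input (batch_size 128 for raw
expression input, learning_rate 2e-5, weight_decay 3e-3, 150 epochs,
beta = 1000); desk-scale fixtures use smaller widths and fewer epochs via
the same config type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax as _softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .autodiff import Tensor
from .metrics import MetricBundle, metric_bundle

__all__ = [
    "ResVAEConfig",
    "ResVAEClassifier",
    "cross_entropy",
    "kld_gaussian",
    "cod_loss",
    "latent_augment",
    "crossval_train",
    "save_checkpoint",
    "load_checkpoint",
]

CLASS_ORDER = ("sensitive", "resistant")
CHECKPOINT_SCHEMA = "resistnet-resvae-1"
_LOGVAR_RANGE = (-10.0, 10.0)


# --------------------------------------------------------------------------
# loss primitives (numpy closed forms, shared with the training graph)
# --------------------------------------------------------------------------
def cross_entropy(p, y, floor: float = 1e-12):
    """Multi-class cross entropy -(1/N) sum_i sum_k y_ik log p_ik.

    Probabilities where the true class has p=0 are clamped at ``floor``;
    the returned report flags whether clamping occurred.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    clamped = bool((p[y > 0] < floor).any())
    val = -(y * np.log(np.maximum(p, floor))).sum(axis=1).mean()
    return float(val), clamped


def kld_gaussian(mu, log_var) -> float:
    """KL( N(mu, sigma^2) || N(0, I) ), summed over dimensions, averaged
    over samples."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=float))
    kl = -0.5 * (1.0 + log_var - mu**2 - np.exp(log_var)).sum(axis=1)
    return float(kl.mean())


def cod_loss(f_T, f_S) -> float:
    """Cosine distillation 1 - cos(f_T, f_S), averaged over rows."""
    f_T = np.atleast_2d(np.asarray(f_T, dtype=float))
    f_S = np.atleast_2d(np.asarray(f_S, dtype=float))
    nT = np.linalg.norm(f_T, axis=1)
    nS = np.linalg.norm(f_S, axis=1)
    if (nT == 0).any() or (nS == 0).any():
        raise ValueError("cosine distillation undefined for zero vectors")
    cos = (f_T * f_S).sum(axis=1) / (nT * nS)
    return float((1.0 - cos).mean())


@dataclass(frozen=True)
class ResVAEConfig:
    hidden_dims: tuple[int, ...] = (512, 128)
    latent_dim: int = 32
    batch_size: int = 128
    learning_rate: float = 2e-5
    weight_decay: float = 3e-3
    num_epochs: int = 150
    beta: float = 1000.0
    theta: float = 0.0
    seed: int = 0

    def validate(self, input_dim: int) -> None:
        if self.latent_dim >= input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        if self.beta < 0 or self.theta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.num_epochs < 1 or self.batch_size < 1:
            raise ValueError("num_epochs and batch_size must be positive")


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------
class ResVAEClassifier(BaseEstimator, ClassifierMixin):
    """Res-VAE with dual heads, sklearn-style.

    Parameters mirror :class:`ResVAEConfig`; ``teacher`` is an optional
    trained ResVAEClassifier whose latent means act as distillation
    targets (weighted by ``theta``).

    Fitted attributes: ``params_`` (name -> array), ``history_`` (list of
    per-epoch loss dicts), ``feature_names_``, ``classes_``.
    """

    def __init__(
        self,
        hidden_dims=(512, 128),
        latent_dim=32,
        batch_size=128,
        learning_rate=2e-5,
        weight_decay=3e-3,
        num_epochs=150,
        beta=1000.0,
        theta=0.0,
        seed=0,
        teacher=None,
    ):
        self.hidden_dims = hidden_dims
        self.latent_dim = latent_dim
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.num_epochs = num_epochs
        self.beta = beta
        self.theta = theta
        self.seed = seed
        self.teacher = teacher

    # ------------------------------------------------------------ plumbing
    @property
    def config(self) -> ResVAEConfig:
        return ResVAEConfig(
            hidden_dims=tuple(self.hidden_dims),
            latent_dim=self.latent_dim,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            num_epochs=self.num_epochs,
            beta=self.beta,
            theta=self.theta,
            seed=self.seed,
        )

    @staticmethod
    def _coerce_X(X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        return X, [f"f{i}" for i in range(X.shape[1])]

    @staticmethod
    def _coerce_y(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UOS":
            bad = set(np.unique(y)) - set(CLASS_ORDER)
            if bad:
                raise ValueError(f"unknown labels {sorted(bad)}")
            return (y == "resistant").astype(int)
        return y.astype(int)

    def _init_params(self, input_dim: int, rng: np.random.Generator) -> dict:
        dims = [input_dim, *self.hidden_dims]
        p: dict[str, np.ndarray] = {}

        def lin(name, d_in, d_out, scale=1.0):
            p[f"{name}_W"] = scale * rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
            p[f"{name}_b"] = np.zeros(d_out)

        # linear trunk with residual MLP blocks: the identity/linear path is
        # preserved end-to-end, the blocks add nonlinear corrections (their
        # output layers start small so training begins near the linear map)
        lin("enc_in", dims[0], dims[1])
        for k in range(1, len(self.hidden_dims)):
            w_in, w_out = dims[k], dims[k + 1]
            lin(f"enc_res{k}_l1", w_in, w_out)
            lin(f"enc_res{k}_l2", w_out, w_out, scale=0.1)
            if w_in != w_out:
                lin(f"enc_res{k}_proj", w_in, w_out)
        lin("enc_mu", dims[-1], self.latent_dim)
        lin("enc_lv", dims[-1], self.latent_dim)
        p["enc_lv_b"] -= 1.0  # start with modest posterior variance

        rdims = [self.latent_dim, *reversed(self.hidden_dims)]
        lin("dec_in", rdims[0], rdims[1])
        for k in range(1, len(self.hidden_dims)):
            w_in, w_out = rdims[k], rdims[k + 1]
            lin(f"dec_res{k}_l1", w_in, w_out)
            lin(f"dec_res{k}_l2", w_out, w_out, scale=0.1)
            if w_in != w_out:
                lin(f"dec_res{k}_proj", w_in, w_out)
        lin("dec_out", rdims[-1], input_dim)
        lin("head", self.latent_dim, 2)
        return p

    @staticmethod
    def _resblock(t: dict, prefix: str, h: Tensor) -> Tensor:
        inner = (h @ t[f"{prefix}_l1_W"] + t[f"{prefix}_l1_b"]).relu()
        out = inner @ t[f"{prefix}_l2_W"] + t[f"{prefix}_l2_b"]
        skip = h @ t[f"{prefix}_proj_W"] + t[f"{prefix}_proj_b"] if f"{prefix}_proj_W" in t else h
        return out + skip

    def _encode_graph(self, t: dict, x: Tensor):
        h = x @ t["enc_in_W"] + t["enc_in_b"]
        for k in range(1, len(self.hidden_dims)):
            h = self._resblock(t, f"enc_res{k}", h)
        mu = h @ t["enc_mu_W"] + t["enc_mu_b"]
        logvar = (h @ t["enc_lv_W"] + t["enc_lv_b"]).clip(*_LOGVAR_RANGE)
        return mu, logvar

    def _decode_graph(self, t: dict, z: Tensor) -> Tensor:
        h = z @ t["dec_in_W"] + t["dec_in_b"]
        for k in range(1, len(self.hidden_dims)):
            h = self._resblock(t, f"dec_res{k}", h)
        return h @ t["dec_out_W"] + t["dec_out_b"]

    def _tensors(self, requires_grad: bool) -> dict:
        return {k: Tensor(v, requires_grad=requires_grad) for k, v in self.params_.items()}

    # ----------------------------------------------------------------- fit
    def fit(self, X, y, sample_weight=None):
        X, feature_names = self._coerce_X(X)
        y01 = self._coerce_y(y)
        cfg = self.config
        cfg.validate(X.shape[1])
        if self.teacher is not None and self.theta > 0:
            check_is_fitted(self.teacher)
            if self.teacher.latent_dim != self.latent_dim:
                raise ValueError("teacher latent_dim must match the student's")

        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(X.shape[1], rng)
        self.feature_names_ = feature_names
        self.classes_ = np.array([0, 1])
        self.class_names_ = CLASS_ORDER
        self.history_: list[dict] = []

        Y = np.eye(2)[y01]
        n = X.shape[0]
        adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        step = 0
        distill = self.teacher is not None and self.theta > 0
        f_T_all = self.teacher.encode(X)[0] if distill else None

        for epoch in range(self.num_epochs):
            order = rng.permutation(n)
            sums = {"L_CE": 0.0, "L_REC": 0.0, "L_KLD": 0.0, "L_COD": 0.0}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                t = self._tensors(requires_grad=True)
                xb = Tensor(X[idx])
                yb = Tensor(Y[idx])
                mu, logvar = self._encode_graph(t, xb)
                eps = Tensor(rng.standard_normal(mu.shape))
                z = mu + (logvar * 0.5).exp() * eps
                xhat = self._decode_graph(t, z)
                # heads read the latent mean; the sampled z feeds the decoder
                logits = mu @ t["head_W"] + t["head_b"]

                logp = logits.log_softmax()
                ce = -(yb * logp).sum(axis=1).mean()
                rec = (xhat - xb).square().mean()
                kld = ((mu.square() + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()
                loss = ce + self.beta * rec + kld
                cod_val = 0.0
                if distill:
                    fT = Tensor(f_T_all[idx])
                    norm_prod = (
                        fT.square().sum(axis=1).sqrt() * mu.square().sum(axis=1).sqrt()
                    )
                    cos = (fT * mu).sum(axis=1) / (norm_prod + 1e-12)
                    cod = (1.0 - cos).mean()
                    loss = loss + self.theta * cod
                    cod_val = float(cod.data)

                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                loss.backward()
                step += 1
                self._adamw_step(t, adam_m, adam_v, step)

                sums["L_CE"] += float(ce.data)
                sums["L_REC"] += float(rec.data)
                sums["L_KLD"] += float(kld.data)
                sums["L_COD"] += cod_val
                n_batches += 1

            report = {k: v / n_batches for k, v in sums.items()}
            report["L_total"] = (
                self.beta * report["L_REC"]
                + report["L_KLD"]
                + self.theta * report["L_COD"]
            )
            report["objective"] = report["L_CE"] + report["L_total"]
            report["epoch"] = epoch
            self.history_.append(report)
        return self

    def _adamw_step(self, t: dict, m: dict, v: dict, step: int, b1=0.9, b2=0.999, eps=1e-8):
        lr = self.learning_rate
        for k, tensor in t.items():
            g = tensor.grad
            if g is None:
                continue
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1**step)
            vhat = v[k] / (1 - b2**step)
            upd = mhat / (np.sqrt(vhat) + eps)
            if k.endswith("_W"):  # decoupled weight decay on weights only
                upd = upd + self.weight_decay * self.params_[k]
            self.params_[k] = self.params_[k] - lr * upd
        # refresh tensor views is unnecessary: tensors are rebuilt per batch

    # ----------------------------------------------------------- inference
    def encode(self, X):
        """Posterior (mu, log sigma^2) of the latent, eval mode."""
        check_is_fitted(self)
        X, _ = self._coerce_X(X)
        t = self._tensors(requires_grad=False)
        mu, logvar = self._encode_graph(t, Tensor(X))
        return mu.data, logvar.data

    def decode(self, Z):
        check_is_fitted(self)
        t = self._tensors(requires_grad=False)
        return self._decode_graph(t, Tensor(np.asarray(Z, dtype=float))).data

    def decision_function(self, X):
        """Two-column logits (sensitive, resistant) from the latent mean."""
        check_is_fitted(self)
        X, _ = self._coerce_X(X)
        t = self._tensors(requires_grad=False)
        mu, _ = self._encode_graph(t, Tensor(X))
        logits = mu @ Tensor(self.params_["head_W"]) + Tensor(self.params_["head_b"])
        return logits.data

    def predict_proba(self, X):
        return _softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def predict_heads(self, X):
        """(p_sensitive, p_resistant, logits) per sample."""
        logits = self.decision_function(X)
        p = _softmax(logits, axis=1)
        return p[:, 0], p[:, 1], logits

    def head_logit_and_grad(self, X, head: int):
        """Value and input-gradient of one head's pre-softmax logit.

        The attribution target: F_head(x) evaluated at the latent mean.
        Returns (values (n,), grads (n, p)).
        """
        check_is_fitted(self)
        X, _ = self._coerce_X(X)
        t = self._tensors(requires_grad=False)
        x = Tensor(X, requires_grad=True)
        mu, _ = self._encode_graph(t, x)
        logits = mu @ Tensor(self.params_["head_W"]) + Tensor(self.params_["head_b"])
        sel = np.zeros((2, 1))
        sel[head, 0] = 1.0
        f = logits @ Tensor(sel)
        f.sum().backward()
        return f.data[:, 0], x.grad

    def score(self, X, y):
        return float(np.mean(self.predict(X) == self._coerce_y(y)))


# --------------------------------------------------------------------------
# latent-space augmentation
# --------------------------------------------------------------------------
def latent_augment(model: ResVAEClassifier, X, y, per_class_target: int, seed: int = 0,
                   sigma_scale: float = 1.0):
    """Oversample under-represented classes in latent space.

    Each under-target class is topped up by encoding its members, drawing
    new latents from the per-sample posterior N(mu, (sigma_scale*sigma)^2),
    and decoding back to feature rows.
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    out_X, out_y = [X], [y]
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        need = per_class_target - len(rows)
        if need <= 0:
            continue
        if len(rows) == 0:
            raise ValueError("cannot augment an empty class")
        mu, logvar = model.encode(X[rows])
        sd = np.exp(0.5 * logvar) * sigma_scale
        pick = rng.integers(0, len(rows), size=need)
        z = mu[pick] + sd[pick] * rng.standard_normal((need, mu.shape[1]))
        out_X.append(model.decode(z))
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


# --------------------------------------------------------------------------
# cross-validation harness
# --------------------------------------------------------------------------
def crossval_train(X, y, cfg: ResVAEConfig | ResVAEClassifier, n_folds: int = 5,
                   seed: int | None = None, teacher=None):
    """Stratified k-fold training; returns (fold_metrics, best_model).

    The checkpoint kept is the fold with the highest validation ROC-AUC.
    Fold membership is seeded and train/validation sets are disjoint by
    construction (asserted).
    """
    if isinstance(cfg, ResVAEClassifier):
        base = cfg
    else:
        base = ResVAEClassifier(**asdict(cfg))
    Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y01 = ResVAEClassifier._coerce_y(y)
    seed = base.seed if seed is None else seed
    counts = np.bincount(y01, minlength=2)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds samples")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_metrics: list[MetricBundle] = []
    best_model, best_auc = None, -np.inf
    for fold, (tr, va) in enumerate(skf.split(Xarr, y01)):
        assert not set(tr) & set(va)
        if len(np.unique(y01[va])) < 2 or len(np.unique(y01[tr])) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        model = ResVAEClassifier(**base.get_params())
        model.set_params(seed=seed + fold, teacher=teacher)
        model.fit(Xarr[tr], y01[tr])
        scores = model.predict_proba(Xarr[va])[:, 1]
        mb = metric_bundle(y01[va], scores)
        fold_metrics.append(mb)
        if mb.auc > best_auc:
            best_auc, best_model = mb.auc, model
    return fold_metrics, best_model


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------
def save_checkpoint(model: ResVAEClassifier, path: str | Path) -> None:
    """JSON checkpoint: schema id, config, class convention, gene order,
    parameters, and training history. Floats round-trip bit-exactly."""
    check_is_fitted(model)
    payload = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "class_order": list(CLASS_ORDER),
        "feature_names": model.feature_names_,
        "params": {k: v.tolist() for k, v in model.params_.items()},
        "history": model.history_,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> ResVAEClassifier:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unknown checkpoint schema {payload.get('schema')!r}")
    cfg = payload["config"]
    model = ResVAEClassifier(**{**cfg, "hidden_dims": tuple(cfg["hidden_dims"])})
    model.params_ = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    model.feature_names_ = payload["feature_names"]
    model.classes_ = np.array([0, 1])
    model.class_names_ = CLASS_ORDER
    model.history_ = payload["history"]
    return model
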