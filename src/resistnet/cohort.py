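"""Synthetic cohorts with planted ground truth.

Emulates what the real inputs provide — a bulk expression matrix with batch
structure, a continuous drug-response metric binarizable at 0.5, and
survival outcomes — while planting the quantities downstream stages must
recover: a sparse set of label-driving genes under a logistic link and
survival times from a proportional-hazards model with known coefficients.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .preprocess import ExpressionMatrix

__all__ = [
    "CohortSpec",
    "simulate_expression",
    "simulate_labels",
    "simulate_survival",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    ``effect_size`` is the logistic coefficient on the standardized sum of
    causal-gene expression; ``cox_beta`` holds log-hazard coefficients
    applied to the first ``len(cox_beta)`` causal genes.
    """

    n_samples: int = 1000
    n_genes: int = 200
    n_causal: int = 10
    effect_size: float = 3.0
    resistant_fraction: float = 0.35
    n_batches: int = 2
    batch_shift_sd: float = 0.3
    cox_beta: tuple[float, ...] = (0.8, 0.8)
    censor_rate: float = 0.2
    baseline_hazard: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal cannot exceed n_genes")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0.0 < self.resistant_fraction < 1.0:
            raise ValueError("resistant_fraction must lie in (0, 1)")
        if len(self.cox_beta) > max(self.n_causal, 1):
            raise ValueError("cox_beta longer than the causal gene set")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_expression(spec: CohortSpec):
    """Draw a log-scale expression matrix with additive batch shifts.

    Returns ``(ExpressionMatrix(state=log_tpm), causal_gene_ids, batch_labels)``.
    Per gene: x_ij = mu_j + shift_{b(i),j} + N(0,1), with per-batch,
    per-gene shifts of sd ``batch_shift_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    samples = [f"S{i:05d}" for i in range(spec.n_samples)]
    mu = rng.normal(0.0, 1.0, size=spec.n_genes)
    batch_labels = rng.integers(0, spec.n_batches, size=spec.n_samples)
    shifts = rng.normal(0.0, spec.batch_shift_sd, size=(spec.n_batches, spec.n_genes))
    X = mu + shifts[batch_labels] + rng.normal(0.0, 1.0, size=(spec.n_samples, spec.n_genes))
    causal = sorted(rng.choice(genes, size=spec.n_causal, replace=False).tolist())
    m = ExpressionMatrix(
        pd.DataFrame(X, index=samples, columns=genes), namespace="symbol", state="log_tpm"
    )
    return m, causal, np.array([f"batch{b}" for b in batch_labels])


def simulate_labels(
    m: ExpressionMatrix,
    causal_gene_ids: list[str],
    effect_size: float,
    seed: int,
    resistant_fraction: float = 0.35,
    drug: str = "drugA",
) -> pd.DataFrame:
    """Bernoulli resistance labels under a logistic link on causal genes.

    P(resistant | x) = expit(effect_size * s - offset), where s is the
    standardized sum of causal-gene expression and the offset is solved so
    the expected resistant fraction matches the target. The continuous auc
    metric is back-filled consistently with the drawn label so that
    thresholding at 0.5 reproduces it: sensitive -> 0.5*p, resistant ->
    0.5 + 0.5*p (both increasing in p).
    """
    rng = np.random.default_rng(seed)
    if causal_gene_ids:
        missing = set(causal_gene_ids) - set(m.gene_ids)
        if missing:
            raise ValueError(f"causal genes absent from matrix: {sorted(missing)[:5]}")
        s = m.values[causal_gene_ids].sum(axis=1).to_numpy()
        sd = s.std()
        s = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    else:
        s = np.zeros(len(m.sample_ids))

    def mean_p(offset):
        return expit(effect_size * s - offset).mean() - resistant_fraction

    offset = brentq(mean_p, -50.0, 50.0)
    p = expit(effect_size * s - offset)
    resistant = rng.uniform(size=len(p)) < p
    auc = np.where(resistant, 0.5 + 0.5 * p, 0.5 * p)
    return pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "drug": drug,
            "auc": auc,
            "label": np.where(resistant, "resistant", "sensitive"),
            "p_resistant": p,
        }
    )


def simulate_survival(
    m: ExpressionMatrix,
    cox_beta: dict[str, float],
    censor_rate: float,
    seed: int,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Event times from an exponential baseline scaled by exp(beta' x),
    with independent exponential censoring calibrated to ``censor_rate``.
    """
    rng = np.random.default_rng(seed)
    n = len(m.sample_ids)
    lp = np.zeros(n)
    for g, b in cox_beta.items():
        if g not in m.gene_ids:
            raise ValueError(f"cox_beta gene {g!r} absent from matrix")
        lp += b * m.values[g].to_numpy()
    rate = baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        # choose the censoring rate c so that mean_i c/(c + rate_i) hits the target
        def frac(c):
            return (c / (c + rate)).mean() - censor_rate

        c = brentq(frac, 1e-12, 1e12)
        C = rng.exponential(1.0 / c, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return pd.DataFrame({"sample_id": m.sample_ids, "time": time, "event": event})


def simulate_cohort(spec: CohortSpec) -> dict:
    """Full cohort: expression, response, survival, and the planted truth.

    Seeds for the three stages are derived from ``spec.seed`` so the cohort
    is reproducible as a whole.
    """
    m, causal, batches = simulate_expression(spec)
    ss = np.random.SeedSequence(spec.seed)
    label_seed, surv_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    response = simulate_labels(
        m, causal, spec.effect_size, label_seed, spec.resistant_fraction
    )
    cox_beta = {g: b for g, b in zip(causal, spec.cox_beta)}
    survival = simulate_survival(
        m, cox_beta, spec.censor_rate, surv_seed, spec.baseline_hazard
    )
    truth = {
        "causal_genes": causal,
        "cox_beta": cox_beta,
        "effect_size": spec.effect_size,
        "resistant_fraction": spec.resistant_fraction,
    }
    return {
        "expression": m,
        "response": response,
        "survival": survival,
        "batches": batches,
        "truth": truth,
        "spec": spec,
    }


def write_cohort(cohort: dict, out_dir: str | Path) -> None:
    """Write expression TSV, response CSV, survival CSV, and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort["expression"].values.to_csv(out / "expression.tsv", sep="\t")
    cohort["response"].drop(columns=["p_resistant"], errors="ignore").to_csv(
        out / "response.csv", index=False
    )
    cohort["survival"].to_csv(out / "survival.csv", index=False)
    pd.DataFrame({"sample_id": cohort["expression"].sample_ids, "batch": cohort["batches"]}).to_csv(
        out / "batches.csv", index=False
    )
    truth = dict(cohort["truth"])
    truth["spec"] = asdict(cohort["spec"])
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
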