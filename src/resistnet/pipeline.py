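"""End-to-end orchestration: simulate/ingest -> preprocess -> cross-validated
training -> attribution -> ranking -> (enrichment) -> survival.

Configuration is a single mapping (or YAML file) with one section per stage;
the seed must be explicit — an unset seed is a validation error, not a
default. Every run writes versioned stage outputs plus a machine-readable
manifest (seed, config hash, stage timings) into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .attribution import (
    compare_rankings,
    gradient_shap,
    integrated_gradients,
    ora_enrich,
    rank_genes,
    tree_shap,
)
from .cohort import CohortSpec, simulate_cohort, write_cohort
from .metrics import metric_bundle
from .preprocess import (
    binarize_response,
    combat_correct,
    log_transform,
    smote_oversample,
    zscore_genes,
)
from .resvae import ResVAEClassifier, crossval_train, save_checkpoint
from .survival import (
    fit_cox,
    kaplan_meier,
    log_rank,
    median_split,
    risk_scores,
    schoenfeld_check,
    td_auc,
)
from .trees import train_forest

__all__ = ["run_pipeline", "load_config", "DESK_RESVAE"]

# Desk-scale Res-VAE configuration used by the bundled demo: narrow linear
# trunk with one residual block, strong decoupled weight decay against
# latent memorization at n << p.
DESK_RESVAE = {
    "hidden_dims": (32, 32),
    "latent_dim": 8,
    "batch_size": 64,
    "learning_rate": 1e-3,
    "weight_decay": 1.0,
    "num_epochs": 150,
    "beta": 1.0,
    "theta": 0.0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        return yaml.safe_load(Path(source).read_text())
    return dict(source)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _validate(cfg: dict) -> None:
    if "seed" not in cfg:
        raise PipelineError("validate", "config must set an explicit seed")
    stages = cfg.get("stages", ["simulate", "preprocess", "train", "attribute", "rank", "survival"])
    if "simulate" not in cfg and "inputs" not in cfg:
        raise PipelineError("validate", "either a simulate section or an inputs section is required")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        if "expression" not in inputs:
            raise PipelineError("validate", "inputs.expression is required")
        if "survival" in stages and "simulate" not in cfg and "survival" not in inputs:
            raise PipelineError("validate", "survival stage requested but no survival table given")
        for key, path in inputs.items():
            if not Path(path).exists():
                raise PipelineError("validate", f"missing input file for {key}: {path}")


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the run manifest."""
    cfg = load_config(config)
    _validate(cfg)
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg.get("out_dir", "resistnet_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", ["simulate", "preprocess", "train", "attribute", "rank", "survival"])
    manifest: dict = {"seed": seed, "config_hash": _config_hash(cfg), "stages": {}}
    state: dict = {}

    def record(stage, t0, **info):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    # ---------------------------------------------------- simulate / ingest
    t0 = time.time()
    try:
        if "simulate" in cfg:
            spec = CohortSpec(**{**cfg["simulate"], "seed": seed})
            cohort = simulate_cohort(spec)
            write_cohort(cohort, out / "cohort")
            state["expression"] = cohort["expression"]
            state["response"] = cohort["response"]
            state["survival"] = cohort["survival"]
            state["batches"] = cohort["batches"]
            state["truth"] = cohort["truth"]
            record("simulate", t0, n_samples=spec.n_samples, n_genes=spec.n_genes)
        else:
            inputs = cfg["inputs"]
            state["expression"] = rio.read_expression(inputs["expression"])
            if "response" in inputs:
                state["response"] = rio.read_response(inputs["response"])
            if "survival" in inputs:
                state["survival"] = rio.read_survival(inputs["survival"])
            if "batches" in inputs:
                b = pd.read_csv(inputs["batches"])
                state["batches"] = b.set_index("sample_id")["batch"].reindex(
                    state["expression"].sample_ids
                ).to_numpy()
            record("ingest", t0, n_samples=len(state["expression"].sample_ids))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    # ------------------------------------------------------------ preprocess
    if "preprocess" in stages:
        t0 = time.time()
        try:
            pp = cfg.get("preprocess", {})
            m = state["expression"]
            if pp.get("log2", m.state == "raw_tpm") and m.state == "raw_tpm":
                m = log_transform(m)
            if pp.get("zscore", True) and m.state == "log_tpm":
                m = zscore_genes(m, eps=pp.get("eps", 1e-8))
            if pp.get("combat", False):
                if "batches" not in state:
                    raise ValueError("combat requested but no batch labels available")
                m = combat_correct(m, state["batches"], parametric_eb=pp.get("parametric_eb", True))
            state["expression"] = m
            if "response" in state and "label" not in state["response"].columns:
                state["response"] = binarize_response(state["response"], pp.get("threshold", 0.5))
            record("preprocess", t0, state=m.state)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("preprocess", str(exc)) from exc

    # ----------------------------------------------------------------- train
    if "train" in stages:
        t0 = time.time()
        try:
            tr = cfg.get("train", {})
            m = state["expression"]
            y = (state["response"]["label"] == "resistant").astype(int).to_numpy()
            model_cfg = {**DESK_RESVAE, **tr.get("resvae", {})}
            model_cfg["hidden_dims"] = tuple(model_cfg["hidden_dims"])
            folds = tr.get("folds", 5)
            fold_metrics, best = crossval_train(
                m.values, y, ResVAEClassifier(**model_cfg, seed=seed), n_folds=folds, seed=seed
            )
            best.feature_names_ = m.gene_ids
            state["model"] = best
            state["y"] = y
            save_checkpoint(best, out / "resvae_checkpoint.json")
            per_fold = [mb.as_dict() for mb in fold_metrics]
            pooled = {
                "mean_auc": float(np.mean([f["auc"] for f in per_fold])),
                "best_auc": float(max(f["auc"] for f in per_fold)),
            }
            (out / "cv_metrics.json").write_text(json.dumps({"folds": per_fold, **pooled}, indent=2))
            if tr.get("forest", True):
                Xs, ys = smote_oversample(m.X, y, k=tr.get("smote_k", 5), seed=seed)
                state["forest"] = train_forest(
                    Xs, ys, seed=seed, feature_names=m.gene_ids,
                    **tr.get("forest_params", {}),
                )
            record("train", t0, **pooled)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("train", str(exc)) from exc

    # ------------------------------------------------------------- attribute
    if "attribute" in stages:
        t0 = time.time()
        try:
            at = cfg.get("attribute", {})
            m = state["expression"]
            model = state["model"]
            methods = at.get("methods", ["ig", "gs"])
            head = at.get("head", "resistance")
            results = {}
            if "ig" in methods:
                results["IG"] = integrated_gradients(
                    model.head_logit_and_grad, m.values, head=head,
                    n_steps=at.get("n_steps", 64),
                )
            if "gs" in methods:
                results["GS"] = gradient_shap(
                    model.head_logit_and_grad, m.values, head=head, seed=seed,
                    n_baseline_samples=at.get("n_baseline_samples", 8),
                    n_alpha_samples=at.get("n_alpha_samples", 4),
                )
            if "ts" in methods and "forest" in state:
                n_explain = min(at.get("ts_samples", 64), m.X.shape[0])
                rng = np.random.default_rng(seed)
                rows = rng.choice(m.X.shape[0], size=n_explain, replace=False)
                ts = tree_shap(state["forest"], m.X[rows], head=head)
                ts.feature_names = m.gene_ids
                results["TS"] = ts
            agg = pd.concat([r.to_frame() for r in results.values()])
            agg.to_csv(out / "attribution_aggregate.csv", index=False)
            state["attribution"] = results
            record("attribute", t0, methods=list(results))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("attribute", str(exc)) from exc

    # ------------------------------------------------------------------ rank
    if "rank" in stages:
        t0 = time.time()
        try:
            K = cfg.get("rank", {}).get("K", 100)
            rankings = {name: rank_genes(r, K=K) for name, r in state["attribution"].items()}
            state["rankings"] = rankings
            payload = {
                name: {"genes": r.genes, "scores": r.scores, "K": r.K, "head": r.head}
                for name, r in rankings.items()
            }
            if len(rankings) >= 2:
                cmp = compare_rankings(*rankings.values())
                payload["comparison"] = {
                    "intersection": cmp["intersection"],
                    "union": cmp["union"],
                    "jaccard": {f"{a}|{b}": v for (a, b), v in cmp["jaccard"].items()},
                }
            (out / "rankings.json").write_text(json.dumps(payload, indent=2))
            record("rank", t0, K=K)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("rank", str(exc)) from exc

    # ---------------------------------------------------------------- enrich
    if "enrich" in stages and cfg.get("enrich", {}).get("gmt"):
        t0 = time.time()
        try:
            gene_sets = rio.read_gmt(cfg["enrich"]["gmt"])
            first = next(iter(state["rankings"].values()))
            enr = ora_enrich(first.genes, gene_sets, universe=state["expression"].gene_ids)
            enr.to_csv(out / "enrichment.csv", index=False)
            record("enrich", t0, n_sets=len(gene_sets))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("enrich", str(exc)) from exc

    # -------------------------------------------------------------- survival
    if "survival" in stages:
        t0 = time.time()
        try:
            sv = cfg.get("survival", {})
            top = sv.get("top", 10)
            ranking = next(iter(state["rankings"].values()))
            genes = ranking.genes[:top]
            m = state["expression"]
            surv = state["survival"].set_index("sample_id").reindex(m.sample_ids)
            rec = pd.DataFrame(
                {"time": surv["time"].to_numpy(), "event": surv["event"].to_numpy().astype(int)}
            )
            for g in genes:
                rec[g] = m.values[g].to_numpy()
            fit = fit_cox(rec, ties_rule=sv.get("ties", "efron"))
            rs = risk_scores(fit, rec[genes])
            groups = median_split(rs)
            chi2, p = log_rank(rec, groups)
            km_high = kaplan_meier(rec[groups == "high"])
            km_low = kaplan_meier(rec[groups == "low"])
            km_high.assign(group="high").pipe(
                lambda a: pd.concat([a, km_low.assign(group="low")])
            ).to_csv(out / "km_curves.csv", index=False)
            report = {
                "genes": genes,
                "cox": fit.as_dict(),
                "log_rank": {"chi2": chi2, "p": p},
                "td_auc": td_auc(rec, rs, horizons=sv.get("horizons", (1.0, 3.0, 5.0))).to_dict("records"),
                "schoenfeld": schoenfeld_check(fit, rec).to_dict("records"),
            }
            (out / "survival_report.json").write_text(json.dumps(report, indent=2))
            record("survival", t0, log_rank_p=p, c_index=fit.c_index)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("survival", str(exc)) from exc

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
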