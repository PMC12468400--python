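"""Cox fitting against lifelines and against the simulation truth;
Kaplan-Meier, log-rank, concordance, td-AUC, Schoenfeld diagnostics."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as ll_cindex

from resistnet.cohort import CohortSpec, simulate_cohort, simulate_expression, simulate_survival
from resistnet.survival import (
    CoxPH,
    c_index,
    fit_cox,
    fit_cox_stratified,
    kaplan_meier,
    km_at,
    log_rank,
    median_split,
    risk_scores,
    schoenfeld_check,
    td_auc,
)


def sim_records(n=300, beta=0.7, censor=0.2, seed=0, n_cov=1):
    spec = CohortSpec(n_samples=n, n_genes=max(4, n_cov + 1), n_causal=n_cov,
                      cox_beta=tuple([beta] * n_cov), seed=seed)
    m, causal, _ = simulate_expression(spec)
    surv = simulate_survival(m, {g: beta for g in causal}, censor, seed=seed + 1)
    rec = pd.DataFrame({"time": surv["time"].to_numpy(), "event": surv["event"].to_numpy()})
    for g in causal:
        rec[g] = m.values[g].to_numpy()
    return rec, causal


class TestCoxFit:
    def test_constant_covariate_gives_zero_beta(self):
        rec, _ = sim_records(n=100, seed=1)
        rec.iloc[:, 2] = 1.0
        fit = fit_cox(rec)
        assert abs(fit.beta[0]) < 1e-8
        assert abs(fit.hr[0] - 1.0) < 1e-8

    def test_recovers_planted_beta_within_3se(self):
        rec, _ = sim_records(n=500, beta=0.8, seed=3)
        fit = fit_cox(rec)
        assert abs(fit.beta[0] - 0.8) < 3 * fit.se[0]

    def test_negated_covariate_negates_beta(self):
        rec, causal = sim_records(n=200, seed=5)
        fit1 = fit_cox(rec)
        rec2 = rec.copy()
        rec2[causal[0]] = -rec2[causal[0]]
        fit2 = fit_cox(rec2)
        assert abs(fit1.beta[0] + fit2.beta[0]) < 1e-8
        assert abs(fit1.loglik_trace[-1] - fit2.loglik_trace[-1]) < 1e-8

    @pytest.mark.parametrize("ties_rule", ["efron", "breslow"])
    def test_matches_lifelines(self, ties_rule):
        rec, _ = sim_records(n=250, beta=0.6, seed=7, n_cov=2)
        fit = fit_cox(rec, ties_rule=ties_rule)
        # continuous times: no ties, so both rules equal lifelines' Efron fit
        cph = CoxPHFitter().fit(rec, "time", "event")
        assert np.abs(fit.beta - cph.params_.to_numpy()).max() < 1e-5
        assert np.abs(fit.se - cph.standard_errors_.to_numpy()).max() < 1e-5

    def test_efron_with_heavy_ties_matches_lifelines(self):
        rec, _ = sim_records(n=150, beta=0.5, seed=11)
        rec["time"] = np.ceil(rec["time"])  # force ties
        fit = fit_cox(rec, ties_rule="efron")
        cph = CoxPHFitter().fit(rec, "time", "event")
        assert np.abs(fit.beta - cph.params_.to_numpy()).max() < 1e-4

    def test_maximizer_property(self):
        rec, _ = sim_records(n=120, seed=13)
        fit = fit_cox(rec)
        assert fit.loglik_trace[-1] >= fit.loglik_trace[0]
        assert fit.converged

    def test_no_events_rejected(self):
        rec, _ = sim_records(n=30, seed=0)
        rec["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox(rec)

    def test_separation_triggers_ridge(self):
        # binary covariate where every x=1 event precedes every x=0 event:
        # the partial likelihood is monotone in beta (no finite maximizer)
        n = 20
        rec = pd.DataFrame({
            "time": np.arange(1.0, 2 * n + 1),
            "event": 1,
            "x": np.array([1.0] * n + [0.0] * n),
        })
        fit = fit_cox(rec)
        assert fit.ridge_used
        assert np.isfinite(fit.beta).all()
        assert abs(fit.beta[0]) < 20

    def test_sklearn_style_wrapper(self):
        rec, causal = sim_records(n=150, seed=17)
        est = CoxPH().fit(rec[causal], rec[["time", "event"]].to_numpy())
        assert np.allclose(est.coef_, fit_cox(rec).beta)
        rs = est.predict(rec[causal])
        assert np.allclose(rs, rec[causal].to_numpy() @ est.coef_)


class TestRiskAndSplit:
    def test_zero_beta_zero_scores(self):
        rec, causal = sim_records(n=50, seed=2)
        fit = fit_cox(rec)
        fit.beta = np.zeros_like(fit.beta)
        assert np.allclose(risk_scores(fit, rec[causal]), 0.0)

    def test_risk_score_arithmetic(self):
        rec, causal = sim_records(n=10, seed=2)
        fit = fit_cox(rec)
        fit.beta = np.array([2.0])
        assert np.allclose(risk_scores(fit, pd.DataFrame({causal[0]: [1.0, 3.0]})), [2.0, 6.0])

    def test_affine_shift_preserves_ranks(self):
        rec, causal = sim_records(n=40, seed=3)
        fit = fit_cox(rec)
        rs1 = risk_scores(fit, rec[causal])
        rs2 = risk_scores(fit, rec[causal] + 5.0)
        assert np.allclose(rs2 - rs1, fit.beta.sum() * 5.0)

    def test_median_split_even(self):
        assert list(median_split([1, 2, 3, 4])) == ["low", "low", "high", "high"]

    def test_median_split_all_ties_low(self):
        assert (median_split([2.0] * 6) == "low").all()

    def test_median_split_needs_two(self):
        with pytest.raises(ValueError):
            median_split([1.0])


class TestKaplanMeier:
    def test_no_events_flat_one(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0]})
        km = kaplan_meier(rec)
        assert km.empty
        assert km_at(km, 10) == 1.0

    def test_two_events_by_hand(self):
        rec = pd.DataFrame({"time": [1, 2], "event": [1, 1]})
        km = kaplan_meier(rec)
        assert km_at(km, 1) == 0.5
        assert km_at(km, 2) == 0.0

    def test_censoring_product_limit_by_hand(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [1, 0, 1]})
        km = kaplan_meier(rec)
        assert abs(km_at(km, 1) - 2 / 3) < 1e-12
        assert km_at(km, 3) == 0.0

    def test_monotone_bounded(self):
        rec, _ = sim_records(n=100, seed=9)
        km = kaplan_meier(rec)
        s = km["survival"].to_numpy()
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rec, _ = sim_records(n=80, seed=10)
        km = kaplan_meier(rec)
        kmf = KaplanMeierFitter().fit(rec["time"], rec["event"])
        for t in km["time"]:
            assert abs(km_at(km, t) - kmf.predict(t)) < 1e-9


class TestLogRank:
    def test_identical_groups_zero(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0]})
        chi2, p = log_rank(rec, ["a"] * 3 + ["b"] * 3)
        assert chi2 == 0.0 and p == 1.0

    def test_label_swap_symmetry(self):
        rec, causal = sim_records(n=60, seed=4)
        g = np.where(rec[causal[0]] > rec[causal[0]].median(), "a", "b")
        chi2a, _ = log_rank(rec, g)
        chi2b, _ = log_rank(rec, np.where(g == "a", "b", "a"))
        assert abs(chi2a - chi2b) < 1e-12

    def test_matches_lifelines(self):
        rec, causal = sim_records(n=120, beta=1.0, seed=6)
        g = median_split(rec[causal[0]])
        chi2, p = log_rank(rec, g)
        ref = logrank_test(rec["time"][g == "high"], rec["time"][g == "low"],
                           rec["event"][g == "high"], rec["event"][g == "low"])
        assert abs(chi2 - ref.test_statistic) < 1e-9
        assert abs(p - ref.p_value) < 1e-12

    def test_type_one_error_calibrated(self):
        # null: survival independent of the split
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            spec = CohortSpec(n_samples=60, n_genes=4, n_causal=1, cox_beta=(),
                              seed=seed)
            m, _, _ = simulate_expression(spec)
            surv = simulate_survival(m, {}, censor_rate=0.2, seed=seed + 10_000)
            rec = pd.DataFrame({"time": surv["time"].to_numpy(),
                                "event": surv["event"].to_numpy()})
            g = median_split(m.X[:, 0])
            _, p = log_rank(rec, g)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08


class TestConcordance:
    def test_perfect_ordering(self):
        rec = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 1]})
        assert c_index(rec, [4, 3, 2, 1]) == 1.0

    def test_constant_scores_half(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1]})
        assert c_index(rec, [1, 1, 1]) == 0.5

    def test_small_set_matches_pair_enumeration(self):
        rec = pd.DataFrame({"time": [2, 5, 3, 8], "event": [1, 0, 1, 1]})
        rs = [1.2, 0.3, 0.9, 0.1]
        conc = 0
        comp = 0
        for i in range(4):
            for j in range(4):
                if rec["time"][i] < rec["time"][j] and rec["event"][i] == 1:
                    comp += 1
                    if rs[i] > rs[j]:
                        conc += 1
                    elif rs[i] == rs[j]:
                        conc += 0.5
        assert c_index(rec, rs) == conc / comp

    def test_matches_lifelines(self):
        rec, causal = sim_records(n=100, seed=8)
        rs = rec[causal[0]].to_numpy()
        mine = c_index(rec, rs)
        ref = ll_cindex(rec["time"], -rs, rec["event"])
        assert abs(mine - ref) < 1e-12

    def test_no_comparable_pairs_rejected(self):
        rec = pd.DataFrame({"time": [1, 1], "event": [0, 0]})
        with pytest.raises(ValueError):
            c_index(rec, [1, 2])


class TestTdAuc:
    def test_perfect_separation(self):
        rec = pd.DataFrame({"time": [0.5, 0.8, 5, 6], "event": [1, 1, 0, 0]})
        out = td_auc(rec, [9, 8, 1, 2], horizons=[1.0])
        assert out["auc"].iloc[0] == 1.0

    def test_random_scores_near_half(self, rng):
        rec, _ = sim_records(n=2000, beta=0.0, seed=14)
        out = td_auc(rec, rng.normal(size=2000), horizons=[3.0])
        assert abs(out["auc"].iloc[0] - 0.5) < 0.06

    def test_degenerate_horizon_flagged(self):
        rec = pd.DataFrame({"time": [1, 2], "event": [1, 1]})
        out = td_auc(rec, [1, 2], horizons=[10.0])
        assert not out["valid"].iloc[0]
        assert np.isnan(out["auc"].iloc[0])


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_mle(self):
        rec, _ = sim_records(n=150, seed=15)
        fit = fit_cox(rec, ties_rule="breslow")
        # raw residual sum at beta_hat is the score, which vanishes
        from resistnet.survival import _split_records

        X, t, d, _ = _split_records(rec)
        eta = X @ fit.beta
        w = np.exp(eta)
        total = np.zeros(len(fit.beta))
        for i in np.flatnonzero(d == 1):
            at_risk = t >= t[i]
            xbar = (w[at_risk, None] * X[at_risk]).sum(axis=0) / w[at_risk].sum()
            total += X[i] - xbar
        assert np.abs(total).max() < 1e-5

    def test_zero_beta_symmetric_design_near_zero_corr(self):
        rec, _ = sim_records(n=200, beta=0.0, seed=16)
        fit = fit_cox(rec)
        out = schoenfeld_check(fit, rec)
        assert abs(out["corr"].iloc[0]) < 0.2

    def test_needs_three_events(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0], "x": [0.1, 0.2, 0.3]})
        fit = fit_cox(rec)
        with pytest.raises(ValueError):
            schoenfeld_check(fit, rec)

    def test_flag_rate_under_proportional_hazards(self):
        flags = 0
        n_rep = 100
        for seed in range(n_rep):
            rec, _ = sim_records(n=120, beta=0.5, censor=0.2, seed=seed + 300)
            fit = fit_cox(rec)
            out = schoenfeld_check(fit, rec)
            flags += int(out["violation"].iloc[0])
        assert 0.01 <= flags / n_rep <= 0.10


class TestStratified:
    def test_stratified_fit_close_to_truth(self):
        rec, causal = sim_records(n=300, beta=0.6, seed=19)
        strata = np.tile(["a", "b"], 150)
        fit = fit_cox_stratified(rec, strata)
        assert abs(fit.beta[0] - 0.6) < 3 * fit.se[0]
        assert fit.converged

    def test_matches_lifelines_strata(self):
        rec, causal = sim_records(n=200, beta=0.6, seed=20)
        rec2 = rec.copy()
        rec2["s"] = np.tile([0, 1], 100)
        fit = fit_cox_stratified(rec, rec2["s"].to_numpy())
        cph = CoxPHFitter().fit(rec2, "time", "event", strata=["s"])
        assert np.abs(fit.beta - cph.params_.to_numpy()).max() < 1e-4
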