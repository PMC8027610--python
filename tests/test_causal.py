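"""DiD regression, ATT algebra, BH-FDR, and the event study."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vgxe import (
    InputValidationError,
    SimConfig,
    att_by_genotype,
    bh_fdr,
    build_did_frame,
    build_ets_frame,
    draw_truth,
    fit_did,
    fit_ets,
    fit_propensity,
    kernel_match_weights,
    predict_bmi_by_genotype,
    simulate_genotypes,
    simulate_panel,
    true_scores,
)
from vgxe.causal import DEFAULT_DID_COVARIATES, DidFit


def _hand_fit(lam=-0.095, th=0.013, de=0.258, tau=0.9) -> DidFit:
    """DidFit assembled from a hand-specified coefficient vector."""
    names = ["const", "BC", "mpgs", "BC_x_mpgs", "vpgs", "BC_x_vpgs", "bmi_lag"]
    params = pd.Series([2.0, lam, 0.163, th, -0.056, de, tau], index=names)
    vcov = pd.DataFrame(np.diag([0.1, 0.102, 0.047, 0.090, 0.070, 0.092, 0.025]) ** 2,
                        index=names, columns=names)
    profile = pd.Series(0.0, index=names)
    profile["const"] = 1.0
    profile["bmi_lag"] = 27.0
    return DidFit(params=params, robust_vcov=vcov, se=np.sqrt(pd.Series(np.diag(vcov), index=names)),
                  p_values=pd.Series(0.5, index=names), fdr_p=pd.Series(np.nan, index=names),
                  n_treated=375, n_control=11_559, r_squared=0.87, nobs=11_934,
                  covariate_profile=profile,
                  score_range={"mpgs": (-3, 3), "vpgs": (-3, 3)})


class TestAttAlgebra:
    def test_att_at_origin_is_the_treatment_main_effect(self):
        fit = _hand_fit()
        att = att_by_genotype(fit, [(0.0, 0.0)])
        assert att.loc[0, "att"] == pytest.approx(-0.095, abs=1e-15)

    def test_att_at_unit_scores_sums_three_coefficients(self):
        fit = _hand_fit()
        att = att_by_genotype(fit, [(1.0, 1.0)])
        assert att.loc[0, "att"] == pytest.approx(-0.095 + 0.013 + 0.258, abs=1e-15)
        assert att.loc[0, "att"] == pytest.approx(0.176, abs=1e-12)

    def test_zero_coefficients_give_zero_att_everywhere(self):
        fit = _hand_fit(lam=0.0, th=0.0, de=0.0)
        grid = [(m, v) for m in (-2, 0, 2) for v in (-2, 0, 2)]
        att = att_by_genotype(fit, grid)
        assert np.allclose(att["att"], 0.0, atol=1e-15)

    def test_prediction_difference_equals_att_identity(self):
        fit = _hand_fit()
        for m, v in [(-1.3, 0.4), (0.0, 0.0), (2.0, -2.0)]:
            pt = predict_bmi_by_genotype(fit, m, v, treated=True)
            pc = predict_bmi_by_genotype(fit, m, v, treated=False)
            expected = fit.params["BC"] + fit.params["BC_x_mpgs"] * m + fit.params["BC_x_vpgs"] * v
            assert pt["predicted_bmi"] - pc["predicted_bmi"] == pytest.approx(expected, abs=1e-12)

    def test_prediction_is_hand_linear_combination(self):
        fit = _hand_fit()
        m, v = 0.7, -0.2
        pred = predict_bmi_by_genotype(fit, m, v, treated=True)["predicted_bmi"]
        p = fit.params
        hand = (p["const"] + p["BC"] + p["mpgs"] * m + p["BC_x_mpgs"] * m
                + p["vpgs"] * v + p["BC_x_vpgs"] * v + p["bmi_lag"] * 27.0)
        assert pred == pytest.approx(hand, abs=1e-12)

    def test_extrapolation_warns(self):
        fit = _hand_fit()
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_bmi_by_genotype(fit, 10.0, 0.0, treated=True)


def _bh_oracle(p, q):
    """Independent O(m^2) step-up oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        rank = pos + 1
        candidates = [m * p[order[k - 1]] / k for k in range(rank, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            kmax = k
    reject[order[:kmax]] = True
    return adj, reject


class TestBhFdr:
    def test_all_small_p_rejected(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()

    def test_empty_input(self):
        adj, rej = bh_fdr([], q=0.05)
        assert adj.size == 0 and rej.size == 0

    def test_single_p_identity(self):
        adj, rej = bh_fdr([0.04], q=0.05)
        assert adj[0] == pytest.approx(0.04) and rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(InputValidationError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.lists(st.integers(1, 100), min_size=1, max_size=8))
    def test_agrees_with_brute_force_oracle_on_grid(self, grid_points):
        p = np.array(grid_points) / 100.0
        adj, rej = bh_fdr(p, q=0.05)
        adj_o, rej_o = _bh_oracle(p, 0.05)
        assert np.allclose(adj, adj_o, atol=1e-12)
        assert np.array_equal(rej, rej_o)


def _matched(frame, bandwidth=0.06):
    pcols = [c for c in frame.columns if c.startswith("pc")]
    covs = list(DEFAULT_DID_COVARIATES) + pcols + ["mpgs", "vpgs"]
    prop = fit_propensity(frame[covs], frame["BC"])
    strata = frame["year_baseline"].astype(str) + "|" + frame["sex"].astype(int).astype(str)
    return kernel_match_weights(prop.fitted_probabilities, frame["BC"] == 1,
                                strata=strata, bandwidth=bandwidth), pcols


class TestFitDid:
    def test_randomized_null_within_cis(self):
        cfg = SimConfig(n_individuals=8_000, n_variants=40, seed=31, att_mean=0.0,
                        att_by_mpgs=0.0, att_by_vpgs=0.0, confounding_strength=0.0)
        geno = simulate_genotypes(cfg)
        truth = draw_truth(cfg)
        panel = simulate_panel(geno, truth, cfg)
        sc = true_scores(geno, truth).rename(columns={"mpgs_true": "mpgs", "vpgs_true": "vpgs"})
        frame = build_did_frame(panel).merge(sc, on="person_id")
        mw, pcols = _matched(frame)
        fit = fit_did(frame, mw, covariates=list(DEFAULT_DID_COVARIATES) + pcols)
        for term in ("BC", "BC_x_mpgs", "BC_x_vpgs"):
            assert abs(fit.params[term]) < 3 * fit.se[term]

    def test_equal_weights_equals_unweighted_ols(self, small_cohort):
        from vgxe.matching import MatchWeights
        from scipy import sparse

        _, _, _, panel, sc = small_cohort
        frame = build_did_frame(panel).merge(sc, on="person_id").head(4_000).reset_index(drop=True)
        t = frame["BC"] == 1
        nt, nc = int(t.sum()), int((~t).sum())
        mw = MatchWeights(
            treated_index=np.flatnonzero(t), control_index=np.flatnonzero(~t),
            pair_weights=sparse.csr_matrix((nt, nc)), control_weights=np.ones(nc),
            support=np.ones(nt, bool), strata=pd.Series(["all"] * len(frame)),
        )
        a = fit_did(frame, mw, covariates=DEFAULT_DID_COVARIATES)
        b = fit_did(frame, None, covariates=DEFAULT_DID_COVARIATES)
        assert np.allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-10)

    def test_zero_weights_error(self, tiny_cohort):
        from vgxe.matching import MatchWeights
        from scipy import sparse
        from vgxe import EstimationError

        _, _, _, panel, sc = tiny_cohort
        frame = build_did_frame(panel).merge(sc, on="person_id")
        t = frame["BC"] == 1
        nt, nc = int(t.sum()), int((~t).sum())
        mw = MatchWeights(
            treated_index=np.flatnonzero(t), control_index=np.flatnonzero(~t),
            pair_weights=sparse.csr_matrix((nt, nc)), control_weights=np.zeros(nc),
            support=np.zeros(nt, bool), strata=pd.Series(["all"] * len(frame)),
        )
        with pytest.raises(EstimationError):
            fit_did(frame, mw, covariates=DEFAULT_DID_COVARIATES)

    def test_fdr_column_present_and_vcov_symmetric(self, small_cohort):
        _, _, _, panel, sc = small_cohort
        frame = build_did_frame(panel).merge(sc, on="person_id")
        mw, pcols = _matched(frame)
        fit = fit_did(frame, mw, covariates=list(DEFAULT_DID_COVARIATES) + pcols)
        V = fit.robust_vcov.to_numpy()
        assert np.allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > -1e-10)
        assert fit.fdr_p[["BC", "BC_x_vpgs"]].notna().all()
        assert fit.n_treated > 0 and fit.n_control > 0


class TestEts:
    def test_frame_restricts_treated_to_event_window(self, tiny_cohort):
        _, _, _, panel, _ = tiny_cohort
        frame = build_ets_frame(panel)
        treated = frame[frame["BC"] == 1]
        assert set(treated["event_time"].unique()) <= {-4.0, -2.0, 0.0, 2.0}
        # dummies: one per non-reference event time, zero at the reference
        ref = treated[treated["event_time"] == -2.0]
        assert (ref[["ev_m4", "ev_0", "ev_p2"]].to_numpy() == 0).all()

    def test_null_simulation_all_event_terms_cover_zero(self):
        cfg = SimConfig(n_individuals=6_000, n_variants=40, seed=33, att_mean=0.0,
                        att_by_mpgs=0.0, att_by_vpgs=0.0, confounding_strength=0.0,
                        n_waves=7)
        geno = simulate_genotypes(cfg)
        truth = draw_truth(cfg)
        panel = simulate_panel(geno, truth, cfg)
        sc = true_scores(geno, truth).rename(columns={"mpgs_true": "mpgs", "vpgs_true": "vpgs"})
        fit = fit_ets(panel, sc, None, covariates=DEFAULT_DID_COVARIATES, stratum="full")
        for rec in fit.event_coefs.itertuples():
            assert rec.ci_low <= 0 <= rec.ci_high

    def test_planted_effect_detected_at_event_zero_not_before(self):
        cfg = SimConfig(n_individuals=12_000, n_variants=40, seed=34, att_mean=0.8,
                        att_by_mpgs=0.0, att_by_vpgs=0.0, confounding_strength=0.0,
                        n_waves=7)
        geno = simulate_genotypes(cfg)
        truth = draw_truth(cfg)
        panel = simulate_panel(geno, truth, cfg)
        sc = true_scores(geno, truth).rename(columns={"mpgs_true": "mpgs", "vpgs_true": "vpgs"})
        fit = fit_ets(panel, sc, None, covariates=DEFAULT_DID_COVARIATES, stratum="full")
        ec = fit.event_coefs.set_index("event_time")
        assert ec.loc[-4, "ci_low"] <= 0 <= ec.loc[-4, "ci_high"]
        assert ec.loc[0, "ci_low"] > 0  # planted 0.8 clearly detected

    def test_median_split_strata_partition_sample(self, small_cohort):
        _, _, _, panel, sc = small_cohort
        frame = build_did_frame(panel).merge(sc, on="person_id")
        mw, pcols = _matched(frame)
        covs = list(DEFAULT_DID_COVARIATES) + pcols
        full = fit_ets(panel, sc, mw, covariates=covs, stratum="full", did_frame=frame)
        below = fit_ets(panel, sc, mw, covariates=covs, stratum="below", did_frame=frame)
        above = fit_ets(panel, sc, mw, covariates=covs, stratum="above", did_frame=frame)
        assert below.nobs + above.nobs == full.nobs
        assert {"full", "below", "above"} == {full.stratum, below.stratum, above.stratum}
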