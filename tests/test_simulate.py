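"""Generator checks: HWE genotypes, planted architecture, treatment assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vgxe import (
    ConfigurationError,
    SimConfig,
    SimulationError,
    TruthRecord,
    draw_truth,
    simulate_genotypes,
    simulate_panel,
    simulate_phenotype,
    split_train_test,
    standardized_bias,
    true_scores,
)
from vgxe.causal import build_did_frame
from vgxe.simulate import assign_treatment, _baseline_covariates


def test_genotype_dosages_are_binomial_support():
    cfg = SimConfig(n_individuals=4, n_variants=2, maf_range=(0.5, 0.5), seed=1,
                    n_mean_causal=1, n_var_causal=1)
    geno = simulate_genotypes(cfg)
    assert set(np.unique(geno.dosages)) <= {0.0, 1.0, 2.0}


def test_genotype_allele_frequency_and_hwe():
    cfg = SimConfig(n_individuals=20_000, n_variants=1, maf_range=(0.3, 0.3), seed=2,
                    n_mean_causal=0, n_var_causal=0)
    geno = simulate_genotypes(cfg)
    freq = geno.dosages.mean() / 2
    se = np.sqrt(0.3 * 0.7 / (2 * 20_000))
    assert abs(freq - 0.3) < 3 * se
    counts = np.bincount(geno.dosages[:, 0].astype(int), minlength=3)
    expected = 20_000 * np.array([0.49, 0.42, 0.09])
    chi2 = np.sum((counts - expected) ** 2 / expected)
    assert stats.chi2.sf(chi2, df=2) > 0.001


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(n_individuals=0).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(maf_range=(0.0, 0.5)).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(n_variants=10, n_mean_causal=11).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(n_waves=1).validate()


def test_phenotype_null_architecture_is_standard_normal():
    cfg = SimConfig(n_individuals=20_000, n_variants=10, seed=3,
                    n_mean_causal=0, n_var_causal=0, base_log_var=0.0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    y = simulate_phenotype(geno, truth, cfg)
    # variance of the sample variance of N(0,1) is 2/(n-1)
    assert abs(np.var(y, ddof=1) - 1.0) < 3 * np.sqrt(2 / (20_000 - 1))


def test_phenotype_variance_ratio_matches_exp_two_alpha():
    cfg = SimConfig(n_individuals=40_000, n_variants=1, maf_range=(0.5, 0.5), seed=4,
                    n_mean_causal=0, n_var_causal=0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    truth.var_alphas[:] = [0.5]
    y = simulate_phenotype(geno, truth, cfg)
    d = geno.dosages[:, 0]
    v2, v0 = np.var(y[d == 2], ddof=1), np.var(y[d == 0], ddof=1)
    ratio = v2 / v0
    n2, n0 = (d == 2).sum(), (d == 0).sum()
    se_log = np.sqrt(2 / n2 + 2 / n0)
    assert abs(np.log(ratio) - 2 * 0.5) < 3 * se_log


def test_phenotype_mean_effect_recovered_by_ols():
    cfg = SimConfig(n_individuals=20_000, n_variants=1, seed=5,
                    n_mean_causal=0, n_var_causal=0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    truth.mean_betas[:] = [1.0]
    y = simulate_phenotype(geno, truth, cfg)
    d = geno.dosages[:, 0]
    slope = np.cov(d, y)[0, 1] / np.var(d, ddof=1)
    se = 1.0 / np.sqrt(np.var(d, ddof=1) * 20_000)
    assert abs(slope - 1.0) < 3 * se


def test_phenotype_overflow_guard():
    cfg = SimConfig(n_individuals=100, n_variants=2, seed=6, n_mean_causal=0, n_var_causal=0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    truth.var_alphas[:] = [100.0, 0.0]
    with pytest.raises(SimulationError):
        simulate_phenotype(geno, truth, cfg)


def test_truth_record_round_trips_bit_exactly():
    cfg = SimConfig(n_individuals=10, n_variants=25, seed=8, n_mean_causal=10, n_var_causal=10)
    truth = draw_truth(cfg)
    back = TruthRecord.from_dict(truth.to_dict())
    assert np.array_equal(back.mean_betas, truth.mean_betas)
    assert np.array_equal(back.var_alphas, truth.var_alphas)
    assert back.true_att_params == truth.true_att_params
    assert back.propensity_coefs == truth.propensity_coefs


def test_random_assignment_is_balanced_and_confounded_is_not():
    rng = np.random.default_rng(9)
    cfg0 = SimConfig(n_individuals=20_000, confounding_strength=0.0, seed=9)
    base = _baseline_covariates(np.arange(20_000), cfg0, rng)
    out0 = assign_treatment(base, draw_truth(cfg0), cfg0)
    t0 = out0["treated"].to_numpy(dtype=bool)
    for c in ("smoker", "log_income", "tenure", "health_good"):
        assert abs(standardized_bias(out0[c], t0)) < 5
    cfg1 = SimConfig(n_individuals=20_000, confounding_strength=1.0, seed=9)
    out1 = assign_treatment(base, draw_truth(cfg1), cfg1)
    t1 = out1["treated"].to_numpy(dtype=bool)
    sbs = [abs(standardized_bias(out1[c], t1)) for c in ("smoker", "log_income", "tenure", "health_good")]
    assert max(sbs) > 10
    # realized fraction near target
    f = cfg1.treatment_fraction
    assert abs(t1.mean() - f) < 4 * np.sqrt(f * (1 - f) / 20_000)


def test_treatment_independent_of_genotype_scores(small_cohort):
    _, geno, truth, panel, scores = small_cohort
    persons = panel.drop_duplicates("person_id").merge(scores, on="person_id")
    t = persons["treated"].to_numpy(dtype=bool)
    n_t, n_c = t.sum(), (~t).sum()
    band = 100 * 4 * np.sqrt(1 / n_t + 1 / n_c)  # 4-SE noise band on SB%
    for col in ("mpgs", "vpgs"):
        assert abs(standardized_bias(persons[col], t)) < band


def test_panel_structure_and_event_times(tiny_cohort):
    _, _, _, panel, _ = tiny_cohort
    assert (panel["bmi"] > 0).all()
    treated = panel[panel["treated"] == 1]
    # treated persons have event_time defined and exactly one post (0) wave
    per = treated.groupby("person_id")["event_time"]
    assert (per.apply(lambda s: (s == 0).sum()) == 1).all()
    assert (per.apply(lambda s: (s == -2).sum()) == 1).all()
    assert panel.loc[panel["treated"] == 0, "event_time"].isna().all()
    # DiD frame: treated contribute exactly one row, controls several
    frame = build_did_frame(panel)
    vc = frame[frame["BC"] == 1].groupby("person_id").size()
    assert (vc == 1).all()
    assert frame[frame["BC"] == 0].groupby("person_id").size().max() > 1


def test_panel_null_effect_means_equal_changes():
    cfg = SimConfig(n_individuals=20_000, n_variants=20, seed=12, n_mean_causal=8, n_var_causal=8, att_mean=0.0,
                    att_by_mpgs=0.0, att_by_vpgs=0.0, confounding_strength=0.0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    panel = simulate_panel(geno, truth, cfg)
    frame = build_did_frame(panel)
    delta = frame["bmi"] - frame["bmi_lag"]
    dt = delta[frame["BC"] == 1]
    dc = delta[frame["BC"] == 0]
    se = np.sqrt(dt.var(ddof=1) / len(dt) + dc.var(ddof=1) / len(dc))
    assert abs(dt.mean() - dc.mean()) < 3 * se


def test_panel_planted_main_effect_recovered_by_difference_in_means():
    cfg = SimConfig(n_individuals=20_000, n_variants=20, seed=13, n_mean_causal=8, n_var_causal=8, att_mean=0.5,
                    att_by_mpgs=0.0, att_by_vpgs=0.0, confounding_strength=0.0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    panel = simulate_panel(geno, truth, cfg)
    frame = build_did_frame(panel)
    delta = frame["bmi"] - frame["bmi_lag"]
    dt, dc = delta[frame["BC"] == 1], delta[frame["BC"] == 0]
    se = np.sqrt(dt.var(ddof=1) / len(dt) + dc.var(ddof=1) / len(dc))
    assert abs((dt.mean() - dc.mean()) - 0.5) < 3 * se


def test_panel_planted_interaction_recovered_by_ols():
    cfg = SimConfig(n_individuals=20_000, n_variants=20, seed=14, n_mean_causal=8, n_var_causal=8, att_mean=0.0,
                    att_by_mpgs=0.0, att_by_vpgs=0.25, confounding_strength=0.0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    panel = simulate_panel(geno, truth, cfg)
    sc = true_scores(geno, truth)
    frame = build_did_frame(panel).merge(sc, on="person_id")
    delta = (frame["bmi"] - frame["bmi_lag"]).to_numpy()
    X = np.column_stack([
        np.ones(len(frame)),
        frame["BC"],
        frame["vpgs_true"],
        frame["BC"] * frame["vpgs_true"],
    ])
    coef, *_ = np.linalg.lstsq(X, delta, rcond=None)
    resid = delta - X @ coef
    cov = np.linalg.inv(X.T @ X) * resid.var(ddof=4)
    assert abs(coef[3] - 0.25) < 3 * np.sqrt(cov[3, 3])


def test_split_train_test_properties():
    ids = np.arange(10)
    tr, te = split_train_test(ids, 0.8, seed=1)
    assert len(tr) == 8 and len(te) == 2
    assert set(tr) | set(te) == set(ids) and not set(tr) & set(te)
    tr2, te2 = split_train_test(ids, 0.8, seed=1)
    assert np.array_equal(tr, tr2) and np.array_equal(te, te2)
    with pytest.warns(UserWarning):
        tr3, te3 = split_train_test(ids, 1.0, seed=1)
    assert len(te3) == 0 and len(tr3) == 10


def test_planted_vqtls_detectable_by_levene(small_cohort):
    """Variance architecture is real: Levene-type test flags a planted vQTL."""
    cfg = SimConfig(n_individuals=20_000, n_variants=5, maf_range=(0.3, 0.5), seed=15,
                    n_mean_causal=0, n_var_causal=0)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    truth.var_alphas[:] = [0.3, 0, 0, 0, 0]
    y = simulate_phenotype(geno, truth, cfg)
    d = geno.dosages[:, 0].astype(int)
    groups = [y[d == k] for k in (0, 1, 2)]
    assert stats.levene(*groups, center="median").pvalue < 1e-4
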