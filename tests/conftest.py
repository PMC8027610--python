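"""Shared fixtures: small synthetic cohorts generated at test time."""

import warnings

import numpy as np
import pytest

from vgxe import SimConfig, draw_truth, simulate_genotypes, simulate_panel, true_scores

warnings.filterwarnings("ignore", message="DGLM did not converge")


@pytest.fixture(scope="session")
def small_cohort():
    """20k-person confounded cohort with the default truth, shared read-only."""
    cfg = SimConfig(n_individuals=20_000, n_variants=40, seed=101)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    panel = simulate_panel(geno, truth, cfg)
    scores = true_scores(geno, truth).rename(
        columns={"mpgs_true": "mpgs", "vpgs_true": "vpgs"}
    )
    return cfg, geno, truth, panel, scores


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast cohort for structural tests."""
    cfg = SimConfig(n_individuals=1_500, n_variants=40, seed=7, n_waves=6)
    geno = simulate_genotypes(cfg)
    truth = draw_truth(cfg)
    panel = simulate_panel(geno, truth, cfg)
    scores = true_scores(geno, truth).rename(
        columns={"mpgs_true": "mpgs", "vpgs_true": "vpgs"}
    )
    return cfg, geno, truth, panel, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
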