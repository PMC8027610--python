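"""Synthetic cohort generator with known truth.

Generates everything the downstream analysis consumes: biallelic genotype
dosages under Hardy-Weinberg equilibrium, a phenotype whose residual variance
is log-linear in a genetic score, a biennial longitudinal BMI panel, baseline
covariates, and a treatment (job loss from a business closure) assigned by a
probit latent index on observed covariates only.  Every stochastic draw is
recorded in a :class:`TruthRecord` so that recovery tests can compare
estimates against the exact parameters used.

Treatment is independent of genotype by construction: the latent index sees
covariates only, which emulates the absence of gene-environment correlation
(no genetic selection into job loss).  The planted average treatment effect
on the treated is ``lambda + theta_m * mPGS_i + delta_v * vPGS_i`` where the
scores are the standardized true genetic values, so both the main effect and
the score interactions of the difference-in-differences model have known
truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from ._errors import ConfigurationError, SimulationError

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "TruthRecord",
    "simulate_genotypes",
    "draw_truth",
    "simulate_phenotype",
    "simulate_panel",
    "assign_treatment",
    "true_scores",
    "split_train_test",
    "PANEL_COVARIATES",
]

# Baseline covariates carried in every synthetic panel.  The "pc" columns
# emulate ancestry principal components; the rest are the socioeconomic and
# behavioural confounders of the job-loss literature.
PANEL_COVARIATES = (
    "sex",
    "age",
    "log_income",
    "tenure",
    "smoker",
    "health_good",
)

# Fixed per-wave BMI-trend loadings on covariates.  These create the
# covariate -> change-in-BMI channel; selection into treatment on the same
# covariates (scaled by ``confounding_strength``) is what biases a naive
# unmatched contrast.
_TREND_COEFS = {"smoker": 0.06, "z_income": -0.05, "health_good": -0.04, "z_age0": 0.03}

# Latent-index loadings, multiplied by confounding_strength.
_PROPENSITY_COEFS = {
    "smoker": 0.45,
    "z_income": -0.50,
    "z_tenure": -0.35,
    "health_good": -0.30,
    "z_age0": 0.20,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study conditions as defaults.

    The defaults describe a cohort of 20,000 older workers observed every two
    years over six waves, a sparse genetic architecture in which the mean and
    variance causal sets are disjoint, a 5% business-closure rate selected on
    observables, and a treatment effect of -0.1 BMI units moderated by the
    variance score (+0.25 per SD).
    """

    n_individuals: int = 20_000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_mean_causal: int = 20
    n_var_causal: int = 20
    mean_effect_sd: float = 0.10   # phenotype units per effect allele
    var_effect_sd: float = 0.10    # log-variance units per effect allele
    base_log_var: float = 0.0      # alpha_0 of the generative variance model
    treatment_fraction: float = 0.10    # person-level share hit by a closure
    confounding_strength: float = 0.6   # latent-index units per covariate SD
    n_waves: int = 6
    att_mean: float = -0.10        # lambda truth
    att_by_vpgs: float = 0.25      # delta truth
    att_by_mpgs: float = 0.0       # theta truth
    seed: int = 0
    # secondary knobs
    n_pcs: int = 5
    missing_rate: float = 0.05          # MCAR rate on log_income and tenure
    bmi_noise_sd: float = 0.9           # within-person biennial noise, kg/m^2
    panel_var_coupling: float = 0.3     # log-variance units per SD of true vPGS
    overlap_causal: bool = False        # allow mean/variance causal sets to overlap
    first_year: int = 1996

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0:
            raise ConfigurationError("n_individuals and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(f"maf_range must lie inside (0,1): {self.maf_range}")
        if self.n_mean_causal > self.n_variants or self.n_var_causal > self.n_variants:
            raise ConfigurationError("causal counts cannot exceed n_variants")
        if not self.overlap_causal and self.n_mean_causal + self.n_var_causal > self.n_variants:
            raise ConfigurationError(
                "disjoint mean/variance causal sets need n_mean_causal + n_var_causal <= n_variants"
            )
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be at least 2")
        if not (0.0 < self.treatment_fraction < 1.0):
            raise ConfigurationError("treatment_fraction must be in (0,1)")


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with allele metadata.

    ``dosages[i, j]`` counts copies of ``effect_allele[j]`` carried by
    individual ``i`` (0, 1 or 2 for hard calls; fractional values in [0, 2]
    are accepted when constructed from imputed data).
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    person_id: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variant_ids = np.asarray(self.variant_ids)
        m = self.dosages.shape[1]
        for name in ("variant_ids", "effect_allele", "other_allele", "maf"):
            if len(getattr(self, name)) != m:
                raise ConfigurationError(f"{name} length {len(getattr(self, name))} != {m} variants")
        if len(np.unique(self.variant_ids)) != m:
            raise ConfigurationError("variant_ids must be unique")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ConfigurationError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        """Row subset by person id, preserving id labels and variant metadata."""
        pos = {p: i for i, p in enumerate(self.person_id)}
        idx = np.array([pos[i] for i in np.asarray(ids)])
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            variant_ids=self.variant_ids,
            effect_allele=self.effect_allele,
            other_allele=self.other_allele,
            maf=self.maf,
            person_id=np.asarray(self.person_id)[idx],
        )


@dataclass
class TruthRecord:
    """Ground truth of one simulated study, stored exactly as drawn."""

    mean_betas: np.ndarray          # per-variant mean effects (0 for non-causal)
    var_alphas: np.ndarray          # per-variant log-variance effects
    true_att_params: tuple[float, float, float]   # (lambda, theta_m, delta_v)
    true_alpha1: float              # implied score effect in the variance model
    propensity_coefs: dict[str, float]
    base_log_var: float = 0.0
    mean_intercept: float = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_betas"] = list(map(float, self.mean_betas))
        d["var_alphas"] = list(map(float, self.var_alphas))
        d["true_att_params"] = list(map(float, self.true_att_params))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        d = dict(d)
        d["mean_betas"] = np.asarray(d["mean_betas"], dtype=float)
        d["var_alphas"] = np.asarray(d["var_alphas"], dtype=float)
        d["true_att_params"] = tuple(d["true_att_params"])
        return cls(**d)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Fan a single global seed out to independent per-stage child seeds."""
    return np.random.SeedSequence(seed).spawn(n)


def simulate_genotypes(config: SimConfig, seed=None) -> GenotypeMatrix:
    """Draw biallelic dosages under HWE: per variant Binomial(2, maf).

    Minor allele frequencies are uniform on ``config.maf_range``; dosages are
    independent across individuals and variants (no linkage disequilibrium).
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)
    maf = rng.uniform(*config.maf_range, size=config.n_variants)
    dosages = rng.binomial(2, maf, size=(config.n_individuals, config.n_variants)).astype(float)
    alleles = np.array(["A", "C", "G", "T"])
    eff = rng.integers(0, 4, size=config.n_variants)
    oth = (eff + rng.integers(1, 4, size=config.n_variants)) % 4
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.array([f"rs{j + 1:06d}" for j in range(config.n_variants)]),
        effect_allele=alleles[eff],
        other_allele=alleles[oth],
        maf=maf,
        person_id=np.arange(config.n_individuals),
    )


def draw_truth(config: SimConfig, seed=None) -> TruthRecord:
    """Draw the genetic architecture and record every parameter exactly.

    Mean- and variance-causal variant sets are disjoint unless
    ``config.overlap_causal`` is set, which decorrelates mean and variance
    effects the way a dispersion-effects test is meant to.
    """
    config.validate()
    rng = _rng(config.seed + 1 if seed is None else seed)
    m = config.n_variants
    betas = np.zeros(m)
    alphas = np.zeros(m)
    if config.overlap_causal:
        mean_idx = rng.choice(m, size=config.n_mean_causal, replace=False)
        var_idx = rng.choice(m, size=config.n_var_causal, replace=False)
    else:
        perm = rng.permutation(m)
        mean_idx = perm[: config.n_mean_causal]
        var_idx = perm[config.n_mean_causal : config.n_mean_causal + config.n_var_causal]
    betas[mean_idx] = rng.normal(0.0, config.mean_effect_sd, size=config.n_mean_causal)
    alphas[var_idx] = rng.normal(0.0, config.var_effect_sd, size=config.n_var_causal)
    coefs = {k: v * config.confounding_strength for k, v in _PROPENSITY_COEFS.items()}
    return TruthRecord(
        mean_betas=betas,
        var_alphas=alphas,
        true_att_params=(config.att_mean, config.att_by_mpgs, config.att_by_vpgs),
        true_alpha1=float(np.sqrt(np.sum(alphas**2))),  # scale of the variance signal
        propensity_coefs=coefs,
        base_log_var=config.base_log_var,
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix, truth: TruthRecord, config: SimConfig, seed=None
) -> np.ndarray:
    """Cross-sectional phenotype with log-linear residual variance.

    ``Y_i = gamma_0 + sum_j beta_j x_ij + eps_i`` with
    ``eps_i ~ Normal(0, exp(alpha_0 + sum_j alpha_j x_ij))``.
    """
    if genotypes.n_variants != len(truth.mean_betas):
        raise ConfigurationError("truth record does not match genotype matrix dimensions")
    rng = _rng(config.seed + 2 if seed is None else seed)
    mean = truth.mean_intercept + genotypes.dosages @ truth.mean_betas
    log_var = truth.base_log_var + genotypes.dosages @ truth.var_alphas
    if np.max(np.abs(log_var)) > 50:
        raise SimulationError(
            "log-variance linear predictor exceeds +/-50; variance effects too large to exponentiate"
        )
    return mean + rng.normal(size=genotypes.n_individuals) * np.exp(0.5 * log_var)


def true_scores(genotypes: GenotypeMatrix, truth: TruthRecord) -> pd.DataFrame:
    """Standardized true mean and variance genetic values per person.

    These are the oracle scores used to plant the treatment-effect
    interactions; estimated scores from a dispersion scan are noisy versions
    of them.  A score with zero architecture standardizes to all zeros.
    """

    def _std(x: np.ndarray) -> np.ndarray:
        s = x.std(ddof=1)
        if s < 1e-12:
            return np.zeros_like(x)
        return (x - x.mean()) / s

    return pd.DataFrame(
        {
            "person_id": genotypes.person_id,
            "mpgs_true": _std(genotypes.dosages @ truth.mean_betas),
            "vpgs_true": _std(genotypes.dosages @ truth.var_alphas),
        }
    )


def _baseline_covariates(
    person_id: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Time-invariant person-level covariates plus age at the first wave."""
    n = len(person_id)
    max_age0 = 70 - 2 * (config.n_waves - 1)
    df = pd.DataFrame(
        {
            "person_id": np.asarray(person_id),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age0": rng.uniform(50, max(max_age0, 51), size=n),
            "log_income": rng.normal(11.2, 0.55, size=n),
            "tenure": np.clip(rng.normal(13, 7, size=n), 0, None),
            "smoker": (rng.random(n) < 0.4).astype(float),
            "health_good": (rng.random(n) < 0.62).astype(float),
        }
    )
    for k in range(config.n_pcs):
        df[f"pc{k + 1}"] = rng.normal(size=n)
    return df


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def assign_treatment(
    base: pd.DataFrame, truth: TruthRecord, config: SimConfig, seed=None
) -> pd.DataFrame:
    """Assign business closures by a probit latent index on covariates only.

    ``base`` is the person-level baseline frame (one row per person with the
    covariates produced by the panel generator).  Adds ``treated`` (0/1) and,
    for treated persons, ``wave_star`` — the wave at which the job loss is
    reported, drawn uniformly from the waves with a complete event window.
    Genotype plays no role, so treatment is independent of both scores by
    construction.

    The probit intercept is calibrated so the expected treated fraction
    matches ``config.treatment_fraction``; a degenerate realisation (all or
    none treated) triggers a warning and a redraw.
    """
    rng = _rng(config.seed + 3 if seed is None else seed)
    index = (
        truth.propensity_coefs["smoker"] * base["smoker"].to_numpy()
        + truth.propensity_coefs["z_income"] * _zscore(base["log_income"].to_numpy())
        + truth.propensity_coefs["z_tenure"] * _zscore(base["tenure"].to_numpy())
        + truth.propensity_coefs["health_good"] * base["health_good"].to_numpy()
        + truth.propensity_coefs["z_age0"] * _zscore(base["age0"].to_numpy())
    )

    def mean_prob(c0: float) -> float:
        return float(np.mean(norm.cdf(c0 + index))) - config.treatment_fraction

    c0 = brentq(mean_prob, -10, 10)
    out = base.copy()
    for _ in range(10):
        treated = (rng.random(len(base)) < norm.cdf(c0 + index)).astype(int)
        if 0 < treated.sum() < len(base):
            break
        warnings.warn("degenerate treatment draw; resampling", stacklevel=2)
    else:  # pragma: no cover - practically unreachable
        raise SimulationError("could not draw a non-degenerate treatment vector")
    out["treated"] = treated
    lo, hi = 2, config.n_waves - 2  # wave_star needs waves {-2, 0, +1} around it
    if hi < lo:
        lo = hi = min(config.n_waves - 1, 1)
    out["wave_star"] = np.where(
        treated == 1, rng.integers(lo, hi + 1, size=len(base)), -1
    )
    return out


def simulate_panel(
    genotypes: GenotypeMatrix, truth: TruthRecord, config: SimConfig, seed=None
) -> pd.DataFrame:
    """Biennial BMI panel with covariates, treatment, and planted effects.

    One row per person-wave.  BMI follows a person intercept (loaded on the
    true mean genetic value), a quadratic age trajectory, a covariate-driven
    per-wave trend (the confounding channel into BMI *changes*), and
    within-person noise whose log-variance is linear in the true variance
    genetic value (``panel_var_coupling``).  Treated persons receive
    ``lambda + theta*mPGS + delta*vPGS`` added to BMI from their job-loss
    wave onward.  ``event_time`` is the offset in years relative to the
    reported loss (…, -4, -2, 0, +2, …; NaN for controls).
    """
    config.validate()
    if config.n_waves < 2:
        raise ConfigurationError("n_waves must be at least 2")
    ss = np.random.SeedSequence(config.seed + 4 if seed is None else seed).spawn(3)
    rng = _rng(ss[0])
    n = genotypes.n_individuals
    base = _baseline_covariates(genotypes.person_id, config, rng)
    base = assign_treatment(base, truth, config, seed=ss[1])

    scores = true_scores(genotypes, truth)
    mstd = scores["mpgs_true"].to_numpy()
    vstd = scores["vpgs_true"].to_numpy()

    rng2 = _rng(ss[2])
    intercept = (
        27.0
        + 1.25 * mstd
        - 0.6 * base["sex"].to_numpy()
        + 0.35 * base["smoker"].to_numpy()
        - 0.5 * (base["log_income"].to_numpy() - 11.2)
        + rng2.normal(0.0, 3.2, size=n)
    )
    slope = (
        _TREND_COEFS["smoker"] * base["smoker"].to_numpy()
        + _TREND_COEFS["z_income"] * _zscore(base["log_income"].to_numpy())
        + _TREND_COEFS["health_good"] * base["health_good"].to_numpy()
        + _TREND_COEFS["z_age0"] * _zscore(base["age0"].to_numpy())
    )
    noise_sd = config.bmi_noise_sd * np.exp(0.5 * config.panel_var_coupling * vstd)
    lam, theta_m, delta_v = truth.true_att_params
    effect = lam + theta_m * mstd + delta_v * vstd

    waves = np.arange(config.n_waves)
    rows = []
    for w in waves:
        age = base["age0"].to_numpy() + 2.0 * w
        bmi = (
            intercept
            + 0.10 * (age - 58.0)
            - 0.006 * (age - 58.0) ** 2
            + slope * w
            + rng2.normal(size=n) * noise_sd
        )
        treated_now = (base["treated"].to_numpy() == 1) & (w >= base["wave_star"].to_numpy())
        bmi = bmi + np.where(treated_now, effect, 0.0)
        rec = base.copy()
        rec["wave"] = w
        rec["year"] = config.first_year + 2 * w
        rec["age"] = age
        rec["bmi"] = np.clip(bmi, 12.0, None)
        rec["event_time"] = np.where(
            base["treated"].to_numpy() == 1,
            2.0 * (w - base["wave_star"].to_numpy()),
            np.nan,
        )
        rows.append(rec)
    panel = pd.concat(rows, ignore_index=True).sort_values(["person_id", "wave"]).reset_index(drop=True)

    # Missing-completely-at-random covariates exercise the missing-indicator
    # coding path downstream.  Missingness is at the person level so that a
    # baseline value is missing consistently across waves.
    if config.missing_rate > 0:
        rng3 = _rng(np.random.SeedSequence(config.seed + 5 if seed is None else seed + 1))
        for col in ("log_income", "tenure"):
            miss = rng3.random(n) < config.missing_rate
            miss_ids = np.asarray(genotypes.person_id)[miss]
            panel.loc[panel["person_id"].isin(miss_ids), col] = np.nan
    panel = panel.drop(columns=["age0"])
    return panel


def split_train_test(ids, fraction: float, seed: int):
    """Disjoint, exhaustive, reproducible split of ids into (train, test).

    ``fraction`` is the share of ids assigned to the training set.  A
    fraction of 1.0 yields an empty test set with a warning.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    ids = np.asarray(ids)
    rng = _rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    if n_train == len(ids) and fraction < 1.0:
        n_train -= 1
    if n_train == len(ids):
        warnings.warn("train fraction of 1.0 leaves an empty test set", stacklevel=2)
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]
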