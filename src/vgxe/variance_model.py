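"""Double generalized linear model for genetic effects on phenotype variance.

The model couples a linear mean submodel with a log-linear variance submodel:

    y_i = gamma_0 + gamma_1 g_i + X_i Theta + eps_i,
    eps_i ~ Normal(0, exp(alpha_0 + alpha_1 g_i + X_i Phi)),

where ``g_i`` is a (standardized) score or a single-variant dosage.  The
dispersion coefficient ``alpha_1`` is the parameter of interest: it measures
the proportional change in phenotype variance per unit of the score, and
``100 * (sqrt(exp(alpha_1)) - 1)`` is the percent change in the phenotype
standard deviation per 1-SD score increase.

Estimation alternates (a) weighted least squares for the mean submodel with
weights ``exp(-variance linear predictor)`` and (b) a gamma GLM with log link
fitted to the leverage-adjusted squared residuals ``e_i^2 / (1 - h_i)`` with
prior weights ``(1 - h_i) / 2`` — the standard REML-flavoured algorithm for
this model class.  Wald inference for ``alpha_1`` comes from the variance
submodel's information matrix; the asymptotic covariance of the dispersion
coefficients is ``2 (Z' diag(1-h) Z)^{-1}``, which the prior weights deliver
with the gamma dispersion fixed at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from scipy.special import ndtri

from ._errors import EstimationError, InputValidationError
from .simulate import GenotypeMatrix

__all__ = [
    "DglmFit",
    "inverse_normal_transform",
    "fit_dglm",
    "interpret_sd_change",
    "dispersion_scan",
    "validate_vpgs",
]


@dataclass
class DglmFit:
    """Fitted double GLM: mean coefficients, variance coefficients, inference.

    ``mean_coefs`` and ``var_coefs`` are indexed by term name; the score term
    is always called ``"score"`` and its dispersion effect is ``alpha1``.
    """

    mean_coefs: pd.Series
    var_coefs: pd.Series
    se_alpha1: float
    ci_alpha1: tuple[float, float]
    p_alpha1: float
    n_iter: int
    converged: bool
    loglik: float
    loglik_path: list = field(default_factory=list, repr=False)
    var_vcov: np.ndarray | None = field(default=None, repr=False)

    @property
    def alpha1(self) -> float:
        return float(self.var_coefs["score"])

    @property
    def gamma1(self) -> float:
        return float(self.mean_coefs["score"])


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset (c = 3/8).

    ``z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4))`` where ``r_i`` is the rank of
    observation ``i``; ties receive the average rank.  Strictly monotone in
    the untied input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InputValidationError("inverse normal transform needs a 1-d vector of length >= 2")
    if not np.isfinite(x).all():
        raise InputValidationError("inverse normal transform requires finite values")
    c = 0.375
    r = rankdata(x, method="average")
    return ndtri((r - c) / (x.size - 2 * c + 1))


def interpret_sd_change(alpha1: float) -> float:
    """Percent change in phenotype SD per one-unit increase of the score.

    The variance submodel is log-linear, so a coefficient ``a`` multiplies
    the variance by ``exp(a)`` and the SD by ``sqrt(exp(a))``; the return
    value is ``100 * (sqrt(exp(a)) - 1)``.
    """
    return 100.0 * (np.sqrt(np.exp(alpha1)) - 1.0)


def _design(score, covariates, n: int) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(n)]
    names = ["const"]
    if score is not None:
        cols.append(np.asarray(score, dtype=float))
        names.append("score")
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns by checking incremental rank
        bad = []
        r = 1
        for k in range(1, X.shape[1]):
            rk = np.linalg.matrix_rank(X[:, : k + 1])
            if rk == r:
                bad.append(names[k])
            r = rk
        raise EstimationError(f"singular design; collinear columns: {bad}")
    return X, names


def _gamma_glm_log(
    d: np.ndarray, Z: np.ndarray, prior_w: np.ndarray, alpha0: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma GLM with log link by IRLS; returns (coefs, covariance).

    For the log link the working weights equal the prior weights, so each
    step solves a weighted least-squares problem on the working response.
    The covariance is ``(Z' W Z)^{-1}`` with the gamma dispersion fixed at 1,
    which with prior weights ``(1-h)/2`` equals ``2 (Z' diag(1-h) Z)^{-1}``.
    """
    alpha = alpha0.copy()
    for _ in range(100):
        eta = Z @ alpha
        mu = np.exp(np.clip(eta, -700, 700))
        zwork = eta + (d - mu) / mu
        ZW = Z * prior_w[:, None]
        new = np.linalg.solve(ZW.T @ Z, ZW.T @ zwork)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    cov = np.linalg.inv((Z * prior_w[:, None]).T @ Z)
    return alpha, cov


def fit_dglm(
    phenotype,
    score,
    covariates=None,
    max_iter: int = 50,
    tol: float = 1e-8,
    intercept_only_variance: bool = False,
) -> DglmFit:
    """Fit the double GLM by alternating WLS and a gamma dispersion GLM.

    Both submodels share the design ``[1, score, covariates]`` unless
    ``intercept_only_variance`` restricts the variance submodel to a
    constant, in which case the mean fit coincides with ordinary least
    squares.  Iteration stops when the extended log-likelihood changes by
    less than ``tol``; on non-convergence the fit is returned with
    ``converged=False`` and a warning rather than an exception.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if not np.isfinite(y).all():
        raise InputValidationError("phenotype contains non-finite values")
    X, names = _design(score, covariates, n)
    if intercept_only_variance:
        Z, znames = _design(None, None, n)
    else:
        Z, znames = _design(score, covariates, n)
    if n <= X.shape[1] + Z.shape[1]:
        raise EstimationError("not enough observations for both submodels")

    # init: OLS mean fit, constant variance
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    alpha = np.zeros(Z.shape[1])
    alpha[0] = np.log(max(np.mean(e**2), 1e-300))

    def extended_loglik(e: np.ndarray, eta_v: np.ndarray) -> float:
        return float(-0.5 * np.sum(eta_v + e**2 * np.exp(-eta_v) + np.log(2 * np.pi)))

    path: list[float] = []
    converged = False
    n_iter = 0
    last = -np.inf
    for n_iter in range(1, max_iter + 1):
        eta_v = Z @ alpha
        if np.max(np.abs(eta_v)) > 500:
            raise EstimationError("variance linear predictor diverged")
        w = np.exp(-eta_v)
        Xw = X * w[:, None]
        XtWX = Xw.T @ X
        beta = np.linalg.solve(XtWX, Xw.T @ y)
        # leverages of the weighted mean fit
        h = np.einsum("ij,ji->i", X, np.linalg.solve(XtWX, Xw.T))
        h = np.clip(h, 0.0, 1.0 - 1e-8)
        e = y - X @ beta
        d = np.maximum(e**2 / (1.0 - h), 1e-300)
        prior_w = (1.0 - h) / 2.0
        alpha, var_cov = _gamma_glm_log(d, Z, prior_w, alpha)
        ll = extended_loglik(e, Z @ alpha)
        path.append(ll)
        if np.abs(ll - last) < tol:
            converged = True
            break
        last = ll
    if not converged:
        warnings.warn(f"DGLM did not converge in {max_iter} iterations", stacklevel=2)

    if intercept_only_variance:
        se, a1 = np.nan, np.nan
    else:
        k = 1  # position of the score term
        se = float(np.sqrt(var_cov[k, k]))
        a1 = float(alpha[k])
    zcrit = norm.ppf(0.975)
    return DglmFit(
        mean_coefs=pd.Series(beta, index=names),
        var_coefs=pd.Series(alpha, index=znames),
        se_alpha1=se,
        ci_alpha1=(a1 - zcrit * se, a1 + zcrit * se),
        p_alpha1=float(2 * norm.sf(abs(a1) / se)) if se > 0 else np.nan,
        n_iter=n_iter,
        converged=converged,
        loglik=path[-1],
        loglik_path=path,
        var_vcov=var_cov,
    )


def dispersion_scan(
    genotypes: GenotypeMatrix,
    phenotype,
    covariates=None,
    maf_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-variant dispersion scan: one double-GLM fit per variant dosage.

    A simplified variance GWAS on unrelated samples: each variant's dosage
    enters as the score of :func:`fit_dglm`, yielding a mean effect and a
    dispersion effect with Wald SE and p-value.  Variants that are
    monomorphic in the sample or below ``maf_floor`` are skipped and flagged.
    The phenotype should already be inverse-normal transformed (or covariates
    supplied for adjustment).
    """
    y = np.asarray(phenotype, dtype=float)
    records = []
    for j, vid in enumerate(genotypes.variant_ids):
        dosage = genotypes.dosages[:, j]
        freq = dosage.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_floor or dosage.std() == 0.0:
            records.append(
                dict(variant_id=vid, mean_effect=np.nan, dispersion_effect=np.nan,
                     dispersion_se=np.nan, dispersion_p=np.nan, skipped=True)
            )
            continue
        fit = fit_dglm(y, dosage, covariates=covariates)
        records.append(
            dict(
                variant_id=vid,
                mean_effect=fit.gamma1,
                dispersion_effect=fit.alpha1,
                dispersion_se=fit.se_alpha1,
                dispersion_p=fit.p_alpha1,
                skipped=False,
            )
        )
    return pd.DataFrame.from_records(records)


def validate_vpgs(phenotype, vpgs, mpgs=None, covariates=None) -> tuple[DglmFit, DglmFit | None]:
    """Held-out validation of a variance score, with and without mPGS adjustment.

    Model 1 regresses the phenotype's mean and log-variance on the vPGS plus
    covariates; Model 2 additionally adjusts the covariate vector for the
    mean score.  Returns ``(model1, model2)``; ``model2`` is None when no
    mPGS is supplied.
    """
    fit1 = fit_dglm(phenotype, vpgs, covariates=covariates)
    fit2 = None
    if mpgs is not None:
        cov2 = pd.DataFrame(covariates).copy() if covariates is not None else pd.DataFrame(index=range(len(np.asarray(vpgs))))
        cov2 = cov2.reset_index(drop=True)
        cov2["mpgs"] = np.asarray(mpgs, dtype=float)
        fit2 = fit_dglm(phenotype, vpgs, covariates=cov2)
    return fit1, fit2
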