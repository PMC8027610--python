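"""Weighted difference-in-differences with genotype interactions, ATT algebra,
Benjamini-Hochberg FDR, and the event-time study.

The headline regression is

    BMI_it = a + lambda*BC + phi*mPGS + theta_m*(BC x mPGS)
             + theta*vPGS + delta*(BC x vPGS) + tau*BMI_{i,t-2} + X'beta + e,

estimated by weighted least squares (treated weight 1, control weight W_j
from kernel matching) with a heteroskedasticity-robust (HC1) sandwich
covariance.  Because the model is linear, the average treatment effect on
the treated at score values (m, v) is exactly

    ATT(m, v) = lambda + theta_m * m + delta * v,

with a delta-method standard error from the robust covariance.  The event
time study replaces the treatment indicator by indicators for each survey
wave relative to the reported job loss (reference: the wave before, y = -2);
near-zero pre-event coefficients support the parallel-trends assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from ._errors import EstimationError, InputValidationError
from .matching import MatchWeights, build_design

__all__ = [
    "DidFit",
    "EtsFit",
    "build_did_frame",
    "fit_did",
    "predict_bmi_by_genotype",
    "att_by_genotype",
    "bh_fdr",
    "build_ets_frame",
    "fit_ets",
    "DEFAULT_DID_COVARIATES",
]

# baseline covariates entering the propensity and outcome models by default
DEFAULT_DID_COVARIATES = (
    "age_baseline",
    "log_income",
    "tenure",
    "smoker",
    "health_good",
)

_ZCRIT = norm.ppf(0.975)


@dataclass
class DidFit:
    """Weighted interaction regression with robust inference.

    ``params`` follows the naming BC (treatment), mpgs, BC_x_mpgs, vpgs,
    BC_x_vpgs, bmi_lag, then covariates.  ``fdr_p`` adjusts the headline
    family (treatment, scores, interactions, lagged outcome) unless the
    caller widened the family to all coefficients.
    """

    params: pd.Series
    robust_vcov: pd.DataFrame
    se: pd.Series
    p_values: pd.Series
    fdr_p: pd.Series
    n_treated: int
    n_control: int
    r_squared: float
    nobs: int
    covariate_profile: pd.Series = field(repr=False, default=None)
    score_range: dict = field(default_factory=dict, repr=False)
    n_dropped_zero_weight: int = 0

    @property
    def att_terms(self) -> tuple[str, str, str]:
        return ("BC", "BC_x_mpgs", "BC_x_vpgs")


def build_did_frame(panel: pd.DataFrame, covariates=None) -> pd.DataFrame:
    """Analysis frame of (t-2, t) wave pairs from a long panel.

    Each row is a post-period observation with its lagged BMI and baseline
    (t-2) covariates attached.  Control persons contribute every consecutive
    wave pair; treated persons contribute only the pair around the reported
    job loss (the wave with ``event_time == 0``).  ``BC`` marks treated rows
    and ``year_baseline`` / ``sex`` carry the exact-matching keys.
    """
    required = {"person_id", "wave", "bmi", "age", "treated"}
    missing = required - set(panel.columns)
    if missing:
        raise InputValidationError(f"panel is missing columns: {sorted(missing)}")
    df = panel.sort_values(["person_id", "wave"]).copy()
    g = df.groupby("person_id", sort=False)
    df["bmi_lag"] = g["bmi"].shift(1)
    df["wave_gap"] = g["wave"].diff()
    df["age_baseline"] = g["age"].shift(1)
    df["year_baseline"] = g["year"].shift(1) if "year" in df.columns else df["wave"] - 1
    rows = df[(df["wave_gap"] == 1) & df["bmi_lag"].notna()].copy()
    is_treated_person = rows["treated"] == 1
    keep = (~is_treated_person) | (rows.get("event_time", pd.Series(np.nan, index=rows.index)) == 0)
    frame = rows[keep].copy()
    frame["BC"] = (frame["treated"] == 1).astype(float)
    return frame.drop(columns=["wave_gap"]).reset_index(drop=True)


def _did_design(
    frame: pd.DataFrame, covariates, score_cols=("mpgs", "vpgs")
) -> pd.DataFrame:
    m, v = score_cols
    for c in (m, v, "bmi_lag"):
        if c not in frame.columns:
            raise InputValidationError(f"column {c!r} required in the analysis frame")
    core = pd.DataFrame(
        {
            "BC": frame["BC"].to_numpy(dtype=float),
            "mpgs": frame[m].to_numpy(dtype=float),
            "BC_x_mpgs": frame["BC"].to_numpy(dtype=float) * frame[m].to_numpy(dtype=float),
            "vpgs": frame[v].to_numpy(dtype=float),
            "BC_x_vpgs": frame["BC"].to_numpy(dtype=float) * frame[v].to_numpy(dtype=float),
            "bmi_lag": frame["bmi_lag"].to_numpy(dtype=float),
        }
    )
    cov = frame[list(covariates)].reset_index(drop=True) if covariates else None
    X = pd.concat([core.reset_index(drop=True), cov], axis=1) if cov is not None else core
    X, dropped = build_design(X)
    if dropped:
        core_terms = {"BC", "mpgs", "BC_x_mpgs", "vpgs", "BC_x_vpgs", "bmi_lag"}
        if core_terms & set(dropped):
            raise EstimationError(f"collinear design: core columns dropped: {sorted(core_terms & set(dropped))}")
        warnings.warn(f"dropped collinear covariate columns: {dropped}", stacklevel=2)
    return X


def _regression_weights(frame: pd.DataFrame, weights: MatchWeights) -> np.ndarray:
    """Per-row regression weights: treated 1 (on support), controls W_j."""
    w = np.zeros(len(frame))
    w[weights.treated_index[weights.support]] = 1.0
    w[weights.control_index] = weights.control_weights
    return w


def fit_did(
    frame: pd.DataFrame,
    weights: MatchWeights | None = None,
    covariates=DEFAULT_DID_COVARIATES,
    score_cols=("mpgs", "vpgs"),
    fdr_q: float = 0.05,
    fdr_family: str = "headline",
    cluster_by_person: bool = False,
) -> DidFit:
    """Weighted least squares DiD with score interactions and HC1 errors.

    ``weights=None`` runs the unweighted (naive) regression on the same
    design, which is the biased-by-construction contrast under confounded
    assignment.  Zero-weight observations are dropped and counted.  FDR
    adjustment covers the headline coefficient family (BC, scores,
    interactions, lagged BMI) or, with ``fdr_family='all'``, every
    non-intercept coefficient.
    """
    X = _did_design(frame, covariates, score_cols)
    y = frame["bmi"].to_numpy(dtype=float)
    if weights is not None:
        w = _regression_weights(frame, weights)
    else:
        w = np.ones(len(frame))
    keep = w > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise EstimationError("all regression weights are zero")
    Xk, yk, wk = X.loc[keep], y[keep], w[keep]
    cov_kw = {}
    if cluster_by_person:
        cov_type = "cluster"
        cov_kw = {"groups": frame.loc[keep, "person_id"].to_numpy()}
    else:
        cov_type = "HC1"
    res = sm.WLS(yk, Xk, weights=wk).fit(cov_type=cov_type, cov_kwds=cov_kw or None)
    params = pd.Series(res.params, index=Xk.columns)
    se = pd.Series(res.bse, index=Xk.columns)
    pvals = pd.Series(res.pvalues, index=Xk.columns)
    headline = [c for c in ("BC", "mpgs", "BC_x_mpgs", "vpgs", "BC_x_vpgs", "bmi_lag") if c in params.index]
    family = list(params.index.drop("const")) if fdr_family == "all" else headline
    adj, _ = bh_fdr(pvals[family].to_numpy(), q=fdr_q)
    fdr_p = pd.Series(np.nan, index=params.index)
    fdr_p[family] = adj
    profile = pd.Series(np.average(Xk.to_numpy(), axis=0, weights=wk), index=Xk.columns)
    bc = frame.loc[keep, "BC"].to_numpy() == 1
    return DidFit(
        params=params,
        robust_vcov=pd.DataFrame(res.cov_params(), index=Xk.columns, columns=Xk.columns),
        se=se,
        p_values=pvals,
        fdr_p=fdr_p,
        n_treated=int(bc.sum()),
        n_control=int((~bc).sum()),
        r_squared=float(res.rsquared),
        nobs=int(res.nobs),
        covariate_profile=profile,
        score_range={
            "mpgs": (float(frame[score_cols[0]].min()), float(frame[score_cols[0]].max())),
            "vpgs": (float(frame[score_cols[1]].min()), float(frame[score_cols[1]].max())),
        },
        n_dropped_zero_weight=n_dropped,
    )


def _prediction_row(fit: DidFit, m: float, v: float, treated: bool, profile: pd.Series) -> pd.Series:
    x = profile.copy()
    x["const"] = 1.0
    x["BC"] = 1.0 if treated else 0.0
    x["mpgs"] = m
    x["vpgs"] = v
    x["BC_x_mpgs"] = x["BC"] * m
    x["BC_x_vpgs"] = x["BC"] * v
    return x.reindex(fit.params.index)


def predict_bmi_by_genotype(
    fit: DidFit, m: float, v: float, treated: bool, covariate_profile: pd.Series | None = None
) -> dict:
    """Predicted BMI at score values (m, v) for a treated or control profile.

    Covariates (including lagged BMI) are held at the weighted means of the
    matched analytic sample unless a profile is supplied.  The 95% CI is
    delta-method from the robust covariance.  Score values outside the
    fitted range trigger an extrapolation warning but are still computed.
    """
    for name, val in (("mpgs", m), ("vpgs", v)):
        lo, hi = fit.score_range.get(name, (-np.inf, np.inf))
        if not (lo <= val <= hi):
            warnings.warn(f"{name}={val} outside the fitted range [{lo:.3g}, {hi:.3g}]; extrapolating", stacklevel=2)
    profile = fit.covariate_profile if covariate_profile is None else covariate_profile
    x = _prediction_row(fit, m, v, treated, profile).to_numpy(dtype=float)
    pred = float(x @ fit.params.to_numpy())
    se = float(np.sqrt(x @ fit.robust_vcov.to_numpy() @ x))
    return {"predicted_bmi": pred, "se": se, "ci": (pred - _ZCRIT * se, pred + _ZCRIT * se)}


def att_by_genotype(fit: DidFit, grid) -> pd.DataFrame:
    """ATT over a grid of (mPGS, vPGS) values with delta-method intervals.

    ``ATT(m, v) = lambda + theta_m*m + delta*v`` read directly off the fitted
    coefficients; the predicted treated-minus-control difference at the same
    profile equals this identically.
    """
    lam_t, th_t, de_t = fit.att_terms
    lam, th, de = (fit.params[t] for t in (lam_t, th_t, de_t))
    V = fit.robust_vcov.loc[[lam_t, th_t, de_t], [lam_t, th_t, de_t]].to_numpy()
    rows = []
    for m, v in grid:
        att = float(lam + th * m + de * v)
        g = np.array([1.0, m, v])
        se = float(np.sqrt(g @ V @ g))
        pt = predict_bmi_by_genotype(fit, m, v, treated=True)
        pc = predict_bmi_by_genotype(fit, m, v, treated=False)
        rows.append(
            dict(
                mpgs=m,
                vpgs=v,
                predicted_bmi_treated=pt["predicted_bmi"],
                predicted_bmi_control=pc["predicted_bmi"],
                att=att,
                se=se,
                ci_low=att - _ZCRIT * se,
                ci_high=att + _ZCRIT * se,
            )
        )
    return pd.DataFrame(rows)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags.

    ``adjusted p_(k) = min_{j >= k} (m * p_(j) / j)`` capped at 1; reject
    when the adjusted p-value is at most ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


@dataclass
class EtsFit:
    """Event-time-study coefficients for one stratum.

    ``event_coefs`` has one row per event time y in {-4, 0, +2} (reference
    y = -2 omitted): coefficient, robust SE and 95% CI.
    """

    stratum: str
    event_coefs: pd.DataFrame
    params: pd.Series = field(repr=False, default=None)
    robust_vcov: pd.DataFrame = field(repr=False, default=None)
    nobs: int = 0
    n_treated: int = 0


ETS_EVENT_TIMES = (-4.0, 0.0, 2.0)  # years relative to the reported job loss


def build_ets_frame(panel: pd.DataFrame) -> pd.DataFrame:
    """Wave-pair frame for the event study.

    Controls contribute every consecutive wave pair (as in the DiD frame);
    treated persons contribute the waves at event times -4, -2, 0 and +2,
    with -2 the omitted reference.  Event-time dummies ``ev_m4``, ``ev_0``,
    ``ev_p2`` are the product of the person's treatment status and the
    event-time indicator.
    """
    df = panel.sort_values(["person_id", "wave"]).copy()
    g = df.groupby("person_id", sort=False)
    df["bmi_lag"] = g["bmi"].shift(1)
    df["wave_gap"] = g["wave"].diff()
    df["age_baseline"] = g["age"].shift(1)
    df["year_baseline"] = g["year"].shift(1) if "year" in df.columns else df["wave"] - 1
    rows = df[(df["wave_gap"] == 1) & df["bmi_lag"].notna()].copy()
    is_treated = rows["treated"] == 1
    ev = rows.get("event_time", pd.Series(np.nan, index=rows.index))
    keep = (~is_treated) | ev.isin([-4.0, -2.0, 0.0, 2.0])
    frame = rows[keep].copy()
    frame["BC"] = (frame["treated"] == 1).astype(float)
    for y, name in zip(ETS_EVENT_TIMES, ("ev_m4", "ev_0", "ev_p2")):
        frame[name] = ((frame["BC"] == 1) & (frame["event_time"] == y)).astype(float)
    return frame.drop(columns=["wave_gap"]).reset_index(drop=True)


def fit_ets(
    panel: pd.DataFrame,
    scores: pd.DataFrame,
    weights: MatchWeights | None,
    covariates=DEFAULT_DID_COVARIATES,
    stratum: str = "full",
    did_frame: pd.DataFrame | None = None,
    cluster_by_person: bool = True,
) -> EtsFit:
    """Event time study regression, optionally stratified at the vPGS median.

    ``BMI_it = a + sum_y lambda_y (BC x I[t - t* = y]) + phi*mPGS
    + tau*BMI_{t-2} + X'beta`` (the full-sample variant also controls for the
    vPGS level), weighted by the baseline matching weights and estimated with
    robust errors clustered by person (both treated persons and multi-wave
    controls contribute repeated, serially correlated observations; set
    ``cluster_by_person=False`` for plain HC1).  ``stratum`` is ``"full"``,
    ``"below"`` (bottom 50% of the standardized vPGS, ties included) or
    ``"above"``.  Event cells with no treated observations are omitted with a
    warning.

    ``scores`` must carry ``person_id``, ``mpgs`` and ``vpgs`` columns; the
    matching weights are reused from the baseline (t-2, t) match, mapped to
    control observations by (person, wave).
    """
    frame = build_ets_frame(panel)
    frame = frame.merge(scores[["person_id", "mpgs", "vpgs"]], on="person_id", how="inner")

    # map baseline match weights onto rows by (person, wave)
    if weights is not None:
        base = build_did_frame(panel) if did_frame is None else did_frame
        ctrl = base.iloc[weights.control_index]
        wmap = {
            (p, w): cw
            for p, w, cw in zip(ctrl["person_id"], ctrl["wave"], weights.control_weights)
        }
        on_support_treated = set(base.iloc[weights.treated_index[weights.support]]["person_id"])
        reg_w = np.array(
            [
                1.0 if bc == 1 else wmap.get((p, w), 0.0)
                for bc, p, w in zip(frame["BC"], frame["person_id"], frame["wave"])
            ]
        )
        treated_drop = (frame["BC"] == 1) & ~frame["person_id"].isin(on_support_treated)
        reg_w[treated_drop.to_numpy()] = 0.0
    else:
        reg_w = np.ones(len(frame))

    # median split on the standardized vPGS over the analytic sample; ties low
    if stratum != "full":
        med = frame.loc[reg_w > 0, "vpgs"].median()
        mask = frame["vpgs"] <= med if stratum == "below" else frame["vpgs"] > med
        frame, reg_w = frame[mask].reset_index(drop=True), reg_w[mask.to_numpy()]
    keep = reg_w > 0
    frame, reg_w = frame[keep].reset_index(drop=True), reg_w[keep]

    ev_names = []
    for name in ("ev_m4", "ev_0", "ev_p2"):
        if frame.loc[frame["BC"] == 1, name].sum() == 0:
            warnings.warn(f"event cell {name} has no treated observations; omitted", stacklevel=2)
        else:
            ev_names.append(name)
    cols = {n: frame[n].to_numpy(dtype=float) for n in ev_names}
    cols["mpgs"] = frame["mpgs"].to_numpy(dtype=float)
    if stratum == "full":
        cols["vpgs"] = frame["vpgs"].to_numpy(dtype=float)
    cols["bmi_lag"] = frame["bmi_lag"].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    if covariates:
        X = pd.concat([X, frame[list(covariates)].reset_index(drop=True)], axis=1)
    X, dropped = build_design(X)
    if set(ev_names) & set(dropped):
        raise EstimationError(f"event dummies collinear: {sorted(set(ev_names) & set(dropped))}")
    if cluster_by_person:
        cov_type, cov_kwds = "cluster", {"groups": frame["person_id"].to_numpy()}
    else:
        cov_type, cov_kwds = "HC1", None
    res = sm.WLS(frame["bmi"].to_numpy(dtype=float), X, weights=reg_w).fit(
        cov_type=cov_type, cov_kwds=cov_kwds)
    params = pd.Series(res.params, index=X.columns)
    vcov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    label = {"ev_m4": -4, "ev_0": 0, "ev_p2": 2}
    recs = []
    for name in ev_names:
        coef = float(params[name])
        se = float(np.sqrt(vcov.loc[name, name]))
        recs.append(
            dict(event_time=label[name], coef=coef, se=se,
                 ci_low=coef - _ZCRIT * se, ci_high=coef + _ZCRIT * se)
        )
    return EtsFit(
        stratum=stratum,
        event_coefs=pd.DataFrame(recs),
        params=params,
        robust_vcov=vcov,
        nobs=int(res.nobs),
        n_treated=int((frame["BC"] == 1).sum()),
    )
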