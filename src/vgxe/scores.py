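"""Polygenic score construction, clumping, and mean-score validation.

A polygenic score is the weighted sum ``PGS_i = sum_j beta_j x_ij`` over the
variants shared between a genotype matrix and a weight table, where ``x_ij``
counts the weight's effect allele.  The same machinery scores mean effects
(mPGS) and dispersion effects (vPGS); only the weights differ.  Scores are
standardized to mean zero and unit standard deviation over the scoring
sample before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, InputValidationError, EstimationError
from .simulate import GenotypeMatrix

__all__ = [
    "WeightTable",
    "ScoreResult",
    "compute_pgs",
    "standardize",
    "greedy_clump",
    "validate_mpgs_growth_curve",
    "GrowthCurveReport",
]


@dataclass
class WeightTable:
    """Per-variant effect-allele weights, optionally with p-values/positions.

    ``table`` columns: ``variant_id``, ``effect_allele``, ``weight`` required;
    ``other_allele``, ``p_value``, ``chrom``, ``pos`` optional (p-values and
    positions are required for clumping).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"variant_id", "effect_allele", "weight"}
        missing = required - set(t.columns)
        if missing:
            raise InputValidationError(f"weight table missing columns: {sorted(missing)}")
        if t["variant_id"].duplicated().any():
            dups = t.loc[t["variant_id"].duplicated(), "variant_id"].tolist()
            raise InputValidationError(f"duplicate variant ids in weight table: {dups}")
        if not np.isfinite(t["weight"].to_numpy(dtype=float)).all():
            raise InputValidationError("weights must be finite")
        if "p_value" in t.columns:
            p = t["p_value"].dropna().to_numpy(dtype=float)
            if ((p <= 0) | (p > 1)).any():
                raise InputValidationError("p_values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ScoreResult:
    """Raw and standardized scores plus the variant-matching report."""

    scores: pd.DataFrame  # person_id, raw_score, standardized_score
    n_used: int
    n_flipped: int
    n_unmatched: int
    n_allele_mismatch: int
    mismatched_ids: list = field(default_factory=list)


def compute_pgs(genotypes: GenotypeMatrix, weights: WeightTable) -> ScoreResult:
    """Weighted allele-count sum over the variants shared with the weights.

    For each weight-table variant found in the genotypes: if the weight's
    effect allele is the genotype file's counted allele the dosage is used
    as-is; if it matches the other allele the dosage is flipped to ``2 - x``;
    if neither allele agrees the variant is skipped with a warning.  Variants
    absent from the genotypes are skipped and counted.
    """
    geno_index = {v: j for j, v in enumerate(genotypes.variant_ids)}
    raw = np.zeros(genotypes.n_individuals)
    n_used = n_flip = n_unmatched = n_mismatch = 0
    mismatched = []
    for row in weights.table.itertuples(index=False):
        j = geno_index.get(row.variant_id)
        if j is None:
            n_unmatched += 1
            continue
        if row.effect_allele == genotypes.effect_allele[j]:
            dosage = genotypes.dosages[:, j]
        elif row.effect_allele == genotypes.other_allele[j]:
            dosage = 2.0 - genotypes.dosages[:, j]
            n_flip += 1
        else:
            n_mismatch += 1
            mismatched.append(row.variant_id)
            continue
        raw = raw + row.weight * dosage
        n_used += 1
    if n_used == 0:
        raise InputValidationError("no variants shared between genotypes and weight table")
    if n_mismatch:
        warnings.warn(
            f"{n_mismatch} variants skipped: neither weight-table allele matches the genotype alleles",
            stacklevel=2,
        )
    frame = pd.DataFrame({"person_id": genotypes.person_id, "raw_score": raw})
    if raw.size < 2 or np.std(raw, ddof=1) < 1e-300:
        # all-zero weights are legitimate (null score); standardized form undefined
        frame["standardized_score"] = np.nan
    else:
        frame["standardized_score"] = standardize(raw)
    return ScoreResult(frame, n_used, n_flip, n_unmatched, n_mismatch, mismatched)


def standardize(values) -> np.ndarray:
    """z-transform with sample mean and sample SD (denominator n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise EstimationError("standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise EstimationError("cannot standardize a constant (zero-variance) vector")
    return (x - x.mean()) / sd


def greedy_clump(
    weights: WeightTable,
    r2_matrix: pd.DataFrame,
    r2_threshold: float = 0.1,
    window_kb: float = 1000.0,
) -> WeightTable:
    """Greedy LD clumping: keep index variants in ascending p-value order.

    A variant is dropped when an already-kept variant on the same chromosome
    lies within ``window_kb`` and their pairwise r^2 meets ``r2_threshold``.
    Ties are broken deterministically by (p, chromosome, position,
    variant_id), so the output is independent of input row order.
    ``r2_matrix`` is a symmetric variant-by-variant table (synthetic here;
    computing LD from a reference panel is out of scope).
    """
    t = weights.table
    for col in ("p_value", "chrom", "pos"):
        if col not in t.columns or t[col].isna().any():
            raise InputValidationError(f"clumping requires complete '{col}' column")
    order = t.sort_values(
        ["p_value", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    kept: list[int] = []
    kept_ids: list[str] = []
    for i, row in order.iterrows():
        clumped = False
        for kid, krow_i in zip(kept_ids, kept):
            krow = order.loc[krow_i]
            if krow["chrom"] != row["chrom"]:
                continue
            if abs(krow["pos"] - row["pos"]) > window_kb * 1000.0:
                continue
            try:
                r2 = float(r2_matrix.loc[row["variant_id"], kid])
            except KeyError:
                try:
                    r2 = float(r2_matrix.loc[kid, row["variant_id"]])
                except KeyError:
                    r2 = 0.0
            if r2 >= r2_threshold:
                clumped = True
                break
        if not clumped:
            kept.append(i)
            kept_ids.append(row["variant_id"])
    return WeightTable(order.loc[kept].reset_index(drop=True))


@dataclass
class GrowthCurveReport:
    """Two-stage growth-curve validation of the mean score."""

    incremental_r2: float
    r2_base: float
    r2_full: float
    slope: float
    slope_se: float
    n_included: int
    n_excluded: int


def validate_mpgs_growth_curve(
    panel: pd.DataFrame,
    mpgs: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex",),
) -> GrowthCurveReport:
    """Validate the mean score against per-person BMI growth-curve intercepts.

    Stage 1 fits, for every person with at least three observations, an OLS
    quadratic in age (centered at the sample mean age so the intercept is the
    expected BMI at the average age): ``BMI_it = b0_i + b1_i*age + b2_i*age^2``.
    Stage 2 regresses the stage-1 intercepts on the score plus covariates and
    reports the score's incremental R^2 over the covariate-only model —
    implemented as a transparent two-stage approximation to a multilevel
    growth model.
    """
    score_map = mpgs.set_index("person_id")["standardized_score"]
    age_center = panel["age"].mean()
    intercepts = {}
    n_excluded = 0
    for pid, grp in panel.groupby("person_id"):
        if len(grp) < 3 or pid not in score_map.index:
            n_excluded += 1
            continue
        a = grp["age"].to_numpy() - age_center
        X = np.column_stack([np.ones_like(a), a, a**2])
        coef, *_ = np.linalg.lstsq(X, grp["bmi"].to_numpy(), rcond=None)
        intercepts[pid] = coef[0]
    if not intercepts:
        raise EstimationError("no person has the 3+ observations a quadratic growth curve needs")
    ids = np.array(sorted(intercepts))
    y = np.array([intercepts[i] for i in ids])
    base_cols = [np.ones(len(ids))]
    person_rows = panel.drop_duplicates("person_id").set_index("person_id")
    for c in covariates:
        base_cols.append(person_rows.loc[ids, c].to_numpy(dtype=float))
    Xb = np.column_stack(base_cols)
    Xf = np.column_stack(base_cols + [score_map.loc[ids].to_numpy()])

    def _r2(X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid**2) / tss, coef, resid

    r2b, _, _ = _r2(Xb)
    r2f, coef_f, resid_f = _r2(Xf)
    dof = len(ids) - Xf.shape[1]
    sigma2 = np.sum(resid_f**2) / max(dof, 1)
    cov = sigma2 * np.linalg.inv(Xf.T @ Xf)
    return GrowthCurveReport(
        incremental_r2=float(r2f - r2b),
        r2_base=float(r2b),
        r2_full=float(r2f),
        slope=float(coef_f[-1]),
        slope_se=float(np.sqrt(cov[-1, -1])),
        n_included=len(ids),
        n_excluded=n_excluded,
    )
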