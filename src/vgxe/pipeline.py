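"""End-to-end workflow on a synthetic cohort.

Mirrors the analytic design of the study this package implements: train
per-variant dispersion weights on a training split, score a held-out cohort
(vPGS from dispersion effects, mPGS from mean effects), validate the vPGS
with a double GLM, build the longitudinal panel, kernel-match on a probit
propensity score, run the weighted difference-in-differences regression with
score interactions, read off ATT by genotype, and close with the event-time
study.  Every stage seeds from one global seed, so two runs with the same
configuration are numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError
from . import io as vio
from .causal import (
    DEFAULT_DID_COVARIATES,
    att_by_genotype,
    build_did_frame,
    fit_did,
    fit_ets,
)
from .matching import balance_table, fit_propensity, kernel_match_weights, trim_common_support
from .scores import WeightTable, compute_pgs, standardize, validate_mpgs_growth_curve
from .simulate import (
    SimConfig,
    child_seeds,
    draw_truth,
    simulate_genotypes,
    simulate_panel,
    simulate_phenotype,
    split_train_test,
    true_scores,
)
from .variance_model import dispersion_scan, interpret_sd_change, inverse_normal_transform, validate_vpgs

log = logging.getLogger("vgxe")

__all__ = ["RunConfig", "RunReport", "run_workflow"]


@dataclass
class RunConfig:
    """Configuration of one full synthetic-study run."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    train_fraction: float = 0.8
    bandwidth: float | str = "silverman"
    exact_keys: tuple[str, ...] = ("year_baseline", "sex")
    fdr_q: float = 0.05
    cluster_by_person: bool = False
    use_true_scores: bool = False     # bypass the scan; plant oracle scores
    run_ets: bool = True
    run_growth_curve: bool = True
    write_arrays: bool = True         # write genotype/panel TSVs alongside results
    make_plots: bool = False
    att_grid: tuple = tuple((0.0, v) for v in (-2.0, -1.0, 0.0, 1.0, 2.0))

    def validate(self) -> None:
        if not (0 < self.fdr_q < 1):
            raise ConfigurationError("fdr_q must be in (0,1)")
        if not isinstance(self.bandwidth, str) and self.bandwidth <= 0:
            raise ConfigurationError("bandwidth must be positive")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        if "maf_range" in raw.get("sim", {}):  # pragma: no cover
            sim.maf_range = tuple(sim.maf_range)
        cfg = cls(sim=sim, **{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Per-stage accounting plus headline coefficients of one run."""

    seed: int
    counts: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    balance_summary: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=float)

    def to_markdown(self) -> str:
        lines = [f"# Run report (seed {self.seed})", "", "## Stage counts"]
        for k, v in self.counts.items():
            lines.append(f"- {k}: {v}")
        lines += ["", "## Convergence"]
        for k, v in self.convergence.items():
            lines.append(f"- {k}: {v}")
        lines += ["", "## Balance"]
        for k, v in self.balance_summary.items():
            lines.append(f"- {k}: {v}")
        lines += ["", "## Headline estimates"]
        for k, v in self.headline.items():
            lines.append(f"- {k}: {v}")
        return "\n".join(lines) + "\n"


def _stage(report: RunReport, name: str):
    class _Timer:
        def __enter__(self):
            log.info("stage %s ...", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            report.timings_s[name] = round(time.perf_counter() - self.t0, 3)
            if exc_type is not None:
                log.error("stage %s failed: %s", name, exc)
            else:
                log.info("stage %s done in %.2fs", name, report.timings_s[name])
            return False

    return _Timer()


def run_workflow(config: RunConfig, outdir=None) -> RunReport:
    """Execute the full pipeline; write artifacts when ``outdir`` is given.

    Returns the :class:`RunReport`; artifacts (scores, weight tables,
    balance table, coefficient JSONs, the report itself) are written under
    ``outdir``.  A stage failure propagates after earlier artifacts have been
    persisted.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    seeds = child_seeds(config.seed, 8)
    artifacts: dict[str, object] = {}

    with _stage(report, "simulate"):
        geno = simulate_genotypes(config.sim, seed=seeds[0])
        truth = draw_truth(config.sim, seed=seeds[1])
        pheno = simulate_phenotype(geno, truth, config.sim, seed=seeds[2])
        report.counts["individuals"] = geno.n_individuals
        report.counts["variants"] = geno.n_variants
        if out is not None:
            vio.write_truth(truth, out / "truth.json")
            if config.write_arrays:
                vio.write_genotypes(geno, out / "genotypes.raw")

    with _stage(report, "split"):
        train_ids, test_ids = split_train_test(geno.person_id, config.train_fraction, seed=int(seeds[3].generate_state(1)[0] % 2**31))
        report.counts["train"] = len(train_ids)
        report.counts["test"] = len(test_ids)
        geno_tr = geno.subset_individuals(train_ids)
        geno_te = geno.subset_individuals(test_ids)

    with _stage(report, "dispersion_scan"):
        if config.use_true_scores:
            scan = None
        else:
            y_tr = inverse_normal_transform(pheno[np.isin(geno.person_id, train_ids)])
            scan = dispersion_scan(geno_tr, y_tr)
            report.counts["variants_scanned"] = int((~scan["skipped"]).sum())
            report.counts["variants_skipped"] = int(scan["skipped"].sum())
            if out is not None:
                scan.to_csv(out / "dispersion_scan.tsv", sep="\t", index=False)

    with _stage(report, "score"):
        if config.use_true_scores:
            sc = true_scores(geno_te, truth).rename(
                columns={"mpgs_true": "mpgs", "vpgs_true": "vpgs"}
            )
        else:
            ok = scan[~scan["skipped"]]
            allele_of = dict(zip(geno.variant_ids, geno.effect_allele))
            vw = WeightTable(pd.DataFrame({
                "variant_id": ok["variant_id"],
                "effect_allele": [allele_of[v] for v in ok["variant_id"]],
                "weight": ok["dispersion_effect"],
                "p_value": ok["dispersion_p"].clip(lower=1e-300),
            }))
            mw = WeightTable(vw.table.assign(weight=ok["mean_effect"].to_numpy()))
            vres = compute_pgs(geno_te, vw)
            mres = compute_pgs(geno_te, mw)
            sc = pd.DataFrame({
                "person_id": geno_te.person_id,
                "mpgs": mres.scores["standardized_score"].to_numpy(),
                "vpgs": vres.scores["standardized_score"].to_numpy(),
            })
            if out is not None:
                vio.write_weights(vw, out / "vpgs_weights.tsv")
                vio.write_weights(mw, out / "mpgs_weights.tsv")
        if out is not None:
            sc.to_csv(out / "scores.tsv", sep="\t", index=False)

    with _stage(report, "validate_vpgs"):
        y_te = inverse_normal_transform(pheno[np.isin(geno.person_id, test_ids)])
        sc_by_id = sc.set_index("person_id")
        v_te = sc_by_id.loc[list(geno_te.person_id), "vpgs"].to_numpy()
        m_te = sc_by_id.loc[list(geno_te.person_id), "mpgs"].to_numpy()
        if np.std(v_te) == 0:
            fit1 = fit2 = None
            report.convergence["dglm_model1"] = "skipped (degenerate vPGS)"
        else:
            fit1, fit2 = validate_vpgs(y_te, v_te, mpgs=m_te if np.std(m_te) > 0 else None)
            report.convergence["dglm_model1"] = fit1.converged
            report.headline["vpgs_alpha1_model1"] = fit1.alpha1
            report.headline["vpgs_alpha1_se_model1"] = fit1.se_alpha1
            report.headline["vpgs_alpha1_p_model1"] = fit1.p_alpha1
            report.headline["vpgs_sd_change_percent"] = interpret_sd_change(fit1.alpha1)
            if fit2 is not None:
                report.headline["vpgs_alpha1_model2"] = fit2.alpha1
                report.convergence["dglm_model2"] = fit2.converged

    with _stage(report, "panel"):
        panel = simulate_panel(geno_te, truth, config.sim, seed=int(seeds[4].generate_state(1)[0] % 2**31))
        report.counts["panel_rows"] = len(panel)
        report.counts["treated_persons"] = int(panel.drop_duplicates("person_id")["treated"].sum())
        if out is not None and config.write_arrays:
            vio.write_panel(panel, out / "panel.tsv")

    with _stage(report, "growth_curve"):
        if config.run_growth_curve and not config.use_true_scores:
            gc = validate_mpgs_growth_curve(
                panel, sc.rename(columns={"mpgs": "standardized_score"}), covariates=("sex",)
            )
            report.headline["mpgs_incremental_r2"] = gc.incremental_r2
            report.counts["growth_curve_included"] = gc.n_included
            report.counts["growth_curve_excluded"] = gc.n_excluded

    with _stage(report, "match"):
        frame = build_did_frame(panel).merge(sc, on="person_id", how="inner")
        pcols = [c for c in frame.columns if c.startswith("pc")]
        prop_covs = list(DEFAULT_DID_COVARIATES) + pcols + ["mpgs", "vpgs"]
        prop = fit_propensity(frame[prop_covs], frame["BC"])
        support = trim_common_support(prop.fitted_probabilities, frame["BC"] == 1)
        strata = frame["year_baseline"].astype(str) + "|" + frame["sex"].astype(int).astype(str)
        mw_ = kernel_match_weights(
            prop.fitted_probabilities, frame["BC"] == 1, strata=strata,
            bandwidth=config.bandwidth, support=support,
        )
        bal = balance_table(frame, "BC", prop_covs, weights=mw_)
        n_tr = int((frame["BC"] == 1).sum())
        report.counts["did_treated_before_support"] = n_tr
        report.counts["did_treated_on_support"] = int(mw_.support.sum())
        report.counts["did_treated_off_support"] = mw_.n_off_support
        report.counts["did_controls"] = int((frame["BC"] == 0).sum())
        matched = bal[bal["match_status"] == "M"]
        report.balance_summary["median_abs_sb_matched"] = float(matched["standardized_bias"].abs().median())
        report.balance_summary["n_flagged_matched"] = int(matched["flagged"].sum())
        report.convergence["propensity"] = prop.converged
        if out is not None:
            bal.to_csv(out / "balance.tsv", sep="\t", index=False)
            ctrl = frame.iloc[mw_.control_index][["person_id", "wave"]].copy()
            ctrl["weight"] = mw_.control_weights
            ctrl.to_csv(out / "match_weights.tsv", sep="\t", index=False)

    with _stage(report, "did"):
        did_covs = list(DEFAULT_DID_COVARIATES) + pcols
        did = fit_did(
            frame, mw_, covariates=did_covs, fdr_q=config.fdr_q,
            cluster_by_person=config.cluster_by_person,
        )
        report.headline["did_lambda"] = float(did.params["BC"])
        report.headline["did_theta_mpgs"] = float(did.params["BC_x_mpgs"])
        report.headline["did_delta_vpgs"] = float(did.params["BC_x_vpgs"])
        report.headline["did_r_squared"] = did.r_squared
        att = att_by_genotype(did, config.att_grid)
        if out is not None:
            coef = pd.DataFrame({
                "coef": did.params, "robust_se": did.se,
                "p": did.p_values, "fdr_p": did.fdr_p,
            })
            coef.to_json(out / "did.json", orient="index", indent=1)
            att.to_json(out / "att_by_genotype.json", orient="records", indent=1)

    if config.run_ets:
        with _stage(report, "ets"):
            ets = {
                s: fit_ets(panel, sc, mw_, covariates=did_covs, stratum=s, did_frame=frame)
                for s in ("full", "below", "above")
            }
            for s, f in ets.items():
                for rec in f.event_coefs.to_dict("records"):
                    report.headline[f"ets_{s}_y{int(rec['event_time']):+d}"] = rec["coef"]
            if out is not None:
                payload = {
                    s: f.event_coefs.to_dict("records") for s, f in ets.items()
                }
                (out / "ets.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    if config.make_plots and out is not None:  # pragma: no cover - optional extra
        with _stage(report, "plots"):
            _make_plots(att, ets if config.run_ets else None, out)

    if out is not None:
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(report.to_markdown())
    return report


def _make_plots(att: pd.DataFrame, ets: dict | None, out: Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.errorbar(att["vpgs"], att["predicted_bmi_treated"], fmt="o-", label="treated")
    ax.errorbar(att["vpgs"], att["predicted_bmi_control"], fmt="s--", label="control")
    ax.set_xlabel("vPGS (SD units)")
    ax.set_ylabel("predicted BMI")
    ax.legend()
    fig.savefig(out / "predicted_bmi.png", dpi=120)
    plt.close(fig)
    if ets:
        fig, axes = plt.subplots(1, len(ets), figsize=(4 * len(ets), 3), sharey=True)
        for ax, (s, f) in zip(np.atleast_1d(axes), ets.items()):
            ec = f.event_coefs
            ax.errorbar(ec["event_time"], ec["coef"],
                        yerr=[ec["coef"] - ec["ci_low"], ec["ci_high"] - ec["coef"]], fmt="o")
            ax.axhline(0, color="grey", lw=0.5)
            ax.set_title(s)
            ax.set_xlabel("years since job loss")
        fig.tight_layout()
        fig.savefig(out / "ets.png", dpi=120)
        plt.close(fig)
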