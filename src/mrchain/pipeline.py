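"""Three-stage study orchestration.

Stage 1 screens every exposure x outcome pair with univariable MR (IVW,
MR-Egger, weighted median, contamination mixture), runs the sensitivity
battery, applies the reported-estimate decision rule and gates significance
at the Bonferroni-corrected family level (0.05 / 6 by default).  Stage 2
runs multivariable MR per outcome over the stage-1 survivors and classifies
them independent vs mediated.  Stage 3 quantifies, for every mediated
survivor, the proportion of its effect carried by each other survivor singly
and by all of them jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import PhenotypePanel, harmonize
from .instruments import InstrumentSelectionConfig, clump, select_genomewide, strength_report
from .mediation import build_chain, proportion_mediated
from .mvmr import classify_independence, mvmr_ivw
from .robustness import assess_sensitivity, decide_reported, presso
from .univariable import MREstimate, contamination_mixture, egger, ivw, weighted_median

log = logging.getLogger(__name__)


def bonferroni_threshold(alpha_family: float, n_comparisons: int) -> float:
    """Familywise threshold alpha / n; the study default 0.05 / 6 = 8.33e-3."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha_family / n_comparisons


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (report display convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


@dataclass
class StudyConfig:
    alpha_family: float = 0.05
    n_comparisons: int = 6
    seed: int = 0
    selection: InstrumentSelectionConfig = field(default_factory=InstrumentSelectionConfig)
    n_boot: int = 1000
    presso_nsim: int = 1000
    sensitivity_alpha: float = 0.05
    mvmr_alpha: float | None = None  # defaults to the Bonferroni threshold
    sd_phenotype: float = 1.0

    @property
    def p_reported(self) -> float:
        return bonferroni_threshold(self.alpha_family, self.n_comparisons)

    @property
    def alpha_independence(self) -> float:
        return self.mvmr_alpha if self.mvmr_alpha is not None else self.p_reported


@dataclass
class StudyReport:
    univariable: pd.DataFrame  # one row per pair x method
    sensitivity: pd.DataFrame  # one row per pair: Q, Egger intercept, PRESSO, decision
    mvmr: pd.DataFrame  # one row per outcome x survivor
    mediation: pd.DataFrame  # one row per (outcome, exposure, mediator set)
    partitions: dict  # outcome -> {"independent": [...], "mediated": [...]}
    notes: list = field(default_factory=list)


def _est_row(outcome, exposure, est: MREstimate) -> dict:
    or_, lo, hi = est.or_view
    return {
        "outcome": outcome,
        "exposure": exposure,
        "method": est.method,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "odds_ratio": or_,
        "or_ci_low": lo,
        "or_ci_high": hi,
        "n_snp": est.n_snp,
    }


def run_study(
    cfg: StudyConfig,
    exposure_panels: dict[str, PhenotypePanel],
    outcome_panels: dict[str, PhenotypePanel],
    ld_r2=None,
) -> StudyReport:
    """Run the full univariable -> multivariable -> mediation design.

    Deterministic given ``cfg.seed``; per-pair seeds are spawned in sorted
    (outcome, exposure) order.  Stages with empty inputs are skipped with a
    note rather than an error.
    """
    rng_root = np.random.SeedSequence(cfg.seed)
    uni_rows: list[dict] = []
    sens_rows: list[dict] = []
    mvmr_rows: list[dict] = []
    med_rows: list[dict] = []
    notes: list[str] = []
    partitions: dict = {}
    threshold = cfg.p_reported

    selected: dict[str, PhenotypePanel] = {}
    for e in sorted(exposure_panels):
        sel = select_genomewide(exposure_panels[e], cfg.selection)
        if ld_r2 is not None and len(sel):
            sel = clump(sel, ld_r2, cfg.selection)
        if len(sel):
            rep = strength_report(sel, cfg.sd_phenotype)
            if not rep.passes:
                notes.append(f"{e}: aggregate F = {rep.f_stat:.1f} <= 10 (weak instruments)")
        selected[e] = sel

    survivors: dict[str, list[str]] = {}
    for o in sorted(outcome_panels):
        survivors[o] = []
        for e in sorted(exposure_panels):
            seed_pair = int(rng_root.spawn(1)[0].generate_state(1)[0] % (2**31))
            sel = selected[e]
            if len(sel) == 0:
                notes.append(f"stage1 skipped for {e} x {o}: no instruments")
                continue
            h = harmonize(sel, outcome_panels[o])
            if h.n_snp == 0:
                notes.append(f"stage1 skipped for {e} x {o}: no harmonized SNPs")
                continue
            ivw_est = ivw(h, model="random")
            wm = weighted_median(h, n_boot=cfg.n_boot, seed=seed_pair) if h.n_snp >= 3 else None
            eg = egger(h) if h.n_snp >= 3 else None
            cm = contamination_mixture(h) if h.n_snp >= 2 else None
            het = assess_sensitivity(h, cfg.sensitivity_alpha)
            pr = (
                presso(h, n_sim=cfg.presso_nsim, seed=seed_pair + 1)
                if h.n_snp >= 4
                else None
            )

            uni_rows.append(_est_row(o, e, ivw_est))
            for est in filter(None, [wm, cm.estimate if cm else None]):
                uni_rows.append(_est_row(o, e, est))
            if eg:
                uni_rows.append(_est_row(o, e, eg[0]))
                uni_rows.append(_est_row(o, e, eg[1]))

            decision = decide_reported(ivw_est, wm or ivw_est, het, pr)
            reported = {
                "ivw": ivw_est,
                "weighted_median": wm or ivw_est,
                "presso_corrected": (pr.corrected_estimate if pr and pr.corrected_estimate else ivw_est),
            }[decision.chosen_method]
            significant = reported.pvalue < threshold
            if significant:
                survivors[o].append(e)
            sens_rows.append(
                {
                    "outcome": o,
                    "exposure": e,
                    "q_stat": het.q_stat,
                    "q_pvalue": het.q_pvalue,
                    "egger_intercept_p": het.egger_intercept_p,
                    "presso_global_p": pr.global_p if pr else np.nan,
                    "presso_n_outliers": len(pr.outlier_snps) if pr else 0,
                    "chosen_method": decision.chosen_method,
                    "rationale": decision.rationale,
                    "reported_beta": reported.beta,
                    "reported_se": reported.se,
                    "reported_p": reported.pvalue,
                    "significant": significant,
                    "threshold": threshold,
                }
            )

    for o in sorted(outcome_panels):
        surv = survivors[o]
        if not surv:
            notes.append(f"stage2 skipped for {o}: zero stage-1 survivors")
            partitions[o] = {"independent": [], "mediated": []}
            continue
        union: set[str] = set()
        for e in surv:
            union |= set(selected[e].snp_ids)
        ref = exposure_panels[surv[0]].subset(union & set(exposure_panels[surv[0]].snp_ids))
        co = [exposure_panels[e] for e in surv[1:]] + [outcome_panels[o]]
        h_mv = harmonize(ref, co)
        mv = mvmr_ivw(h_mv, surv)
        part = classify_independence(surv, mv, cfg.alpha_independence)
        partitions[o] = part
        for e in surv:
            b, s = mv.estimate(e)
            mvmr_rows.append(
                {
                    "outcome": o,
                    "exposure": e,
                    "beta": b,
                    "se": s,
                    "ci_low": b - 1.959963984540054 * s,
                    "ci_high": b + 1.959963984540054 * s,
                    "pvalue": mv.pvalue(e),
                    "odds_ratio": float(np.exp(b)),
                    "n_snp": mv.n_snp,
                    "classification": "independent" if e in part["independent"] else "mediated",
                }
            )

        for e in part["mediated"]:
            mediators = {m: exposure_panels[m] for m in surv if m != e}
            if not mediators:
                notes.append(f"stage3 skipped for {e} x {o}: no candidate mediators")
                continue
            subsets = [[m] for m in mediators]
            if len(mediators) > 1:
                subsets.append(list(mediators))
            for sub in subsets:
                chain = build_chain(
                    exposure_panels[e], mediators, outcome_panels[o],
                    cfg.selection, ld_r2, mediator_subset=sub,
                )
                res = proportion_mediated(chain)
                med_rows.append(
                    {
                        "outcome": o,
                        "exposure": e,
                        "mediators": "+".join(sub),
                        "beta3_adjusted": chain.beta3,
                        "se3": chain.se3,
                        "or_adjusted": float(np.exp(chain.beta3)),
                        "indirect": res.indirect,
                        "total": res.total,
                        "proportion_pct": res.proportion,
                        "proportion_se": res.se,
                        "ci_low_pct": res.ci_low,
                        "ci_high_pct": res.ci_high,
                    }
                )
    if not med_rows:
        notes.append("stage3 produced no mediation rows")
    return StudyReport(
        univariable=pd.DataFrame(uni_rows),
        sensitivity=pd.DataFrame(sens_rows),
        mvmr=pd.DataFrame(mvmr_rows),
        mediation=pd.DataFrame(med_rows),
        partitions=partitions,
        notes=notes,
    )
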