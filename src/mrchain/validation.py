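"""Simulation studies validating estimator calibration and study-level recovery.

Each function runs a self-contained, seeded experiment against the synthetic
generator (or directly simulated harmonized sets where allele bookkeeping is
irrelevant) and returns the measured quantity: coverage rates, robustness to
planted contamination, MR-PRESSO outlier sensitivity, Cochran's Q test size,
mediation recovery and end-to-end study partition accuracy.  The same
routines back both the test suite and the reproduction script, so reported
numbers always come from a fresh run of the estimators.

Scenario scales mirror the emulated GWAS setting: exposure panels of several
hundred thousand samples, a case-control outcome in the tens of thousands,
instrument counts inside the 14-507 range, per-SNP effects large enough to
pass genome-wide significance.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm

from .gwas_io import HarmonizedSet, harmonize
from .instruments import select_genomewide
from .mediation import build_chain, proportion_mediated, proportion_mediated_mc
from .mvmr import mvmr_ivw
from .pipeline import StudyConfig, run_study
from .robustness import cochran_q, presso
from .synthetic import (
    default_study_config,
    mediation_config,
    simulate_panels,
    two_trait_config,
)
from .univariable import contamination_mixture, egger, ivw, weighted_median


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# independently coded weighted-least-squares oracles (normal equations for the
# statsmodels-backed fits, statsmodels for the hand-coded IVW)

def ivw_oracle(h: HarmonizedSet) -> tuple[float, float]:
    """Fixed-effects IVW via statsmodels WLS through the origin."""
    w = 1.0 / h.se_y**2
    res = sm.WLS(h.beta_y, h.beta_x[:, None], weights=w).fit()
    se_fixed = float(res.bse[0] / np.sqrt(res.scale))
    return float(res.params[0]), se_fixed


def egger_oracle(h: HarmonizedSet) -> tuple[float, float]:
    """(intercept, slope) by hand-solved weighted normal equations."""
    sign = np.where(h.beta_x < 0, -1.0, 1.0)
    bx, by = h.beta_x * sign, h.beta_y * sign
    w = 1.0 / h.se_y**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtw = X.T * w
    params = np.linalg.solve(xtw @ X, xtw @ by)
    return float(params[0]), float(params[1])


def mvmr_oracle(h: HarmonizedSet, exposure_ids: list[str]) -> np.ndarray:
    """MVMR coefficients by hand-solved weighted normal equations."""
    X = np.column_stack([h.beta(e) for e in exposure_ids])
    w = 1.0 / h.se_y**2
    xtw = X.T * w
    return np.linalg.solve(xtw @ X, xtw @ h.beta_y)


def oracle_agreement(seed: int, k: int = 10) -> float:
    """Worst relative disagreement between the estimators and the independent
    WLS oracles on a k-SNP two-exposure fixture (should be ~1e-12)."""
    rng = np.random.default_rng(seed)
    bx1 = rng.uniform(0.02, 0.08, k) * rng.choice([-1, 1], k)
    bx2 = rng.uniform(0.02, 0.08, k) * rng.choice([-1, 1], k)
    sy = rng.uniform(0.005, 0.02, k)
    by = 0.3 * bx1 - 0.2 * bx2 + rng.normal(0, sy)
    h2 = HarmonizedSet.from_arrays(bx1, 0.002, by, sy)
    table = h2.table.copy()
    table.insert(6, "beta_m", bx2)
    table.insert(7, "se_m", np.full(k, 0.002))
    table.insert(8, "eaf_m", 0.5)
    table.insert(9, "n_m", 0)
    h3 = HarmonizedSet(["exposure", "m", "outcome"], table, h2.alignment_log)

    rel = []
    est = ivw(h2, model="fixed")
    ob, ose = ivw_oracle(h2)
    rel += [abs(est.beta - ob) / abs(ob), abs(est.se - ose) / ose]
    slope, intercept = egger(h2)
    oi, osl = egger_oracle(h2)
    rel += [abs(slope.beta - osl) / abs(osl), abs(intercept.beta - oi) / max(abs(oi), 1e-12)]
    mv = mvmr_ivw(h3, ["exposure", "m"])
    om = mvmr_oracle(h3, ["exposure", "m"])
    rel += list(np.abs(mv.betas - om) / np.abs(om))
    return float(max(rel))


# ---------------------------------------------------------------------------
# estimator recovery and CI calibration

def point_recovery(seed: int, effect: float = 0.4) -> dict:
    """Point estimates and SEs of all four estimators on one seeded default
    dataset with a planted causal effect."""
    panels, _ = simulate_panels(two_trait_config(seed=seed, effect=effect))
    h = harmonize(select_genomewide(panels["exposure"]), panels["lung_cancer"])
    out = {}
    est = ivw(h)
    out["ivw"] = (est.beta, est.se)
    slope, _ = egger(h)
    out["egger"] = (slope.beta, slope.se)
    wm = weighted_median(h, seed=seed)
    out["weighted_median"] = (wm.beta, wm.se)
    cm = contamination_mixture(h).estimate
    out["conmix"] = (cm.beta, cm.se)
    return out


def coverage_experiment(seed: int, n_rep: int = 1000, effect: float = 0.0) -> dict:
    """Empirical 95% CI coverage of the planted effect for each estimator."""
    hits = {"ivw": 0, "egger": 0, "weighted_median": 0, "conmix": 0}
    seeds = _child_seeds(seed, n_rep)
    for s in seeds:
        panels, _ = simulate_panels(two_trait_config(seed=int(s), effect=effect))
        h = harmonize(select_genomewide(panels["exposure"]), panels["lung_cancer"])
        est = ivw(h)
        hits["ivw"] += est.ci_low <= effect <= est.ci_high
        slope, _ = egger(h)
        hits["egger"] += slope.ci_low <= effect <= slope.ci_high
        wm = weighted_median(h, seed=int(s) + 1)
        hits["weighted_median"] += wm.ci_low <= effect <= wm.ci_high
        cm = contamination_mixture(h).estimate
        hits["conmix"] += cm.ci_low <= effect <= cm.ci_high
    return {k: v / n_rep for k, v in hits.items()}


# ---------------------------------------------------------------------------
# robustness battery

def contamination_experiment(
    seed: int,
    n_rep: int = 200,
    k: int = 30,
    effect: float = 0.3,
    invalid_fraction: float = 0.4,
    ratio_shift: float = 0.5,
) -> dict:
    """Weighted median vs IVW under directional invalid instruments.

    ``invalid_fraction`` of the instruments get their Wald ratio shifted by
    about ``ratio_shift`` (directional pleiotropy).  Returns the mean
    estimates and mean reported SEs of both estimators, plus bias/SE ratios.
    """
    rng = np.random.default_rng(seed)
    n_inv = int(round(invalid_fraction * k))
    wm_est, wm_se, ivw_est, ivw_se = [], [], [], []
    for _ in range(n_rep):
        bx0 = rng.uniform(0.04, 0.08, k) * rng.choice([-1, 1], k)
        se_x = np.full(k, 0.0025)
        se_y = np.full(k, 0.0086)
        shift = np.zeros(k)
        shift[:n_inv] = rng.normal(ratio_shift, ratio_shift / 4, n_inv)
        by = (effect + shift) * bx0 + rng.normal(0, se_y)
        bx = bx0 + rng.normal(0, se_x)
        h = HarmonizedSet.from_arrays(bx, se_x, by, se_y)
        wm = weighted_median(h, seed=int(rng.integers(2**31)))
        e = ivw(h)
        wm_est.append(wm.beta)
        wm_se.append(wm.se)
        ivw_est.append(e.beta)
        ivw_se.append(e.se)
    wm_bias = abs(float(np.mean(wm_est)) - effect)
    ivw_bias = abs(float(np.mean(ivw_est)) - effect)
    return {
        "wm_bias_se_ratio": wm_bias / float(np.mean(wm_se)),
        "ivw_bias_se_ratio": ivw_bias / float(np.mean(ivw_se)),
        "wm_mean": float(np.mean(wm_est)),
        "ivw_mean": float(np.mean(ivw_est)),
    }


def presso_sensitivity(
    seed: int, n_rep: int = 200, k_clean: int = 30, n_sim: int = 1000, ratio_shift: float = 1.0
) -> float:
    """Fraction of replicates in which the single planted outlier (Wald ratio
    shifted by ``ratio_shift``) is flagged by the MR-PRESSO outlier test."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        k = k_clean + 1
        bx0 = rng.uniform(0.05, 0.08, k) * rng.choice([-1, 1], k)
        se_x = np.full(k, 0.0025)
        se_y = np.full(k, 0.0086)
        by = 0.3 * bx0 + rng.normal(0, se_y)
        by[0] += ratio_shift * bx0[0]
        bx = bx0 + rng.normal(0, se_x)
        h = HarmonizedSet.from_arrays(bx, se_x, by, se_y)
        res = presso(h, n_sim=n_sim, seed=int(rng.integers(2**31)))
        hits += h.snp_ids[0] in res.outlier_snps
    return hits / n_rep


def q_type1_error(seed: int, n_rep: int = 2000, k: int = 50, effect: float = 0.0) -> float:
    """Rejection rate of Cochran's Q at alpha = 0.05 under homogeneous effects."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        bx0 = rng.uniform(0.015, 0.08, k) * rng.choice([-1, 1], k)
        se_x = np.full(k, 0.0025)
        se_y = np.full(k, 0.0086)
        by = effect * bx0 + rng.normal(0, se_y)
        bx = bx0 + rng.normal(0, se_x)
        h = HarmonizedSet.from_arrays(bx, se_x, by, se_y)
        rejections += cochran_q(h).q_pvalue < 0.05
    return rejections / n_rep


# ---------------------------------------------------------------------------
# mediation and end-to-end recovery

def mediation_recovery(seed: int, n_mc: int = 100_000) -> dict:
    """Proportion mediated on a planted exposure->mediator->outcome chain with
    zero direct effect (truth: 100%), plus the delta-method / Monte-Carlo SE
    ratio."""
    panels, _ = simulate_panels(mediation_config(seed=seed))
    chain = build_chain(panels["exposure"], {"mediator": panels["mediator"]}, panels["lung_cancer"])
    res = proportion_mediated(chain)
    _, mc_sd = proportion_mediated_mc(chain, n_draw=n_mc, seed=seed + 1)
    return {
        "proportion_pct": res.proportion,
        "se_pct": res.se,
        "se_ratio_delta_vs_mc": res.se / mc_sd,
        "beta3": chain.beta3,
        "beta3_se": chain.se3,
    }


def partition_accuracy(seed: int, n_rep: int = 100) -> float:
    """Fraction of replicates where the full three-stage study reproduces the
    planted independent/mediated partition of the default 4-exposure DAG."""
    truth_part = {"independent": {"education", "smoking"}, "mediated": {"bmi", "income"}}
    seeds = _child_seeds(seed, n_rep)
    hits = 0
    for s in seeds:
        cfg = default_study_config(seed=int(s))
        panels, _ = simulate_panels(cfg)
        exposures = {t: panels[t] for t in cfg.trait_ids}
        outcomes = {cfg.outcome_id: panels[cfg.outcome_id]}
        report = run_study(StudyConfig(seed=int(s)), exposures, outcomes)
        part = report.partitions[cfg.outcome_id]
        hits += (
            set(part["independent"]) == truth_part["independent"]
            and set(part["mediated"]) == truth_part["mediated"]
        )
    return hits / n_rep
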