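"""Heterogeneity and pleiotropy diagnostics plus the reported-estimate decision.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
fixed-effects IVW estimate; the MR-Egger intercept tests average directional
pleiotropy; MR-PRESSO is a simulation-based global pleiotropy test with a
per-SNP outlier test and a distortion test of the outlier-corrected IVW
estimate.  The decision rule selects which estimate a study reports:

  no heterogeneity, no pleiotropy          -> IVW
  heterogeneity, concordant median & IVW   -> weighted median
  pleiotropy                               -> MR-PRESSO outlier-corrected IVW
  heterogeneity, discordant directions     -> IVW flagged "discordant"
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedSet
from .univariable import MREstimate, _estimate, _ivw_core, egger, ivw


@dataclass
class HeterogeneityReport:
    q_stat: float
    df: int
    q_pvalue: float
    egger_intercept_p: float | None
    alpha: float = 0.05

    @property
    def heterogeneous(self) -> bool:
        return self.q_pvalue < self.alpha

    @property
    def pleiotropic(self) -> bool:
        return self.egger_intercept_p is not None and self.egger_intercept_p < self.alpha


def cochran_q(h: HarmonizedSet, alpha: float = 0.05) -> HeterogeneityReport:
    """Cochran's Q of the Wald ratios around the fixed-effects IVW estimate.

    Q = sum_j w_j (ratio_j - beta_ivw)^2 with w_j the inverse first-order
    ratio variance beta_xj^2 / se_yj^2; p from chi-square with k - 1 df.
    The Egger-intercept field is left unset (see :func:`assess_sensitivity`).
    """
    k = h.n_snp
    if k < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    _, _, q = _ivw_core(h.beta_x, h.beta_y, h.se_y)
    return HeterogeneityReport(
        q_stat=q,
        df=k - 1,
        q_pvalue=float(stats.chi2.sf(q, k - 1)),
        egger_intercept_p=None,
        alpha=alpha,
    )


def assess_sensitivity(h: HarmonizedSet, alpha: float = 0.05) -> HeterogeneityReport:
    """Cochran's Q plus the MR-Egger intercept test (needs >= 3 SNPs for Egger)."""
    rep = cochran_q(h, alpha)
    if h.n_snp >= 3:
        _, intercept = egger(h)
        rep.egger_intercept_p = intercept.pvalue
    return rep


@dataclass
class PressoResult:
    global_rss_obs: float
    global_p: float
    outlier_snps: dict  # snp_id -> per-SNP empirical p
    corrected_estimate: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the weighted leave-one-out residual sum of
    squares; its null distribution comes from ``n_sim`` parametric draws of
    (beta_x, beta_y) under the no-pleiotropy model.  Per-SNP outliers are
    flagged at the Bonferroni level ``outlier_alpha / k``; when outliers are
    found the IVW estimate is recomputed without them and the distortion test
    compares the before/after difference against random same-size removals.
    Empirical p-values use the (1 + exceedances) / (n_sim + 1) form, so the
    smallest reportable p is 1 / (n_sim + 1).
    """
    k = h.n_snp
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 SNPs")
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives an unusably coarse p-value floor")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    w = 1.0 / sy**2

    def loo_residuals(bx_m: np.ndarray, by_m: np.ndarray) -> np.ndarray:
        # weighted squared residual of each SNP against the IVW fit that excludes it
        s_xy = np.sum(w * bx_m * by_m, axis=-1, keepdims=True)
        s_xx = np.sum(w * bx_m**2, axis=-1, keepdims=True)
        beta_loo = (s_xy - w * bx_m * by_m) / (s_xx - w * bx_m**2)
        return w * (by_m - beta_loo * bx_m) ** 2

    res_obs = loo_residuals(bx, by)
    rss_obs = float(np.sum(res_obs))

    beta_loo_obs = (np.sum(w * bx * by) - w * bx * by) / (np.sum(w * bx**2) - w * bx**2)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(bx * beta_loo_obs, sy, size=(n_sim, k))
    res_sim = loo_residuals(bx_sim, by_sim)
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_mask = p_snp < outlier_alpha / k
    outliers = {s: float(p) for s, p, m in zip(h.snp_ids, p_snp, outlier_mask) if m}

    corrected = None
    distortion_p = None
    n_out = len(outliers)
    if n_out and k - n_out >= 2:
        keep = [s for s in h.snp_ids if s not in outliers]
        corrected = ivw(h.subset(keep), model="random")
        corrected.method = "presso_corrected"
        beta_all = ivw(h, model="random").beta
        d_obs = beta_all - corrected.beta
        # null distortion: remove random subsets of the same size
        d_sim = np.empty(n_sim)
        s_xy_full = np.sum(w * bx * by)
        s_xx_full = np.sum(w * bx**2)
        for i in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            b_sub = (s_xy_full - np.sum(w[drop] * bx[drop] * by[drop])) / (
                s_xx_full - np.sum(w[drop] * bx[drop] ** 2)
            )
            d_sim[i] = beta_all - b_sub
        distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))
    return PressoResult(
        global_rss_obs=rss_obs,
        global_p=global_p,
        outlier_snps=outliers,
        corrected_estimate=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass(frozen=True)
class ReportedEstimateDecision:
    chosen_method: str  # "ivw" | "weighted_median" | "presso_corrected"
    rationale: str


def decide_reported(
    ivw_est: MREstimate,
    wmedian_est: MREstimate,
    het: HeterogeneityReport,
    presso_result: PressoResult | None = None,
) -> ReportedEstimateDecision:
    """Select the reported estimate from the sensitivity diagnostics.

    Pure rule table; raises when pleiotropy is flagged but no MR-PRESSO
    result is supplied.
    """
    if het.pleiotropic:
        if presso_result is None:
            raise ValueError("pleiotropy flagged but no MR-PRESSO result supplied")
        if presso_result.corrected_estimate is not None:
            return ReportedEstimateDecision("presso_corrected", "pleiotropy_outliers_removed")
        return ReportedEstimateDecision("presso_corrected", "pleiotropy_no_outliers_found")
    if het.heterogeneous:
        if np.sign(wmedian_est.beta) == np.sign(ivw_est.beta):
            return ReportedEstimateDecision("weighted_median", "heterogeneity_concordant")
        return ReportedEstimateDecision("ivw", "heterogeneity_discordant")
    return ReportedEstimateDecision("ivw", "no_heterogeneity_no_pleiotropy")
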