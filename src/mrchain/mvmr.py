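"""Multivariable MR: joint weighted regression of outcome effects on several
exposures' effects, and the independent-vs-mediated classification.

With instruments pooled across exposures, the outcome betas are regressed on
the m exposure-beta columns without intercept, weighted by 1/se_y^2.  Each
coefficient is the direct effect of that exposure conditional on the others;
an exposure whose conditional effect is non-significant is classified as
mediated (its univariable effect runs through the co-exposures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .gwas_io import HarmonizedSet
from .univariable import Z95


@dataclass
class MVMRResult:
    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    n_snp: int
    inflation: float

    def estimate(self, exposure_id: str) -> tuple[float, float]:
        """(beta, se) of one exposure's conditional direct effect."""
        i = self.exposures.index(exposure_id)
        return float(self.betas[i]), float(self.ses[i])

    def pvalue(self, exposure_id: str) -> float:
        return float(self.pvalues[self.exposures.index(exposure_id)])


def mvmr_ivw(h: HarmonizedSet, exposure_ids: list[str] | None = None) -> MVMRResult:
    """Multivariable IVW over the harmonized set's exposure columns.

    ``exposure_ids`` defaults to every trait but the last (the outcome).  SEs
    carry the multiplicative overdispersion inflation max(1, sigma), matching
    the univariable random-effects IVW; p-values use the normal approximation.
    Raises on a rank-deficient exposure-beta matrix, naming the collinear
    exposures.
    """
    if exposure_ids is None:
        exposure_ids = h.trait_ids[:-1]
    m = len(exposure_ids)
    k = h.n_snp
    if k <= m:
        raise ValueError(f"need more instruments ({k}) than exposures ({m})")
    X = np.column_stack([h.beta(e) for e in exposure_ids])
    y = h.beta_y
    w = 1.0 / h.se_y**2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < m:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(Xw, rowvar=False)
        pairs = [
            f"{exposure_ids[i]}~{exposure_ids[j]}"
            for i in range(m)
            for j in range(i + 1, m)
            if not np.isfinite(corr[i, j]) or abs(corr[i, j]) > 1 - 1e-10
        ]
        zero = [e for i, e in enumerate(exposure_ids) if not np.any(Xw[:, i])]
        raise ValueError(
            f"rank-deficient exposure matrix; collinear: {pairs or zero or exposure_ids}"
        )
    res = sm.WLS(y, X, weights=w).fit()
    sigma = float(np.sqrt(res.scale))
    adj = max(1.0, sigma) / sigma
    betas = np.asarray(res.params, float)
    ses = np.asarray(res.bse, float) * adj
    p = 2.0 * stats.norm.sf(np.abs(betas / ses))
    return MVMRResult(
        exposures=list(exposure_ids),
        betas=betas,
        ses=ses,
        ci_low=betas - Z95 * ses,
        ci_high=betas + Z95 * ses,
        pvalues=np.clip(p, 5e-324, 1.0),
        n_snp=k,
        inflation=max(1.0, sigma),
    )


def classify_independence(
    uv_significant: list[str], mv: MVMRResult, alpha: float
) -> dict[str, list[str]]:
    """Partition univariably significant exposures into independent vs mediated.

    An exposure is independent iff its MVMR p-value is strictly below
    ``alpha``; all other listed exposures are mediated (their effect on the
    outcome runs through co-exposures) and are handed to the mediation stage.
    """
    unknown = [e for e in uv_significant if e not in mv.exposures]
    if unknown:
        raise ValueError(f"exposures absent from MVMR result: {unknown}")
    independent = [e for e in uv_significant if mv.pvalue(e) < alpha]
    mediated = [e for e in uv_significant if e not in independent]
    return {"independent": independent, "mediated": mediated}
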