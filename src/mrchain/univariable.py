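"""Univariable two-sample MR estimators.

All estimators consume a :class:`~mrchain.gwas_io.HarmonizedSet` whose first
trait is the exposure and last trait the outcome.  The per-SNP building block
is the Wald ratio beta_y / beta_x; the inverse-variance weighted (IVW)
estimate is the 1/se_y^2-weighted regression of beta_y on beta_x through the
origin, equivalently the inverse-variance weighted mean of the Wald ratios.
MR-Egger adds a free intercept (average directional pleiotropy); the weighted
median is consistent with up to 50% invalid instruments; the contamination
mixture classifies each SNP as valid or invalid by profile likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .gwas_io import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))

#: default replicate count and seed for the weighted-median parametric bootstrap
DEFAULT_N_BOOT = 1000
DEFAULT_BOOT_SEED = 20_230_101


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds (or continuous-outcome) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    info: dict = field(default_factory=dict)

    @property
    def or_view(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) — exp-transformed view for binary outcomes."""
        return (float(np.exp(self.beta)), float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))


def _estimate(method, beta, se, n_snp, dist="norm", df=None, **info) -> MREstimate:
    beta = float(beta)
    se = float(se)
    if dist == "t":
        crit = float(stats.t.ppf(0.975, df))
        p = float(2.0 * stats.t.sf(abs(beta / se), df)) if se > 0 else 0.0
    else:
        crit = Z95
        p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - crit * se,
        ci_high=beta + crit * se,
        pvalue=min(max(p, 5e-324), 1.0),
        n_snp=n_snp,
        info=info,
    )


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float, second_order: bool = False
) -> MREstimate:
    """Single-SNP causal estimate beta_y / beta_x.

    The default SE is the first-order delta-method se_y / |beta_x|; with
    ``second_order=True`` the exposure uncertainty term
    beta_y^2 * se_x^2 / beta_x^4 is added under the square root.
    """
    if beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0")
    ratio = beta_y / beta_x
    var = se_y**2 / beta_x**2
    if second_order:
        var += beta_y**2 * se_x**2 / beta_x**4
    return _estimate("wald", ratio, np.sqrt(var), 1, second_order=second_order)


def _ivw_core(bx: np.ndarray, by: np.ndarray, se_y: np.ndarray):
    """Closed-form weighted regression through the origin; returns (beta, se_fixed, Q)."""
    w = 1.0 / se_y**2
    s_xx = float(np.sum(w * bx**2))
    if s_xx == 0:
        raise ValueError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by)) / s_xx
    se_fixed = float(np.sqrt(1.0 / s_xx))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate.

    ``model="fixed"`` uses the nominal weighted-regression SE;
    ``model="random"`` (default) multiplies it by max(1, sqrt(Q / (k - 1))),
    the multiplicative random-effects inflation.  One SNP degrades to the
    Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = h.n_snp
    if k == 0:
        raise ValueError("empty harmonized set")
    bx, by, se_y = h.beta_x, h.beta_y, h.se_y
    if k == 1:
        est = wald_ratio(bx[0], h.se_x[0], by[0], se_y[0])
        est.method = f"ivw_{model}"
        return est
    beta, se_fixed, q = _ivw_core(bx, by, se_y)
    se = se_fixed
    inflation = 1.0
    if model == "random":
        inflation = max(1.0, np.sqrt(q / (k - 1)))
        se = se_fixed * inflation
    return _estimate(f"ivw_{model}", beta, se, k, q=q, inflation=inflation)


def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression of beta_y on beta_x with a free intercept.

    Exposure betas are oriented non-negative first (outcome betas flipped
    with them).  Returns (slope, intercept) estimates; the slope is the
    causal effect, the intercept the average directional pleiotropy.  SEs use
    the multiplicative overdispersion max(1, sigma) and a t distribution with
    k - 2 degrees of freedom.
    """
    k = h.n_snp
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    sign = np.where(h.beta_x < 0, -1.0, 1.0)
    bx = h.beta_x * sign
    by = h.beta_y * sign
    w = 1.0 / h.se_y**2
    res = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    sigma = float(np.sqrt(res.scale))
    # statsmodels bse already carries sigma; rescale to max(1, sigma)
    adj = max(1.0, sigma) / sigma
    se_int, se_slope = res.bse[0] * adj, res.bse[1] * adj
    slope = _estimate(
        "egger_slope", res.params[1], se_slope, k, dist="t", df=k - 2, sigma=sigma
    )
    intercept = _estimate(
        "egger_intercept", res.params[0], se_int, k, dist="t", df=k - 2, sigma=sigma
    )
    return slope, intercept


def _ratio_stats(h: HarmonizedSet, second_order: bool = False):
    bx = h.beta_x
    if np.any(bx == 0):
        raise ValueError("zero exposure beta; drop the SNP before estimation")
    ratios = h.beta_y / bx
    var = h.se_y**2 / bx**2
    if second_order:
        var = var + h.beta_y**2 * h.se_x**2 / bx**4
    return ratios, np.sqrt(var)


def _weighted_median_rows(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with linear interpolation between order stats."""
    b = np.atleast_2d(b)
    w = np.atleast_2d(w)
    idx = np.argsort(b, axis=1)
    bs = np.take_along_axis(b, idx, axis=1)
    ws = np.take_along_axis(w, idx, axis=1)
    wn = ws / ws.sum(axis=1, keepdims=True)
    cum = np.cumsum(wn, axis=1) - 0.5 * wn
    j = np.sum(cum < 0.5, axis=1)
    rows = np.arange(b.shape[0])
    j_hi = np.clip(j, 0, b.shape[1] - 1)
    j_lo = np.clip(j - 1, 0, b.shape[1] - 1)
    c_hi = cum[rows, j_hi]
    c_lo = cum[rows, j_lo]
    b_hi = bs[rows, j_hi]
    b_lo = bs[rows, j_lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(c_hi > c_lo, (0.5 - c_lo) / (c_hi - c_lo), 0.0)
    out = b_lo + frac * (b_hi - b_lo)
    out = np.where(j == 0, bs[:, 0], out)
    out = np.where(j >= b.shape[1], bs[:, -1], out)
    return out


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MREstimate:
    """Weighted-median estimate with a seeded parametric-bootstrap SE.

    Wald ratios are ordered and weighted by their inverse first-order
    variance; the estimate is where cumulative weight crosses 0.5 (linear
    interpolation).  The SE is the standard deviation of the estimate over
    ``n_boot`` redraws of (beta_x, beta_y) from their sampling normals.
    """
    k = h.n_snp
    if k < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    ratios, ratio_se = _ratio_stats(h)
    w = 1.0 / ratio_se**2
    point = float(_weighted_median_rows(ratios[None, :], w[None, :])[0])

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(h.beta_x, h.se_x, size=(n_boot, k))
    by_b = rng.normal(h.beta_y, h.se_y, size=(n_boot, k))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    r_b = by_b / bx_b
    w_b = (bx_b / h.se_y) ** 2
    boots = _weighted_median_rows(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", point, se, k, n_boot=n_boot, seed=seed)


@dataclass
class ConMixResult:
    """Contamination-mixture output: estimate, SNP classification and profile."""

    estimate: MREstimate
    valid_snps: list[str]
    psi: float
    profile: "np.ndarray"  # (grid, log-likelihood) columns

    @property
    def invalid_snps(self) -> list[str]:
        valid = set(self.valid_snps)
        return [s for s in self.estimate.info["snp_ids"] if s not in valid]


def contamination_mixture(
    h: HarmonizedSet,
    psi: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 1000,
) -> ConMixResult:
    """Contamination-mixture estimate over a profile-likelihood grid.

    Each SNP's Wald ratio is modelled as valid, N(theta, se_r^2), or invalid,
    N(0, se_r^2 + psi^2); the profile log-likelihood at each candidate theta
    sums the better of the two per SNP.  The causal estimate maximizes the
    profile; the 95% CI is the chi-square(1) drop (1.92 log-likelihood units)
    region.  ``psi`` defaults to 1.5x the SD of the ratio estimates; the grid
    spans min/max ratio +/- 3 SD with ``n_grid`` points.
    """
    k = h.n_snp
    if k < 1:
        raise ValueError("empty harmonized set")
    # second-order ratio SEs: with weak instruments the first-order variance
    # understates the ratio spread and inflates spurious invalid calls
    ratios, ratio_se = _ratio_stats(h, second_order=True)
    if psi is None:
        psi = 1.5 * float(np.std(ratios, ddof=1)) if k > 1 else 1.0
    if psi <= 0:
        psi = 1e-6
    if grid is None:
        spread = float(np.std(ratios, ddof=1)) if k > 1 else float(ratio_se[0])
        spread = max(spread, 1e-12)
        grid = np.linspace(ratios.min() - 3 * spread, ratios.max() + 3 * spread, n_grid)
    grid = np.asarray(grid, float)

    ll_valid = -0.5 * ((ratios[None, :] - grid[:, None]) / ratio_se[None, :]) ** 2 - np.log(
        ratio_se[None, :]
    )
    sd_inv = np.sqrt(ratio_se**2 + psi**2)
    ll_invalid = -0.5 * (ratios / sd_inv) ** 2 - np.log(sd_inv)
    ll = np.sum(np.maximum(ll_valid, ll_invalid[None, :]), axis=1)

    imax = int(np.argmax(ll))
    if imax in (0, len(grid) - 1) and k > 1:
        raise ValueError("profile-likelihood maximum on grid boundary; widen the grid")
    beta = float(grid[imax])
    inside = grid[ll >= ll[imax] - 2.0]
    ci_low, ci_high = float(inside.min()), float(inside.max())
    se = (ci_high - ci_low) / (2.0 * Z95)
    if se <= 0:
        se = float(ratio_se.min()) / np.sqrt(k)
    est = _estimate("conmix", beta, se, k, psi=psi, snp_ids=list(h.snp_ids))
    est.ci_low, est.ci_high = ci_low, ci_high
    valid_mask = ll_valid[imax] >= ll_invalid
    valid = [s for s, v in zip(h.snp_ids, valid_mask) if v]
    return ConMixResult(
        estimate=est, valid_snps=valid, psi=float(psi), profile=np.column_stack([grid, ll])
    )
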