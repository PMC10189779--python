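"""Mediation (network) MR: the beta1/beta2/beta3 effect chain and the
proportion-mediated formula with error-propagation standard errors.

For an exposure X, mediators M_1..M_K and outcome Y:

  beta1_k  effect of X on M_k                (univariable IVW)
  beta2_k  effect of M_k on Y adjusted for X (MVMR coefficient of M_k)
  beta3    effect of X on Y adjusted for the mediator set (MVMR coefficient of X)

The proportion of the total effect carried by the mediators is

  E (%) = 100 * sum_k(beta1_k * beta2_k) / (beta3 + sum_k(beta1_k * beta2_k))

with the SE from the first-order multivariate delta method treating the
coefficients as independent (no correlation between mediators assumed).  E
and its CI may legitimately fall outside [0, 100] and are never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gwas_io import PhenotypePanel, harmonize
from .instruments import InstrumentSelectionConfig, clump, select_genomewide
from .mvmr import mvmr_ivw
from .univariable import Z95, ivw


@dataclass
class MediationChain:
    """IVW-derived regression coefficients of one exposure->mediators->outcome chain."""

    exposure_id: str
    mediator_ids: list[str]
    beta1: np.ndarray  # exposure -> mediator k
    se1: np.ndarray
    beta2: np.ndarray  # mediator k -> outcome, adjusted for the exposure
    se2: np.ndarray
    beta3: float  # exposure -> outcome, adjusted for the mediator set
    se3: float

    def __post_init__(self) -> None:
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, float))
        self.se1 = np.atleast_1d(np.asarray(self.se1, float))
        self.beta2 = np.atleast_1d(np.asarray(self.beta2, float))
        self.se2 = np.atleast_1d(np.asarray(self.se2, float))
        kk = len(self.mediator_ids)
        if not (len(self.beta1) == len(self.se1) == len(self.beta2) == len(self.se2) == kk):
            raise ValueError("beta1/beta2 arrays must have one entry per mediator")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0) or self.se3 <= 0:
            raise ValueError("all standard errors must be positive")


@dataclass
class MediationResult:
    proportion: float  # E, in percent
    se: float  # delta-method SE of E, percent
    ci_low: float
    ci_high: float
    indirect: float  # sum_k beta1_k * beta2_k
    total: float  # beta3 + indirect


def proportion_mediated(chain: MediationChain) -> MediationResult:
    """Proportion mediated E with a first-order delta-method SE.

    Gradient of E = I / (b3 + I) with I = sum_k b1k b2k:
      dE/db1k = b2k * b3 / T^2,  dE/db2k = b1k * b3 / T^2,  dE/db3 = -I / T^2
    with T = b3 + I; variance is the diagonal (independence) quadratic form.
    """
    indirect = float(np.sum(chain.beta1 * chain.beta2))
    total = chain.beta3 + indirect
    if total == 0:
        raise ValueError("total effect is zero; proportion mediated undefined")
    e = indirect / total
    g1 = chain.beta2 * chain.beta3 / total**2
    g2 = chain.beta1 * chain.beta3 / total**2
    g3 = -indirect / total**2
    var = float(np.sum(g1**2 * chain.se1**2) + np.sum(g2**2 * chain.se2**2) + g3**2 * chain.se3**2)
    se = float(np.sqrt(var))
    return MediationResult(
        proportion=100.0 * e,
        se=100.0 * se,
        ci_low=100.0 * (e - Z95 * se),
        ci_high=100.0 * (e + Z95 * se),
        indirect=indirect,
        total=total,
    )


def proportion_mediated_mc(
    chain: MediationChain, n_draw: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo cross-check of the delta method: (mean, SD) of E in percent
    over draws of the chain coefficients from their sampling normals."""
    rng = np.random.default_rng(seed)
    b1 = rng.normal(chain.beta1, chain.se1, size=(n_draw, len(chain.beta1)))
    b2 = rng.normal(chain.beta2, chain.se2, size=(n_draw, len(chain.beta2)))
    b3 = rng.normal(chain.beta3, chain.se3, size=n_draw)
    indirect = np.sum(b1 * b2, axis=1)
    e = 100.0 * indirect / (b3 + indirect)
    return float(np.mean(e)), float(np.std(e, ddof=1))


def _union_harmonized(
    reference: PhenotypePanel,
    co_panels: list[PhenotypePanel],
    outcome: PhenotypePanel,
    instrument_ids: set[str],
):
    """Harmonize the pooled instrument set across reference, co-exposures and outcome."""
    ref = reference.subset(instrument_ids & set(reference.snp_ids))
    return harmonize(ref, co_panels + [outcome])


def build_chain(
    exposure: PhenotypePanel,
    mediators: dict[str, PhenotypePanel],
    outcome: PhenotypePanel,
    cfg: InstrumentSelectionConfig = InstrumentSelectionConfig(),
    ld_r2=None,
    mediator_subset: list[str] | None = None,
) -> MediationChain:
    """Assemble the beta1/beta2/beta3 chain from raw panels.

    Instruments are genome-wide selected (and clumped when an LD matrix is
    supplied) per trait; beta2_k comes from a pairwise (exposure, mediator k)
    MVMR on the pooled instruments, beta3 from an MVMR of the exposure with
    the whole mediator subset.  All coefficients are IVW-derived.
    """
    ids = mediator_subset if mediator_subset is not None else list(mediators)
    sel_exp = select_genomewide(exposure, cfg)
    if ld_r2 is not None:
        sel_exp = clump(sel_exp, ld_r2, cfg)
    if len(sel_exp) == 0:
        raise ValueError(f"no instruments for exposure {exposure.phenotype_id}")
    sel_med: dict[str, PhenotypePanel] = {}
    for mid in ids:
        sel = select_genomewide(mediators[mid], cfg)
        if ld_r2 is not None:
            sel = clump(sel, ld_r2, cfg)
        if len(sel) == 0:
            raise ValueError(f"no instruments for mediator {mid}")
        sel_med[mid] = sel

    beta1 = np.empty(len(ids))
    se1 = np.empty(len(ids))
    beta2 = np.empty(len(ids))
    se2 = np.empty(len(ids))
    for i, mid in enumerate(ids):
        h1 = harmonize(sel_exp, mediators[mid])
        est1 = ivw(h1, model="random")
        beta1[i], se1[i] = est1.beta, est1.se
        union = set(sel_exp.snp_ids) | set(sel_med[mid].snp_ids)
        h2 = _union_harmonized(exposure, [mediators[mid]], outcome, union)
        mv = mvmr_ivw(h2, [exposure.phenotype_id, mid])
        beta2[i], se2[i] = mv.estimate(mid)

    union_all = set(sel_exp.snp_ids)
    for mid in ids:
        union_all |= set(sel_med[mid].snp_ids)
    h3 = _union_harmonized(exposure, [mediators[m] for m in ids], outcome, union_all)
    mv3 = mvmr_ivw(h3, [exposure.phenotype_id] + ids)
    beta3, se3 = mv3.estimate(exposure.phenotype_id)

    return MediationChain(
        exposure_id=exposure.phenotype_id,
        mediator_ids=list(ids),
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta3=beta3,
        se3=se3,
    )


def mediation_analysis(
    exposure: PhenotypePanel,
    mediators: dict[str, PhenotypePanel],
    outcome: PhenotypePanel,
    cfg: InstrumentSelectionConfig = InstrumentSelectionConfig(),
    ld_r2=None,
) -> dict[str, MediationResult]:
    """Per-mediator (single-mediator chains) and joint proportion mediated.

    Keys are each mediator id plus ``"joint"`` for the chain through all
    mediators simultaneously (joint beta3 adjusted for the full set).
    """
    out: dict[str, MediationResult] = {}
    for mid in mediators:
        chain = build_chain(exposure, mediators, outcome, cfg, ld_r2, mediator_subset=[mid])
        out[mid] = proportion_mediated(chain)
    if len(mediators) > 1:
        chain = build_chain(exposure, mediators, outcome, cfg, ld_r2)
        out["joint"] = proportion_mediated(chain)
    return out
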