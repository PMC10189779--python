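"""Instrument selection and instrument-strength metrics.

Genetic instruments for an exposure are SNPs passing genome-wide significance
(p < 5e-8), a minor-allele-frequency floor, and greedy LD clumping so that the
retained set is approximately independent.  Instrument strength is summarised
by the variance explained R^2 = 2 * beta^2 * EAF * (1 - EAF) / SD^2 and the
F statistic ((N - k - 1) / k) * (R^2 / (1 - R^2)); F > 10 is the conventional
weak-instrument gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import PhenotypePanel


@dataclass(frozen=True)
class InstrumentSelectionConfig:
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    maf_min: float = 0.01
    f_min: float = 10.0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "clump_window_kb", "maf_min", "f_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.clump_r2 < 1.0:
            raise ValueError("clump_r2 must lie in (0, 1)")


@dataclass
class StrengthReport:
    """Variance explained and F statistics for a selected instrument set."""

    per_snp_r2: np.ndarray
    total_r2: float
    f_stat: float
    per_snp_f: np.ndarray
    n: int
    k: int

    @property
    def passes(self) -> bool:
        return self.f_stat > 10.0


def select_genomewide(
    panel: PhenotypePanel, cfg: InstrumentSelectionConfig = InstrumentSelectionConfig()
) -> PhenotypePanel:
    """Retain records with p < p_threshold and MAF >= maf_min (strict p cutoff).

    Records with missing eaf pass the MAF filter (frequency unknown, retained
    for estimation).  An empty survivor set yields an empty panel plus a
    warning, not an error.
    """
    if len(panel) == 0:
        raise ValueError(f"panel {panel.phenotype_id} is empty")
    df = panel.df
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = (df["pval"] < cfg.p_threshold) & (maf.isna() | (maf >= cfg.maf_min))
    out = PhenotypePanel(
        panel.phenotype_id, panel.trait_type, df[keep].reset_index(drop=True), dict(panel.meta)
    )
    if len(out) == 0:
        warnings.warn(
            f"no genome-wide significant instruments for {panel.phenotype_id}", stacklevel=2
        )
    return out


def clump(
    panel: PhenotypePanel,
    ld_r2: pd.DataFrame,
    cfg: InstrumentSelectionConfig = InstrumentSelectionConfig(),
) -> PhenotypePanel:
    """Greedy LD clumping against a supplied r^2 matrix.

    Repeatedly takes the unclaimed SNP with the smallest p-value as an index
    SNP and removes every unclaimed SNP with r^2 > clump_r2 against it.
    P-value ties break lexicographically on snp id.  The kb window is not
    applied (no positions are carried; all pairs in the matrix are eligible).
    """
    snps = panel.snp_ids
    missing = [s for s in snps if s not in ld_r2.index or s not in ld_r2.columns]
    if missing:
        raise ValueError(f"SNP(s) missing from LD matrix: {missing[:5]}")
    order = panel.df.sort_values(["pval", "snp"], kind="mergesort")["snp"].tolist()
    sub = ld_r2.loc[order, order].to_numpy(float)
    claimed = np.zeros(len(order), dtype=bool)
    kept: list[str] = []
    for i, snp in enumerate(order):
        if claimed[i]:
            continue
        kept.append(snp)
        claimed |= sub[i] > cfg.clump_r2
        claimed[i] = True
    return panel.subset(kept)


def r2_explained(beta, eaf, sd: float = 1.0):
    """Variance in the phenotype explained by one SNP: 2*beta^2*(1-EAF)*EAF/SD^2.

    ``sd`` is the phenotype standard deviation; the default 1.0 corresponds to
    a standardized phenotype.  Vectorized over ``beta``/``eaf``.
    """
    sd = float(sd)
    if sd <= 0:
        raise ValueError("sd must be strictly positive")
    beta = np.asarray(beta, float)
    eaf = np.asarray(eaf, float)
    if np.any((eaf < 0) & ~np.isnan(eaf)) or np.any((eaf > 1) & ~np.isnan(eaf)):
        raise ValueError("eaf outside [0, 1]")
    return 2.0 * beta**2 * (1.0 - eaf) * eaf / sd**2


def f_statistic(total_r2: float, n: int, k: int) -> float:
    """Aggregate instrument F: ((N - k - 1) / k) * (R^2 / (1 - R^2))."""
    if not 0.0 <= total_r2 < 1.0:
        raise ValueError("total_r2 must lie in [0, 1)")
    if n <= k + 1:
        raise ValueError("require n > k + 1")
    return ((n - k - 1) / k) * (total_r2 / (1.0 - total_r2))


def strength_report(panel: PhenotypePanel, sd: float = 1.0) -> StrengthReport:
    """Per-SNP and aggregate instrument strength for a selected panel.

    SNPs with missing eaf contribute no R^2 (their per-SNP entries are NaN and
    are excluded from the total).  N is the median reported sample size.
    Per-SNP F values are computed with k = 1.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    df = panel.df
    per_r2 = np.asarray(r2_explained(df["beta"], df["eaf"], sd), float)
    total = float(np.nansum(per_r2))
    k = len(df)
    n = int(np.median(df["n"]))
    with np.errstate(invalid="ignore"):
        per_f = (np.asarray(df["n"], float) - 2.0) * per_r2 / (1.0 - per_r2)
    return StrengthReport(
        per_snp_r2=per_r2,
        total_r2=total,
        f_stat=f_statistic(total, n, k),
        per_snp_f=per_f,
        n=n,
        k=k,
    )
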