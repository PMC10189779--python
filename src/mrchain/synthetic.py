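"""Synthetic GWAS summary statistics with a known causal structure.

The generator emulates the two-sample MR setting: a directed acyclic graph of
quantitative risk factors feeding a binary outcome, with each trait measured
in its own (non-overlapping) GWAS.  Summary statistics are simulated directly
on the summary scale — per-SNP instrument effects gamma_j on their source
trait, effects on downstream traits given by summed path products, standard
errors driven by sample size through se_j = 1/sqrt(2 N eaf_j (1 - eaf_j))
(log-odds scale for the binary outcome), and optional pleiotropic outcome
effects for a configurable fraction of instruments.  A truth record captures
every simulated quantity, so estimator recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import PhenotypePanel

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"),
    ("C", "G"), ("C", "T"), ("G", "T"),
]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class DagConfig:
    """Configuration of the causal DAG and the per-trait GWAS panels.

    ``trait_ids`` lists the upstream (non-outcome) traits; ``edges`` maps
    directed pairs (source, target) — target may be the outcome — to effect
    sizes on the target's scale (log odds for the outcome).  The edge set
    must be acyclic.  ``n_snp`` gives instrument counts per upstream trait (the
    emulated studies used 14–507 instruments per risk factor);
    ``sample_sizes`` the per-trait GWAS N, with the binary outcome N given as
    cases + controls.  ``invalid_fraction`` of each trait's instruments get a
    pleiotropic outcome effect: balanced mode draws it symmetric around zero,
    directional mode centers it at ``pleiotropy_scale``.
    """

    trait_ids: tuple[str, ...]
    edges: dict
    n_snp: dict
    sample_sizes: dict
    outcome_id: str = "lung_cancer"
    n_cases: int = 11_348
    n_controls: int = 15_861
    eaf_range: tuple[float, float] = (0.05, 0.95)
    effect_range: tuple[float, float] = (0.015, 0.08)
    invalid_fraction: float = 0.0
    pleiotropy_mode: str = "balanced"
    pleiotropy_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if self.pleiotropy_mode not in ("balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        for t in self.trait_ids:
            if self.n_snp.get(t, 0) <= 0:
                raise ValueError(f"n_snp missing or non-positive for {t}")
            if self.sample_sizes.get(t, 0) <= 0:
                raise ValueError(f"sample size missing or non-positive for {t}")
        for (src, dst) in self.edges:
            nodes = set(self.trait_ids) | {self.outcome_id}
            if src not in self.trait_ids or dst not in nodes or src == dst:
                raise ValueError(f"bad edge ({src}, {dst})")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def outcome_n(self) -> int:
        return self.n_cases + self.n_controls

    def all_sample_sizes(self) -> dict:
        out = dict(self.sample_sizes)
        out[self.outcome_id] = self.outcome_n
        return out


def total_effects(cfg: DagConfig) -> dict:
    """Summed path products from every trait to every node it reaches."""
    memo: dict = {cfg.outcome_id: {}}
    visiting: set = set()

    def tot(node: str) -> dict:
        if node in memo:
            return memo[node]
        if node in visiting:
            raise ValueError(f"cycle detected through {node}")
        visiting.add(node)
        t: dict = {}
        for (a, b), eff in cfg.edges.items():
            if a != node:
                continue
            t[b] = t.get(b, 0.0) + eff
            for c, downstream in tot(b).items():
                t[c] = t.get(c, 0.0) + eff * downstream
        visiting.discard(node)
        memo[node] = t
        return t

    for node in cfg.trait_ids:
        tot(node)
    return memo


def simulate_panels(cfg: DagConfig) -> tuple[dict, dict]:
    """Simulate one panel per trait (plus the outcome) and the truth record.

    Every panel covers the union of all traits' instrument SNPs, so
    harmonization and multivariable pooling are exercised exactly as with
    real summary data.  Each panel independently re-presents alleles
    (swapped and/or strand-complemented at random), which the harmonization
    step must undo.  The truth record stores gamma, pleiotropy alpha, the
    per-node true betas and the total-effect matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    totals = total_effects(cfg)
    nodes = list(cfg.trait_ids) + [cfg.outcome_id]
    sizes = cfg.all_sample_sizes()

    snp_ids: list[str] = []
    source: list[str] = []
    for t in cfg.trait_ids:
        for j in range(cfg.n_snp[t]):
            snp_ids.append(f"rs_{t}_{j:04d}")
            source.append(t)
    m = len(snp_ids)
    source_arr = np.array(source)

    eaf = rng.uniform(*cfg.eaf_range, size=m)
    gamma = rng.uniform(*cfg.effect_range, size=m) * rng.choice([-1.0, 1.0], size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    invalid = np.zeros(m, dtype=bool)
    alpha = np.zeros(m)
    if cfg.invalid_fraction > 0:
        for t in cfg.trait_ids:
            mask = source_arr == t
            n_inv = int(round(cfg.invalid_fraction * mask.sum()))
            if n_inv:
                idx = rng.choice(np.flatnonzero(mask), size=n_inv, replace=False)
                invalid[idx] = True
        n_inv_total = int(invalid.sum())
        if cfg.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, cfg.pleiotropy_scale, size=n_inv_total)
        else:
            alpha[invalid] = rng.normal(
                cfg.pleiotropy_scale, cfg.pleiotropy_scale / 2.0, size=n_inv_total
            )

    true_beta = {}
    for node in nodes:
        tb = np.zeros(m)
        for t in cfg.trait_ids:
            mask = source_arr == t
            path = 1.0 if node == t else totals[t].get(node, 0.0)
            tb[mask] = gamma[mask] * path
        if node == cfg.outcome_id:
            tb = tb + alpha
        true_beta[node] = tb

    panels: dict[str, PhenotypePanel] = {}
    for node in nodes:
        n_t = sizes[node]
        se = 1.0 / np.sqrt(2.0 * n_t * eaf * (1.0 - eaf))
        beta_obs = true_beta[node] + rng.normal(0.0, se)
        # per-panel random allele presentation: swap and/or strand flip
        do_swap = rng.random(m) < 0.3
        do_strand = rng.random(m) < 0.2
        ea_p = np.where(do_swap, oa, ea)
        oa_p = np.where(do_swap, ea, oa)
        ea_p = np.where(do_strand, [ _COMP[a] for a in ea_p ], ea_p)
        oa_p = np.where(do_strand, [ _COMP[a] for a in oa_p ], oa_p)
        beta_p = np.where(do_swap, -beta_obs, beta_obs)
        eaf_p = np.where(do_swap, 1.0 - eaf, eaf)
        pval = np.clip(2.0 * stats.norm.sf(np.abs(beta_p) / se), 1e-300, 1.0)
        df = pd.DataFrame(
            {
                "snp": snp_ids,
                "effect_allele": ea_p,
                "other_allele": oa_p,
                "eaf": eaf_p,
                "beta": beta_p,
                "se": se,
                "pval": pval,
                "n": n_t,
            }
        )
        trait_type = "binary" if node == cfg.outcome_id else "continuous"
        panels[node] = PhenotypePanel(node, trait_type, df)

    truth = {
        "snp_ids": snp_ids,
        "source": source,
        "gamma": dict(zip(snp_ids, gamma.tolist())),
        "alpha": dict(zip(snp_ids, alpha.tolist())),
        "invalid": [s for s, v in zip(snp_ids, invalid) if v],
        "eaf": dict(zip(snp_ids, eaf.tolist())),
        "edges": {f"{a}->{b}": v for (a, b), v in cfg.edges.items()},
        "total_effects": {t: dict(totals[t]) for t in totals},
        "true_beta": {node: dict(zip(snp_ids, tb.tolist())) for node, tb in true_beta.items()},
    }
    return panels, truth


def simulate_ld_blocks(
    n_snp: int,
    block_size: int,
    within_r2: float,
    seed: int = 0,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Block-diagonal r^2 matrix: ``within_r2`` inside blocks, 0 outside, 1 on
    the diagonal.  ``snp_ids`` default to snp_0000..; ``seed`` is accepted for
    interface symmetry (the construction is deterministic)."""
    if not 0.0 <= within_r2 < 1.0:
        raise ValueError("within_r2 must lie in [0, 1)")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if snp_ids is None:
        snp_ids = [f"snp_{i:04d}" for i in range(n_snp)]
    if len(snp_ids) != n_snp:
        raise ValueError("snp_ids length must equal n_snp")
    block = np.asarray([i // block_size for i in range(n_snp)])
    mat = np.where(block[:, None] == block[None, :], within_r2, 0.0)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=snp_ids, columns=snp_ids)


def default_study_config(seed: int) -> DagConfig:
    """The documented four-exposure study scenario.

    Smoking and education act on lung cancer directly (log-OR +-0.45, odds
    ratios ~1.57 and ~0.64); BMI and income have no direct path and act only
    through those two (so multivariable MR should classify them as mediated).
    Sample sizes mirror the emulated GWAS (0.4–1.2 million for the exposures,
    an 11,348-case / 15,861-control outcome) with 150 instruments per trait.
    """
    traits = ("bmi", "income", "smoking", "education")
    edges = {
        ("smoking", "lung_cancer"): 0.45,
        ("education", "lung_cancer"): -0.45,
        ("bmi", "smoking"): 0.40,
        ("income", "education"): 0.50,
    }
    return DagConfig(
        trait_ids=traits,
        edges=edges,
        n_snp={t: 150 for t in traits},
        sample_sizes={
            "bmi": 700_000,
            "income": 397_751,
            "smoking": 1_200_000,
            "education": 1_100_000,
        },
        seed=seed,
    )


def two_trait_config(seed: int, effect: float = 0.4, n_snp: int = 150, **kwargs) -> DagConfig:
    """One exposure, one binary outcome — the estimator-validation scenario."""
    return DagConfig(
        trait_ids=("exposure",),
        edges={("exposure", "lung_cancer"): effect},
        n_snp={"exposure": n_snp},
        sample_sizes={"exposure": 400_000},
        seed=seed,
        **kwargs,
    )


def mediation_config(
    seed: int,
    direct: float = 0.0,
    via: float = 0.8,
    onward: float = 0.6,
    n_snp: int = 150,
) -> DagConfig:
    """Exposure -> mediator -> outcome chain with a configurable direct path.

    Uses a large outcome GWAS (1e5 cases / 1e5 controls) so that the
    proportion-mediated point estimate is tightly determined.
    """
    return DagConfig(
        trait_ids=("exposure", "mediator"),
        edges={
            ("exposure", "mediator"): via,
            ("mediator", "lung_cancer"): onward,
            ("exposure", "lung_cancer"): direct,
        },
        n_snp={"exposure": n_snp, "mediator": n_snp},
        sample_sizes={"exposure": 500_000, "mediator": 500_000},
        n_cases=100_000,
        n_controls=100_000,
        seed=seed,
    )
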