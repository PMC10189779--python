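"""GWAS summary-statistic containers, tab-separated I/O and allele harmonization.

Two-sample MR combines per-SNP association estimates from separate GWAS of an
exposure and an outcome.  Before any estimator runs, the panels have to be put
on a common effect allele per SNP: alleles reported swapped are sign-flipped,
alleles reported on the opposite strand are complemented, and palindromic
(A/T or C/G) SNPs whose strand cannot be resolved from allele letters are
aligned by allele frequency or dropped when the frequency is uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order used by read/write and expected on panel frames
STANDARD_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

#: default palindromic-ambiguity band on the effect-allele frequency
PALINDROME_EAF_BAND = (0.42, 0.58)


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one phenotype.

    ``beta`` is the additive per-allele effect of ``effect_allele`` on the
    phenotype (log odds ratio for a binary phenotype), ``se`` its standard
    error, ``eaf`` the effect-allele frequency and ``n`` the GWAS sample size.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive")
        if not np.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.snp_id}: pvalue outside (0, 1]")
        if self.n <= 0:
            raise ValueError(f"{self.snp_id}: sample size must be positive")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def pvalue_consistent(self, tol_log10: float = 1.0) -> bool:
        """Check the reported p-value against a two-sided normal test of beta/se.

        Records whose reported p disagrees with ``2*Phi(-|beta/se|)`` by more
        than ``tol_log10`` decades are flagged (likely unit or column errors).
        """
        z = abs(self.beta / self.se)
        expected = 2.0 * stats.norm.sf(z)
        lo = max(self.pvalue, 1e-300)
        le = max(expected, 1e-300)
        return abs(np.log10(lo) - np.log10(le)) <= tol_log10


@dataclass
class PhenotypePanel:
    """All summary statistics for one phenotype, one row per SNP."""

    phenotype_id: str
    trait_type: str  # "continuous" | "binary"
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in STANDARD_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel {self.phenotype_id}: missing columns {missing}")
        if self.df["snp"].duplicated().any():
            dups = self.df.loc[self.df["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"panel {self.phenotype_id}: duplicate snp ids {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp"].tolist()

    def record(self, snp_id: str) -> SummaryStatRecord:
        row = self.df.loc[self.df["snp"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        return _row_to_record(row.iloc[0])

    def records(self) -> Iterator[SummaryStatRecord]:
        for _, row in self.df.iterrows():
            yield _row_to_record(row)

    def subset(self, snp_ids: Iterable[str]) -> "PhenotypePanel":
        wanted = set(snp_ids)
        sub = self.df[self.df["snp"].isin(wanted)].reset_index(drop=True)
        return PhenotypePanel(self.phenotype_id, self.trait_type, sub, dict(self.meta))

    def consistency_flags(self, tol_log10: float = 1.0) -> pd.Series:
        """Boolean per SNP: True where reported p and beta/se disagree."""
        z = np.abs(self.df["beta"].to_numpy() / self.df["se"].to_numpy())
        expected = np.maximum(2.0 * stats.norm.sf(z), 1e-300)
        reported = np.maximum(self.df["pval"].to_numpy(float), 1e-300)
        bad = np.abs(np.log10(reported) - np.log10(expected)) > tol_log10
        return pd.Series(bad, index=self.df["snp"], name="inconsistent_pvalue")


def _row_to_record(row: pd.Series) -> SummaryStatRecord:
    return SummaryStatRecord(
        snp_id=str(row["snp"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        eaf=float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pvalue=float(row["pval"]),
        n=int(row["n"]),
    )


DEFAULT_COLUMN_MAP = {c: c for c in STANDARD_COLUMNS}


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    phenotype_id: str | None = None,
    trait_type: str = "continuous",
) -> PhenotypePanel:
    """Read a tab-separated summary-statistics file into a :class:`PhenotypePanel`.

    ``column_map`` maps standard names (``snp``, ``effect_allele``, ...) to the
    column names actually present in the file.  Rows with unparseable numeric
    fields are dropped; the count is stored in ``panel.meta["rows_dropped"]``.
    Missing ``eaf`` values are kept as NaN (the record is then excluded from
    frequency-based steps downstream).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [cmap[c] for c in STANDARD_COLUMNS if cmap[c] not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = raw[[cmap[c] for c in STANDARD_COLUMNS]].copy()
    df.columns = STANDARD_COLUMNS
    n_in = len(df)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # eaf may legitimately be missing; every other numeric field is mandatory
    ok = df[["beta", "se", "pval", "n"]].notna().all(axis=1)
    ok &= df["se"] > 0
    ok &= (df["pval"] > 0) & (df["pval"] <= 1)
    df = df[ok].reset_index(drop=True)
    df["n"] = df["n"].astype(int)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    dropped = n_in - len(df)
    if dropped:
        log.info("%s: dropped %d unparseable row(s)", path, dropped)
    panel = PhenotypePanel(
        phenotype_id=phenotype_id or str(path),
        trait_type=trait_type,
        df=df,
    )
    panel.meta["rows_dropped"] = dropped
    return panel


def write_summary_stats(panel: PhenotypePanel, path) -> None:
    """Write a panel as tab-separated text with the standard header.

    Floats are written with ``repr`` round-trip precision so that
    read-after-write reproduces the panel exactly.
    """
    panel.df[STANDARD_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Per-SNP effects of several phenotypes aligned to one shared effect allele.

    ``trait_ids`` is ordered; by convention the first trait is the (reference)
    exposure and the last is the outcome.  ``table`` is indexed by SNP and
    holds ``beta_<trait>``, ``se_<trait>`` and ``eaf_<trait>`` columns plus the
    shared allele pair.  ``alignment_log`` records the action taken for every
    shared SNP (kept / flipped / dropped-palindromic / dropped-mismatch).
    """

    trait_ids: list[str]
    table: pd.DataFrame
    alignment_log: pd.DataFrame
    trait_types: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(
        cls,
        beta_x,
        se_x,
        beta_y,
        se_y,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
        snp_ids: Sequence[str] | None = None,
        eaf=None,
    ) -> "HarmonizedSet":
        """Build an already-aligned two-trait set directly from effect arrays."""
        beta_x = np.asarray(beta_x, float)
        k = len(beta_x)
        if snp_ids is None:
            snp_ids = [f"snp_{i:04d}" for i in range(k)]
        eaf = np.full(k, 0.5) if eaf is None else np.asarray(eaf, float)
        table = pd.DataFrame(
            {
                "effect_allele": ["A"] * k,
                "other_allele": ["G"] * k,
                f"beta_{exposure_id}": beta_x,
                f"se_{exposure_id}": np.asarray(se_x, float),
                f"eaf_{exposure_id}": eaf,
                f"n_{exposure_id}": 0,
                f"beta_{outcome_id}": np.asarray(beta_y, float),
                f"se_{outcome_id}": np.asarray(se_y, float),
                f"eaf_{outcome_id}": eaf,
                f"n_{outcome_id}": 0,
            },
            index=pd.Index(snp_ids, name="snp"),
        )
        logdf = pd.DataFrame(
            {"snp": snp_ids, "action": "kept", "reason": "constructed from arrays"}
        )
        return cls([exposure_id, outcome_id], table, logdf)

    @property
    def snp_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def beta(self, trait_id: str) -> np.ndarray:
        return self.table[f"beta_{trait_id}"].to_numpy(float)

    def se(self, trait_id: str) -> np.ndarray:
        return self.table[f"se_{trait_id}"].to_numpy(float)

    def eaf(self, trait_id: str) -> np.ndarray:
        return self.table[f"eaf_{trait_id}"].to_numpy(float)

    # two-trait convenience surface used by the univariable estimators
    @property
    def exposure_id(self) -> str:
        return self.trait_ids[0]

    @property
    def outcome_id(self) -> str:
        return self.trait_ids[-1]

    @property
    def beta_x(self) -> np.ndarray:
        return self.beta(self.exposure_id)

    @property
    def se_x(self) -> np.ndarray:
        return self.se(self.exposure_id)

    @property
    def beta_y(self) -> np.ndarray:
        return self.beta(self.outcome_id)

    @property
    def se_y(self) -> np.ndarray:
        return self.se(self.outcome_id)

    def subset(self, snp_ids: Sequence[str]) -> "HarmonizedSet":
        keep = [s for s in self.snp_ids if s in set(snp_ids)]
        return HarmonizedSet(
            list(self.trait_ids),
            self.table.loc[keep].copy(),
            self.alignment_log[self.alignment_log["snp"].isin(keep)].reset_index(drop=True),
            dict(self.trait_types),
        )

    def to_panels(self) -> list[PhenotypePanel]:
        """Re-express the harmonized set as one aligned panel per trait."""
        panels = []
        for tid in self.trait_ids:
            df = pd.DataFrame(
                {
                    "snp": self.table.index,
                    "effect_allele": self.table["effect_allele"].to_numpy(),
                    "other_allele": self.table["other_allele"].to_numpy(),
                    "eaf": self.eaf(tid),
                    "beta": self.beta(tid),
                    "se": self.se(tid),
                    "pval": np.clip(
                        2.0 * stats.norm.sf(np.abs(self.beta(tid) / self.se(tid))), 1e-300, 1.0
                    ),
                    "n": self.table[f"n_{tid}"].to_numpy(int)
                    if f"n_{tid}" in self.table
                    else 0,
                }
            )
            panels.append(PhenotypePanel(tid, self.trait_types.get(tid, "continuous"), df))
        return panels


def harmonize(
    exposure: PhenotypePanel,
    others: PhenotypePanel | Sequence[PhenotypePanel],
    palindrome_eaf_band: tuple[float, float] = PALINDROME_EAF_BAND,
) -> HarmonizedSet:
    """Align one or more panels to the exposure panel's effect alleles.

    Per shared SNP and non-reference panel: identical alleles are kept;
    swapped alleles flip the sign of beta and replace eaf by 1-eaf;
    strand-complement alleles are complemented (optionally with a flip);
    palindromic SNPs are aligned by comparing effect-allele frequencies and
    dropped when any panel's eaf falls inside ``palindrome_eaf_band`` or is
    missing; any other allele pair is dropped as a mismatch.

    Raises ``ValueError`` when the panels share no SNPs.
    """
    if isinstance(others, PhenotypePanel):
        others = [others]
    others = list(others)
    if not others:
        raise ValueError("harmonize requires at least one non-reference panel")

    ref = exposure.df.set_index("snp")
    shared = ref.index
    frames = []
    for p in others:
        o = p.df.set_index("snp")
        shared = shared.intersection(o.index)
        frames.append(o)
    if len(shared) == 0:
        raise ValueError(
            f"no shared SNPs between {exposure.phenotype_id} and "
            f"{[p.phenotype_id for p in others]}"
        )
    shared = pd.Index([s for s in exposure.snp_ids if s in set(shared)], name="snp")

    ref = ref.loc[shared]
    band_lo, band_hi = palindrome_eaf_band
    ref_ea = ref["effect_allele"]
    ref_oa = ref["other_allele"]
    is_pal = _complement(ref_oa) == ref_ea

    ref_in_band = ref["eaf"].isna() | ((ref["eaf"] >= band_lo) & (ref["eaf"] <= band_hi))

    action = pd.Series("kept", index=shared)
    reason = pd.Series("alleles identical across panels", index=shared)

    out = pd.DataFrame(
        {
            "effect_allele": ref_ea,
            "other_allele": ref_oa,
            f"beta_{exposure.phenotype_id}": ref["beta"].astype(float),
            f"se_{exposure.phenotype_id}": ref["se"].astype(float),
            f"eaf_{exposure.phenotype_id}": ref["eaf"].astype(float),
            f"n_{exposure.phenotype_id}": ref["n"].astype(int),
        },
        index=shared,
    )

    pal = is_pal.to_numpy()
    ref_band = ref_in_band.to_numpy()
    ref_eaf = ref["eaf"].to_numpy(float)
    for p, frame in zip(others, frames):
        o = frame.loc[shared]
        ea, oa = o["effect_allele"], o["other_allele"]
        same = ((ea == ref_ea) & (oa == ref_oa)).to_numpy()
        swap = ((ea == ref_oa) & (oa == ref_ea)).to_numpy()
        csame = ((_complement(ea) == ref_ea) & (_complement(oa) == ref_oa)).to_numpy()
        cswap = ((_complement(ea) == ref_oa) & (_complement(oa) == ref_ea)).to_numpy()

        o_eaf = o["eaf"].to_numpy(float)
        drop_mismatch = ~(same | swap | csame | cswap)
        # for palindromic SNPs allele letters cannot distinguish swap from
        # strand flip: align by which side of 0.5 each panel's eaf falls on
        other_in_band = np.isnan(o_eaf) | ((o_eaf >= band_lo) & (o_eaf <= band_hi))
        drop_pal = pal & (ref_band | other_in_band) & ~drop_mismatch
        pal_ok = pal & ~drop_pal & ~drop_mismatch
        nonpal = ~pal & ~drop_mismatch
        flip = np.zeros(len(shared), dtype=bool)
        with np.errstate(invalid="ignore"):
            flip[pal_ok] = (ref_eaf[pal_ok] < 0.5) != (o_eaf[pal_ok] < 0.5)
        flip[nonpal] = (swap | cswap)[nonpal]
        strand_fixed = nonpal & (csame | cswap)

        beta = np.where(flip, -o["beta"].to_numpy(float), o["beta"].to_numpy(float))
        eaf = np.where(flip, 1.0 - o_eaf, o_eaf)
        out[f"beta_{p.phenotype_id}"] = beta
        out[f"se_{p.phenotype_id}"] = o["se"].astype(float)
        out[f"eaf_{p.phenotype_id}"] = eaf
        out[f"n_{p.phenotype_id}"] = o["n"].astype(int)

        action[drop_mismatch] = "dropped-mismatch"
        reason[drop_mismatch] = f"unresolvable alleles vs {p.phenotype_id}"
        newly_pal = drop_pal & (action != "dropped-mismatch")
        action[newly_pal] = "dropped-palindromic"
        reason[newly_pal] = f"palindromic with ambiguous eaf vs {p.phenotype_id}"
        flipped_now = flip & ~action.isin(["dropped-mismatch", "dropped-palindromic"])
        action[flipped_now & (action == "kept")] = "flipped"
        reason[flipped_now] = f"effect allele flipped to match vs {p.phenotype_id}"
        reason[strand_fixed & (action.isin(["kept", "flipped"]))] += " (strand complemented)"

    keep_mask = ~action.isin(["dropped-mismatch", "dropped-palindromic"])
    logdf = pd.DataFrame(
        {"snp": shared, "action": action.to_numpy(), "reason": reason.to_numpy()}
    ).reset_index(drop=True)
    trait_ids = [exposure.phenotype_id] + [p.phenotype_id for p in others]
    trait_types = {exposure.phenotype_id: exposure.trait_type}
    trait_types.update({p.phenotype_id: p.trait_type for p in others})
    return HarmonizedSet(trait_ids, out[keep_mask].copy(), logdf, trait_types)


def write_alignment_log(h: HarmonizedSet, path) -> None:
    h.alignment_log.to_csv(path, sep="\t", index=False)
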