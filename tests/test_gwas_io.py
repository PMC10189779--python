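"""I/O round-trips, record validation and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrchain import (
    PhenotypePanel,
    SummaryStatRecord,
    harmonize,
    read_summary_stats,
    simulate_panels,
    two_trait_config,
    write_summary_stats,
)

from conftest import make_panel


class TestSummaryStatRecord:
    def test_valid_record_accepted(self):
        r = SummaryStatRecord("rs1", "A", "G", 0.3, 0.1, 0.02, 5.7e-7, 10_000)
        assert not r.is_palindromic

    @pytest.mark.parametrize(
        "kw",
        [
            dict(effect_allele="A", other_allele="A"),
            dict(se=0.0),
            dict(se=-1.0),
            dict(eaf=1.2),
            dict(pvalue=0.0),
            dict(pvalue=1.5),
            dict(n=0),
            dict(effect_allele="N"),
        ],
    )
    def test_invalid_record_rejected(self, kw):
        base = dict(
            snp_id="rs1", effect_allele="A", other_allele="G",
            eaf=0.3, beta=0.1, se=0.02, pvalue=5.7e-7, n=10_000,
        )
        base.update(kw)
        with pytest.raises(ValueError):
            SummaryStatRecord(**base)

    def test_pvalue_consistency_flag(self):
        # z = 5 -> p ~ 5.7e-7; a reported p of 0.5 is flagged
        good = SummaryStatRecord("rs1", "A", "G", 0.3, 0.1, 0.02, 5.7e-7, 1000)
        bad = SummaryStatRecord("rs2", "A", "G", 0.3, 0.1, 0.02, 0.5, 1000)
        assert good.pvalue_consistent()
        assert not bad.pvalue_consistent()
        # default betas/ses give z = 10, 5, 2
        panel = make_panel(pval=(1.5e-23, 5.7e-7, 0.9))
        flags = panel.consistency_flags()
        assert flags.tolist() == [False, False, True]


class TestReadWrite:
    def test_well_formed_tsv_round_trip(self, tmp_path):
        panel = make_panel()
        path = tmp_path / "panel.tsv"
        write_summary_stats(panel, path)
        back = read_summary_stats(path, phenotype_id="trait")
        pd.testing.assert_frame_equal(panel.df, back.df)
        assert back.meta["rows_dropped"] == 0

    def test_unparseable_row_dropped_and_counted(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "snp\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
            "rs1\tA\tG\t0.3\t0.1\t0.01\t1e-9\t1000\n"
            "rs2\tA\tG\t0.3\t0.1\tNA\t1e-9\t1000\n"
            "rs3\tC\tT\t0.4\t-0.2\t0.02\t1e-8\t1000\n"
        )
        panel = read_summary_stats(path)
        assert len(panel) == 2
        assert panel.meta["rows_dropped"] == 1

    def test_missing_eaf_kept_as_nan(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "snp\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
            "rs1\tA\tG\tNA\t0.1\t0.01\t1e-9\t1000\n"
        )
        panel = read_summary_stats(path)
        assert len(panel) == 1
        assert np.isnan(panel.df["eaf"].iloc[0])

    def test_missing_mandatory_column_named(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("snp\teffect_allele\tother_allele\teaf\tse\tpval\tn\nrs1\tA\tG\t0.3\t0.01\t1e-9\t1000\n")
        with pytest.raises(ValueError, match="beta"):
            read_summary_stats(path)

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "SNP\tA1\tA2\tfreq\tb\tstderr\tp\tN\n" "rs1\ta\tg\t0.3\t0.1\t0.01\t1e-9\t1000\n"
        )
        cmap = dict(snp="SNP", effect_allele="A1", other_allele="A2", eaf="freq",
                    beta="b", se="stderr", pval="p", n="N")
        panel = read_summary_stats(path, column_map=cmap)
        assert panel.snp_ids == ["rs1"]
        assert panel.df["effect_allele"].iloc[0] == "A"  # uppercased

    def test_duplicate_snp_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_panel(snp=("rs1", "rs1", "rs3"))


class TestHarmonize:
    def test_identical_alleles_kept_unchanged(self):
        exp = make_panel("exp", snp=("rs1",), effect_allele=("A",), other_allele=("G",),
                         eaf=(0.3,), beta=(0.1,))
        out = make_panel("out", snp=("rs1",), effect_allele=("A",), other_allele=("G",),
                         eaf=(0.3,), beta=(0.05,))
        h = harmonize(exp, out)
        assert h.n_snp == 1
        assert h.beta("out")[0] == pytest.approx(0.05)
        assert h.alignment_log["action"].tolist() == ["kept"]

    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = make_panel("exp", snp=("rs1",), effect_allele=("A",), other_allele=("G",),
                         eaf=(0.3,), beta=(0.1,))
        out = make_panel("out", snp=("rs1",), effect_allele=("G",), other_allele=("A",),
                         eaf=(0.3,), beta=(0.05,))
        h = harmonize(exp, out)
        assert h.beta("out")[0] == pytest.approx(-0.05)
        assert h.eaf("out")[0] == pytest.approx(0.7)
        assert h.alignment_log["action"].tolist() == ["flipped"]

    def test_strand_complement_resolved(self):
        # outcome reports T/C = complement of exposure's A/G: keep, no flip
        exp = make_panel("exp", snp=("rs1",), effect_allele=("A",), other_allele=("G",),
                         eaf=(0.3,), beta=(0.1,))
        out = make_panel("out", snp=("rs1",), effect_allele=("T",), other_allele=("C",),
                         eaf=(0.3,), beta=(0.05,))
        h = harmonize(exp, out)
        assert h.beta("out")[0] == pytest.approx(0.05)

    def test_mismatched_alleles_dropped(self):
        exp = make_panel("exp", snp=("rs1",), effect_allele=("A",), other_allele=("G",))
        out = make_panel("out", snp=("rs1",), effect_allele=("A",), other_allele=("C",))
        h = harmonize(exp, out)
        assert h.n_snp == 0
        assert h.alignment_log["action"].tolist() == ["dropped-mismatch"]

    def test_palindromic_band_rule_exhaustive(self):
        """Band rule over a 10-SNP A/T fixture checked against an explicit oracle."""
        eafs = [0.05, 0.15, 0.25, 0.35, 0.42, 0.50, 0.58, 0.65, 0.80, 0.95]
        snps = [f"rs{i}" for i in range(10)]
        exp = make_panel("exp", snp=snps, effect_allele=["A"] * 10, other_allele=["T"] * 10,
                         eaf=eafs, beta=[0.1] * 10, se=[0.01] * 10)
        out = make_panel("out", snp=snps, effect_allele=["A"] * 10, other_allele=["T"] * 10,
                         eaf=eafs, beta=[0.05] * 10, se=[0.01] * 10)
        h = harmonize(exp, out, palindrome_eaf_band=(0.42, 0.58))
        expected_dropped = {s for s, f in zip(snps, eafs) if 0.42 <= f <= 0.58}
        log = h.alignment_log.set_index("snp")["action"]
        for s, f in zip(snps, eafs):
            if s in expected_dropped:
                assert log[s] == "dropped-palindromic"
            else:
                assert log[s] == "kept"  # same-side eafs, no flip
        assert set(h.snp_ids) == set(snps) - expected_dropped

    def test_palindromic_opposite_eaf_flipped(self):
        exp = make_panel("exp", snp=("rs1",), effect_allele=("A",), other_allele=("T",),
                         eaf=(0.2,), beta=(0.1,))
        out = make_panel("out", snp=("rs1",), effect_allele=("A",), other_allele=("T",),
                         eaf=(0.8,), beta=(0.05,))
        h = harmonize(exp, out)
        assert h.beta("out")[0] == pytest.approx(-0.05)
        assert h.eaf("out")[0] == pytest.approx(0.2)

    def test_empty_intersection_raises(self):
        exp = make_panel("exp", snp=("rs1",), effect_allele=("A",), other_allele=("G",))
        out = make_panel("out", snp=("rs9",), effect_allele=("A",), other_allele=("G",))
        with pytest.raises(ValueError, match="no shared SNPs"):
            harmonize(exp, out)

    def test_idempotent_on_simulated_panels(self):
        panels, _ = simulate_panels(two_trait_config(seed=42, n_snp=60))
        h1 = harmonize(panels["exposure"], panels["lung_cancer"])
        exp2, out2 = h1.to_panels()
        h2 = harmonize(exp2, out2)
        assert h2.n_snp == h1.n_snp
        np.testing.assert_allclose(h2.beta_x, h1.beta_x)
        np.testing.assert_allclose(h2.beta_y, h1.beta_y)
        assert (h2.alignment_log["action"] == "kept").all()

    def test_allele_relabel_invariance(self):
        """Swapping both panels' allele labels leaves Wald ratios unchanged."""
        panels, _ = simulate_panels(two_trait_config(seed=7, n_snp=60))
        h1 = harmonize(panels["exposure"], panels["lung_cancer"])

        def relabel(panel):
            df = panel.df.copy()
            df[["effect_allele", "other_allele"]] = df[["other_allele", "effect_allele"]].to_numpy()
            df["beta"] = -df["beta"]
            df["eaf"] = 1.0 - df["eaf"]
            return PhenotypePanel(panel.phenotype_id, panel.trait_type, df)

        h2 = harmonize(relabel(panels["exposure"]), relabel(panels["lung_cancer"]))
        assert h1.snp_ids == h2.snp_ids
        np.testing.assert_allclose(h1.beta_y / h1.beta_x, h2.beta_y / h2.beta_x, rtol=1e-12)
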