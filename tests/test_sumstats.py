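"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pytest

from drugmr.errors import EmptyDatasetError, EmptyIntersectionError, FormatError
from drugmr.sumstats import (
    AssociationRecord,
    SummaryDataset,
    Variant,
    harmonize,
    read_sumstats,
    write_sumstats,
)

from conftest import make_dataset, make_record


def write_ma(path, rows):
    header = "SNP A1 A2 freq b se p N"
    path.write_text("\n".join([header] + rows) + "\n")


class TestVariant:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError):
            Variant("1", 100, "rs1", "A", "A")

    def test_rejects_eaf_outside_unit_interval(self):
        with pytest.raises(ValueError):
            Variant("1", 100, "rs1", "A", "G", eaf=1.2)

    def test_key_ignores_allele_order(self):
        a = Variant("1", 100, "rs1", "A", "G")
        b = Variant("1", 100, "rs1", "G", "A")
        assert a.key == b.key

    def test_palindrome_detection(self):
        assert Variant("1", 1, "x", "A", "T").is_palindromic
        assert Variant("1", 1, "x", "C", "G").is_palindromic
        assert not Variant("1", 1, "x", "A", "G").is_palindromic


class TestAssociationRecord:
    def test_nonpositive_se_rejected(self):
        from conftest import make_variant
        with pytest.raises(ValueError):
            AssociationRecord(variant=make_variant(1), beta=0.1, se=0.0,
                              pvalue=0.5, n=100)

    def test_inconsistent_pvalue_warns_not_fails(self):
        from conftest import make_variant
        with pytest.warns(UserWarning):
            AssociationRecord(variant=make_variant(1), beta=0.1, se=0.02,
                              pvalue=0.9, n=100)


class TestReadWrite:
    def test_three_row_file_parses_to_three_records(self, tmp_path):
        f = tmp_path / "x.ma"
        write_ma(f, [
            "1:100 A G 0.3 0.12 0.02 1.9e-9 50000",
            "1:200 C T 0.2 -0.05 0.01 5.7e-7 50000",
            "1:300 G A 0.45 0.01 0.02 0.62 50000",
        ])
        ds = read_sumstats(f)
        assert len(ds) == 3
        assert ds.load_report.rows_in == 3
        assert ds.load_report.rows_kept == 3

    def test_round_trip_preserves_records(self, tmp_path):
        ds = make_dataset([make_record(100 + i, beta=0.1 * (i + 1) / 3,
                                       se=0.02, n=9000) for i in range(4)])
        f = tmp_path / "rt.ma"
        write_sumstats(ds, f)
        back = read_sumstats(f)
        assert len(back) == len(ds)
        for key, rec in ds.records.items():
            got = back.records[key]
            assert got.beta == pytest.approx(rec.beta, rel=1e-6)
            assert got.se == pytest.approx(rec.se, rel=1e-6)
            assert got.variant.eaf == pytest.approx(rec.variant.eaf, rel=1e-6)

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        f = tmp_path / "bad.ma"
        write_ma(f, [
            "1:100 A G 0.3 0.12 0.02 1e-9 50000",
            "1:200 C T 0.2 0.05 0.0 0.5 50000",
        ])
        ds = read_sumstats(f)
        assert len(ds) == 1
        rep = ds.load_report
        assert rep.rows_rejected == 1
        assert rep.reasons["nonpositive_se"] == 1
        assert rep.rows_in == rep.rows_kept + rep.rows_rejected

    def test_missing_column_names_the_column(self, tmp_path):
        f = tmp_path / "noc.ma"
        f.write_text("SNP A1 A2 freq b p N\n1:100 A G 0.3 0.1 1e-4 100\n")
        with pytest.raises(FormatError, match="se"):
            read_sumstats(f)

    def test_empty_file_raises(self, tmp_path):
        f = tmp_path / "empty.ma"
        f.write_text("SNP A1 A2 freq b se p N\n")
        with pytest.raises(EmptyDatasetError):
            read_sumstats(f)

    def test_missing_p_recomputed_from_z(self, tmp_path):
        f = tmp_path / "nop.ma"
        f.write_text("SNP A1 A2 freq b se p N\n1:100 A G 0.3 0.1 0.05 NA 100\n")
        ds = read_sumstats(f)
        rec = next(iter(ds))
        import scipy.stats as st
        assert rec.pvalue == pytest.approx(2 * st.norm.sf(2.0), rel=1e-9)

    def test_write_empty_dataset_refused(self, tmp_path):
        with pytest.raises(EmptyDatasetError):
            write_sumstats(SummaryDataset("t"), tmp_path / "never.ma")


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = make_dataset([make_record(100, 0.2, 0.02, ea="A", oa="G")])
        out = make_dataset([make_record(100, 0.1, 0.02, ea="G", oa="A",
                                        eaf=0.7)], trait_id="out")
        df = harmonize(exp, out)
        assert df.loc[0, "beta_y"] == pytest.approx(-0.1)
        assert df.loc[0, "eaf_y"] == pytest.approx(0.3)
        assert bool(df.loc[0, "flipped"])

    def test_identical_coding_unchanged(self):
        exp = make_dataset([make_record(100, 0.2, 0.02)])
        out = make_dataset([make_record(100, 0.1, 0.02)], trait_id="out")
        df = harmonize(exp, out)
        assert df.loc[0, "beta_y"] == pytest.approx(0.1)
        assert not bool(df.loc[0, "flipped"])

    def test_strand_complement_resolved(self):
        # outcome coded on the other strand: A/G vs T/C
        exp = make_dataset([make_record(100, 0.2, 0.02, ea="A", oa="G")])
        out = make_dataset([make_record(100, 0.1, 0.02, ea="T", oa="C")],
                           trait_id="out")
        df = harmonize(exp, out)
        assert df.loc[0, "beta_y"] == pytest.approx(0.1)

    def test_palindrome_at_maf_half_dropped(self):
        exp = make_dataset([make_record(100, 0.2, 0.02, ea="A", oa="T",
                                        eaf=0.5)])
        out = make_dataset([make_record(100, 0.1, 0.02, ea="A", oa="T",
                                        eaf=0.5)], trait_id="out")
        df = harmonize(exp, out, palindrome_policy="freq_infer",
                       maf_ambiguity_bound=0.42)
        assert df.empty
        assert df.attrs["report"].reasons["palindromic_ambiguous"] == 1

    def test_palindrome_frequency_inference_flips(self):
        # exposure eaf 0.1, outcome eaf 0.9: opposite sides -> flip
        exp = make_dataset([make_record(100, 0.2, 0.02, ea="A", oa="T",
                                        eaf=0.1)])
        out = make_dataset([make_record(100, 0.1, 0.02, ea="A", oa="T",
                                        eaf=0.9)], trait_id="out")
        df = harmonize(exp, out)
        assert df.loc[0, "beta_y"] == pytest.approx(-0.1)

    def test_palindrome_missing_freq_dropped(self):
        exp = make_dataset([make_record(100, 0.2, 0.02, ea="A", oa="T",
                                        eaf=None)])
        out = make_dataset([make_record(100, 0.1, 0.02, ea="A", oa="T",
                                        eaf=0.2)], trait_id="out")
        df = harmonize(exp, out)
        assert df.empty

    def test_irreconcilable_alleles_dropped_and_logged(self):
        exp = make_dataset([make_record(100, 0.2, 0.02, ea="A", oa="G")])
        out = make_dataset([make_record(100, 0.1, 0.02, ea="A", oa="C")],
                           trait_id="out")
        df = harmonize(exp, out)
        assert df.empty
        assert df.attrs["report"].reasons["allele_mismatch"] == 1

    def test_multiallelic_position_dropped(self):
        exp = make_dataset([make_record(100, 0.2, 0.02, ea="A", oa="G"),
                            make_record(100, 0.1, 0.02, ea="A", oa="C")])
        out = make_dataset([make_record(100, 0.1, 0.02)], trait_id="out")
        df = harmonize(exp, out)
        assert df.empty
        assert df.attrs["report"].reasons["multiallelic"] == 1

    def test_no_overlap_raises(self):
        exp = make_dataset([make_record(100, 0.2, 0.02)])
        out = make_dataset([make_record(999, 0.1, 0.02)], trait_id="out")
        with pytest.raises(EmptyIntersectionError):
            harmonize(exp, out)

    def test_counts_conserved(self):
        exp = make_dataset([
            make_record(100, 0.2, 0.02),
            make_record(200, 0.2, 0.02, ea="A", oa="T", eaf=0.5),
            make_record(300, 0.2, 0.02),
        ])
        out = make_dataset([
            make_record(100, 0.1, 0.02),
            make_record(200, 0.1, 0.02, ea="A", oa="T", eaf=0.5),
            make_record(300, 0.1, 0.02, ea="A", oa="C"),
        ], trait_id="out")
        df = harmonize(exp, out)
        rep = df.attrs["report"]
        assert rep.rows_in == rep.rows_kept + rep.rows_rejected == 3

    def test_idempotent_on_aligned_pair(self, rng):
        """Re-harmonizing an already-aligned outcome changes nothing."""
        recs_x, recs_y = [], []
        for i in range(12):
            b = rng.normal(0, 0.1)
            recs_x.append(make_record(100 + i, b, 0.02, eaf=0.25))
            recs_y.append(make_record(100 + i, b / 2, 0.03, eaf=0.25))
        exp, out = make_dataset(recs_x), make_dataset(recs_y, trait_id="out")
        df1 = harmonize(exp, out)
        aligned = make_dataset([
            make_record(int(r.pos), float(r.beta_y), float(r.se_y),
                        eaf=float(r.eaf_y))
            for r in df1.itertuples(index=False)
        ], trait_id="out")
        df2 = harmonize(exp, aligned)
        np.testing.assert_allclose(df1["beta_y"], df2["beta_y"])
        assert not df2["flipped"].any()

    def test_sign_flip_involution(self, rng):
        """Flipping every outcome record's coding leaves paired betas fixed."""
        recs_x, recs_y = [], []
        for i in range(10):
            recs_x.append(make_record(100 + i, rng.normal(0, 0.1), 0.02))
            recs_y.append(make_record(100 + i, rng.normal(0, 0.1), 0.03))
        exp, out = make_dataset(recs_x), make_dataset(recs_y, trait_id="out")
        flipped = make_dataset([
            AssociationRecord(variant=r.variant.flipped(), beta=-r.beta,
                              se=r.se, pvalue=r.pvalue, n=r.n,
                              trait_id=r.trait_id)
            for r in out
        ], trait_id="out")
        df1, df2 = harmonize(exp, out), harmonize(exp, flipped)
        np.testing.assert_allclose(df1["beta_y"], df2["beta_y"])
        np.testing.assert_allclose(df1["beta_x"], df2["beta_x"])
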