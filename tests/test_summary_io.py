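"""Summary-statistic IO and allele harmonization."""

import numpy as np
import pytest

from mrglyc.summary_io import (
    ConfigurationError,
    SummaryStatsParseError,
    harmonize,
    read_summary_stats,
    write_summary_stats,
)
from .conftest import make_record


def write_tsv(path, rows, header="id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadWrite:
    def test_three_row_round_trip(self, tmp_path):
        records = [make_record(f"rs{i}", beta=0.01 * i, se=0.005 + 0.001 * i)
                   for i in range(1, 4)]
        p = tmp_path / "ss.tsv"
        write_summary_stats(records, p)
        back = read_summary_stats(p)
        assert len(back) == 3 and not back.rejected
        for a, b in zip(records, back):
            assert a.variant == b.variant
            assert a.beta == pytest.approx(b.beta, abs=0) and a.se == b.se
            assert a.pval == b.pval and a.n == b.n

    def test_dialect_mapping(self, tmp_path):
        p = tmp_path / "foreign.tsv"
        write_tsv(p, ["rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t0.5\t1000"],
                  header="snp\tchrom\tpos\tea\toa\teaf\tbeta\tse\tpval\tn")
        res = read_summary_stats(p, dialect={"id": "snp", "effect_allele": "ea",
                                             "other_allele": "oa"})
        assert len(res) == 1 and res[0].variant.id == "rs1"

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        write_tsv(p, ["rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t0.5"],
                  header="id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval")
        with pytest.raises(ConfigurationError, match="n"):
            read_summary_stats(p)

    def test_non_numeric_beta_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        write_tsv(p, ["rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t0.5\t1000",
                      "rs2\t1\t200\tA\tG\t0.3\tnot_a_number\t0.02\t0.5\t1000"])
        with pytest.raises(SummaryStatsParseError, match="line 3"):
            read_summary_stats(p)

    @pytest.mark.parametrize("row,reason", [
        ("rs1\t1\t100\tA\tG\t0.3\t0.1\t0.0\t0.5\t1000", "non-positive SE"),
        ("rs1\t1\t100\tA\tA\t0.3\t0.1\t0.02\t0.5\t1000", "identical"),
        ("rs1\t1\t100\tA\tG\t1.3\t0.1\t0.02\t0.5\t1000", "eaf"),
    ])
    def test_invariant_failures_collected_not_dropped(self, tmp_path, row, reason):
        p = tmp_path / "ss.tsv"
        write_tsv(p, [row, "rs2\t1\t200\tA\tG\t0.3\t0.1\t0.02\t0.5\t1000"])
        res = read_summary_stats(p)
        assert len(res) == 1
        assert len(res.rejected) == 1
        vid, msg = res.rejected[0]
        assert vid == "rs1" and reason in msg

    def test_missing_eaf_written_as_na(self, tmp_path):
        rec = make_record("rs1", eaf=None)
        p = tmp_path / "ss.tsv"
        write_summary_stats([rec], p)
        assert "NA" in p.read_text()
        back = read_summary_stats(p)
        assert back[0].variant.eaf is None


class TestHarmonize:
    def test_swapped_alleles_flip_sign_and_eaf(self):
        exp = [make_record("rs1", beta=0.1, ea="A", oa="G", eaf=0.3)]
        out = [make_record("rs1", beta=0.05, ea="G", oa="A", eaf=0.7)]
        hs = harmonize(exp, out)
        assert len(hs) == 1
        assert hs.Gamma_out[0] == pytest.approx(-0.05)
        assert hs.outcome_records[0].variant.effect_allele == "A"
        assert hs.outcome_records[0].variant.eaf == pytest.approx(0.3)

    def test_palindromic_mid_frequency_dropped(self):
        exp = [make_record("rs1", ea="A", oa="T", eaf=0.50)]
        out = [make_record("rs1", ea="A", oa="T", eaf=0.50)]
        hs = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert len(hs) == 0
        assert hs.dropped == [("rs1", "palindromic-ambiguous")]

    def test_palindromic_extreme_frequency_kept(self):
        exp = [make_record("rs1", ea="A", oa="T", eaf=0.10)]
        out = [make_record("rs1", ea="A", oa="T", eaf=0.11)]
        hs = harmonize(exp, out)
        assert len(hs) == 1

    def test_unmatched_and_mismatch_reasons(self):
        exp = [make_record("rs1"), make_record("rs2", ea="A", oa="G")]
        out = [make_record("rs2", ea="A", oa="C")]
        hs = harmonize(exp, out)
        assert dict(hs.dropped) == {"rs1": "unmatched", "rs2": "allele-mismatch"}

    def test_42_matched_variants_all_retained(self, rng):
        exp = [make_record(f"rs{j}", beta=rng.normal(), ea="A", oa="G")
               for j in range(42)]
        out = [make_record(f"rs{j}", beta=rng.normal(), ea="A", oa="G")
               for j in range(42)]
        hs = harmonize(exp, out)
        assert len(hs) == 42 and not hs.dropped

    def test_idempotent(self, rng):
        exp = [make_record(f"rs{j}", beta=rng.normal(), ea="A", oa="G", eaf=0.2)
               for j in range(8)]
        out = [make_record(f"rs{j}", beta=rng.normal(), ea="G", oa="A", eaf=0.8)
               for j in range(8)]
        once = harmonize(exp, out)
        twice = harmonize(once.exposure_records, once.outcome_records)
        assert np.allclose(once.gamma, twice.gamma)
        assert np.allclose(once.Gamma_out, twice.Gamma_out)
        assert not twice.dropped

    def test_flipping_all_outcome_records_is_a_no_op(self, rng):
        exp = [make_record(f"rs{j}", beta=rng.normal(), ea="A", oa="G")
               for j in range(10)]
        out = [make_record(f"rs{j}", beta=rng.normal(), ea="A", oa="G", eaf=0.3)
               for j in range(10)]
        direct = harmonize(exp, out)
        flipped = harmonize(exp, [r.flipped() for r in out])
        assert np.allclose(direct.gamma, flipped.gamma)
        assert np.allclose(direct.Gamma_out, flipped.Gamma_out)

    def test_partition_accounting(self, rng):
        exp = ([make_record(f"m{j}", ea="A", oa="G") for j in range(5)]
               + [make_record("lonely")]
               + [make_record("pal", ea="C", oa="G", eaf=0.5)])
        out = ([make_record(f"m{j}", ea="A", oa="G") for j in range(5)]
               + [make_record("pal", ea="C", oa="G", eaf=0.5)]
               + [make_record("outcome_only")])
        hs = harmonize(exp, out)
        assert len(hs) <= min(len(exp), len(out))
        assert len(hs) + len(hs.dropped) == len(exp)
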