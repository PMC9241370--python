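"""Domain types and on-disk format round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from saaspred.io import (
    read_aaindex,
    read_annotation_table,
    read_fasta,
    read_msa,
    read_pssm_ascii,
    read_saas_table,
    write_annotation_table,
    write_fasta,
    write_msa,
    write_pssm_ascii,
    write_saas_table,
)
from saaspred.records import (
    AMINO_ACIDS,
    Annotation,
    Msa,
    ProteinRecord,
    Pssm,
    SaasError,
    SaasRecord,
    format_substitution,
    parse_substitution,
)


class TestParseSubstitution:
    @pytest.mark.parametrize("text,expected", [
        ("G87D", ("G", 87, "D")),
        ("T55M", ("T", 55, "M")),
        ("a5v", ("A", 5, "V")),
    ])
    def test_examples(self, text, expected):
        assert parse_substitution(text) == expected

    @pytest.mark.parametrize("bad", ["A5A", "G0D", "87D", "GD", "G8.7D", ""])
    def test_malformed(self, bad):
        with pytest.raises(SaasError):
            parse_substitution(bad)

    @settings(derandomize=True, max_examples=50)
    @given(wt=st.sampled_from(AMINO_ACIDS), mut=st.sampled_from(AMINO_ACIDS),
           pos=st.integers(min_value=1, max_value=10000))
    def test_roundtrip(self, wt, mut, pos):
        if wt == mut:
            return
        assert parse_substitution(format_substitution(wt, pos, mut)) == (wt, pos, mut)


class TestSaasRecord:
    def test_wt_must_match_sequence(self):
        prot = ProteinRecord("P1", "ACDEF")
        SaasRecord("P1", "F", 5, "G").check_against(prot)
        with pytest.raises(SaasError, match="has C"):
            SaasRecord("P1", "G", 2, "D").check_against(prot)

    def test_position_beyond_length(self):
        with pytest.raises(SaasError):
            SaasRecord("P1", "F", 9, "G").check_against(ProteinRecord("P1", "ACDEF"))


class TestFasta:
    def test_minimal(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">P1 description here\nacd\nef\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].protein_id == "P1"
        assert recs[0].sequence == "ACDEF"

    def test_order_preserved_and_roundtrip(self, tmp_path):
        recs = [ProteinRecord("B", "ACDEF"), ProteinRecord("A", "GHIKL")]
        p = tmp_path / "two.fasta"
        write_fasta(p, recs)
        back = read_fasta(p)
        assert [r.protein_id for r in back] == ["B", "A"]
        assert [r.sequence for r in back] == ["ACDEF", "GHIKL"]

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(SaasError):
            read_fasta(p)

    def test_bad_characters_named(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">BADREC\nAC1EF\n")
        with pytest.raises(SaasError, match="BADREC"):
            read_fasta(p)


class TestMsaIo:
    def test_read(self, tmp_path):
        p = tmp_path / "m.fasta"
        p.write_text(">q\nAC-DE\n>h\nACXDE\n>g\nACDDE\n")
        msa = read_msa(p)
        assert msa.n_rows == 3 and msa.width == 5
        assert msa.query_index == 0

    def test_ragged_errors(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">a\nACDEF\n>b\nACDEF\n>c\nACDE\n")
        with pytest.raises(SaasError, match="ragged"):
            read_msa(p)

    def test_single_row_allowed(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">a\nACDEF\n")
        assert read_msa(p).n_rows == 1

    def test_roundtrip(self, tmp_path, family):
        p = tmp_path / "fam.fasta"
        write_msa(p, family)
        back = read_msa(p)
        assert back.rows == family.rows and back.ids == family.ids


class TestPssmAscii:
    def test_roundtrip_and_manual_value(self, tmp_path):
        scores = {i: {aa: float((i * 7 + k) % 13 - 6)
                      for k, aa in enumerate(AMINO_ACIDS)}
                  for i in range(1, 6)}
        pssm = Pssm(scores=scores)
        p = tmp_path / "q.pssm"
        write_pssm_ascii(p, pssm, "ACDEF")
        back = read_pssm_ascii(p)
        assert back.length == 5
        assert back.scores[1]["A"] == scores[1]["A"]
        assert back.scores == scores

    def test_trailing_columns_ignored(self, tmp_path):
        header = "      " + "  ".join(AMINO_ACIDS) + "  " + "  ".join(AMINO_ACIDS)
        row = "  1 A " + " ".join(str(v % 10) for v in range(40)) + "  0.35 1.02"
        p = tmp_path / "wide.pssm"
        p.write_text("\nheader\n" + header + "\n" + row + "\n")
        pssm = read_pssm_ascii(p)
        assert pssm.length == 1
        assert pssm.scores[1]["A"] == 0.0
        assert pssm.scores[1][AMINO_ACIDS[19]] == 19 % 10

    def test_truncated_row_errors(self, tmp_path):
        p = tmp_path / "trunc.pssm"
        p.write_text("\nheader\n " + " ".join(AMINO_ACIDS) + "\n  1 A 1 2 3\n")
        with pytest.raises(SaasError):
            read_pssm_ascii(p)


class TestAaindex:
    def test_entries_parsed(self, aaindex_entries):
        kinds = {e.accession: e.kind for e in aaindex_entries}
        assert kinds["SYNH010101"] == "index1"
        assert kinds["SYNM2A0101"].startswith("matrix")

    def test_missing_flagged(self, aaindex_entries):
        flags = {e.accession: e.has_missing for e in aaindex_entries}
        assert flags["SYNM050101"] is True
        assert flags["SYNH010101"] is False

    def test_asymmetric_dropped(self, aaindex_entries):
        assert "SYNM3X0101" not in {e.accession for e in aaindex_entries}

    def test_lower_triangular_completed_symmetric(self, aaindex_entries):
        mat = next(e for e in aaindex_entries if e.accession == "SYNM2A0101")
        for a, b in [("A", "R"), ("L", "I"), ("W", "C")]:
            assert mat.pair_value(a, b) == mat.pair_value(b, a)
            assert mat.pair_value(a, b) is not None

    def test_known_index_value(self, aaindex_entries):
        # first value of the flat-file order (A) in the synthetic scale
        e = next(x for x in aaindex_entries if x.accession == "SYNH010101")
        assert e.index_value("A") == 1.8
        assert e.index_value("V") == 4.2

    def test_record_without_accession_errors(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("D no accession\nI  A/L\n  1.0\n//\n")
        with pytest.raises(SaasError):
            read_aaindex(p)


class TestTables:
    def test_saas_roundtrip(self, tmp_path):
        recs = [SaasRecord("P1", "G", 87, "D", label="functional"),
                SaasRecord("P2", "T", 55, "M", label="neutral",
                           source="simulated")]
        p = tmp_path / "saas.tsv"
        write_saas_table(p, recs)
        back = read_saas_table(p)
        assert back == recs

    def test_annotation_roundtrip(self, tmp_path):
        anns = {"P1": [Annotation("ACT_SITE", 10, 10),
                       Annotation("DOMAIN", 5, 40)]}
        p = tmp_path / "ann.tsv"
        write_annotation_table(p, anns)
        assert read_annotation_table(p) == anns

    def test_missing_columns_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("protein_id\twt\n")
        with pytest.raises(SaasError):
            read_saas_table(p)
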