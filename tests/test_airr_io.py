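import pytest

from immunorep import airr_io
from immunorep.models import RearrangementRecord

from conftest import make_record, make_repertoire


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadAirrTable:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "a.tsv"
        write_tsv(
            path,
            ["v_call", "j_call", "junction", "junction_aa", "consensus_count"],
            [
                ["TRBV7-2*01", "TRBJ2-1*01", "TGTGCCAGCAGCTTATTTTTT", "CASSLFF", 5],
                ["TRBV7-2*01", "TRBJ2-1*01", "TGTGCCAGCAGCTTATTTTTC", "CASSLFF", 3],
            ],
        )
        rep = airr_io.read_airr_table(path, "S1", 1_000_000)
        assert len(rep) == 2
        assert sorted(r.read_count for r in rep) == [3, 5]
        assert all(r.locus == "TRB" for r in rep)

    def test_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_tsv(path, ["v_call", "j_call", "junction", "junction_aa"], [])
        rep = airr_io.read_airr_table(path, "S1", 1000)
        assert len(rep) == 0

    def test_fully_empty_file(self, tmp_path):
        path = tmp_path / "zero.tsv"
        path.write_text("")
        assert len(airr_io.read_airr_table(path, "S1", 1000)) == 0

    def test_locus_inferred_from_v_call(self, tmp_path):
        path = tmp_path / "k.tsv"
        write_tsv(
            path,
            ["v_call", "j_call", "junction", "junction_aa"],
            [["IGKV1-5*01", "IGKJ1*01", "TGTCAACAATTT", "CQQF"]],
        )
        rep = airr_io.read_airr_table(path, "S1", 1000)
        assert rep.records[0].locus == "IGK"

    def test_missing_count_column_defaults_to_one(self, tmp_path):
        path = tmp_path / "c.tsv"
        write_tsv(
            path,
            ["v_call", "j_call", "junction", "junction_aa"],
            [["TRBV7-2*01", "TRBJ2-1*01", "TGTGCCAGCTTT", "CASF"]],
        )
        rep = airr_io.read_airr_table(path, "S1", 1000)
        assert rep.records[0].read_count == 1

    def test_count_precedence_consensus_over_duplicate(self, tmp_path):
        path = tmp_path / "p.tsv"
        write_tsv(
            path,
            ["v_call", "j_call", "junction", "junction_aa", "duplicate_count", "consensus_count"],
            [["TRBV7-2*01", "TRBJ2-1*01", "TGTGCCAGCTTT", "CASF", 9, 4]],
        )
        rep = airr_io.read_airr_table(path, "S1", 1000)
        assert rep.records[0].read_count == 4

    @pytest.mark.parametrize("missing", ["v_call", "j_call", "junction", "junction_aa"])
    def test_missing_mandatory_column_raises_naming_it(self, tmp_path, missing):
        header = ["v_call", "j_call", "junction", "junction_aa"]
        header.remove(missing)
        path = tmp_path / "bad.tsv"
        write_tsv(path, header, [])
        with pytest.raises(airr_io.AirrFormatError, match=missing):
            airr_io.read_airr_table(path, "S1", 1000)

    def test_high_n_cdr3_dropped(self, tmp_path):
        path = tmp_path / "n.tsv"
        write_tsv(
            path,
            ["v_call", "j_call", "junction", "junction_aa"],
            [["TRBV7-2*01", "TRBJ2-1*01", "TGTNNNNNNTTT", "CXXF"]],
        )
        rep = airr_io.read_airr_table(path, "S1", 1000)
        assert len(rep) == 0

    def test_explicit_locus_column_wins(self, tmp_path):
        path = tmp_path / "l.tsv"
        write_tsv(
            path,
            ["v_call", "j_call", "junction", "junction_aa", "locus"],
            [["TRBV7-2*01", "TRBJ2-1*01", "TGTGCCAGCTTT", "CASF", "TRB"]],
        )
        rep = airr_io.read_airr_table(path, "S1", 1000)
        assert rep.records[0].locus == "TRB"


class TestReadTrust4Report:
    HEADER = ["#count", "frequency", "CDR3nt", "CDR3aa", "V", "D", "J", "C"]

    def test_basic_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_tsv(
            path,
            self.HEADER,
            [[8, 0.5, "TGTGCCAGCAGCTTATTTTTT", "CASSLFF", "TRBV7-2", ".", "TRBJ2-1", "."]],
        )
        rep = airr_io.read_trust4_report(path, "S1", 1000)
        assert len(rep) == 1
        rec = rep.records[0]
        assert rec.locus == "TRB"
        assert rec.read_count == 8
        assert rec.v_call == "TRBV7-2"

    def test_out_of_frame_marker(self, tmp_path):
        path = tmp_path / "oof.tsv"
        write_tsv(
            path,
            self.HEADER,
            [[2, 0.1, "TGTGCCAGCAGCTTATTTTT", "out_of_frame", "TRBV7-2", ".", "TRBJ2-1", "."]],
        )
        rep = airr_io.read_trust4_report(path, "S1", 1000)
        assert len(rep) == 1
        assert rep.records[0].out_of_frame

    def test_empty_report(self, tmp_path):
        path = tmp_path / "e.tsv"
        write_tsv(path, self.HEADER, [])
        assert len(airr_io.read_trust4_report(path, "S1", 1000)) == 0

    def test_unrecognized_header(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_tsv(path, ["foo", "bar"], [])
        with pytest.raises(airr_io.AirrFormatError):
            airr_io.read_trust4_report(path, "S1", 1000)


class TestFilterProductive:
    def test_stop_codon_removed(self):
        # TAA at codon 2 -> '*' in translation
        rec = make_record(cdr3_nt="TGTTAAAGCTTT", sequence_id="stop")
        rep = make_repertoire([rec])
        assert len(airr_io.filter_productive(rep)) == 0

    def test_stop_in_declared_aa_removed(self):
        rec = make_record(cdr3_nt="TGTGCCAGCTTT", cdr3_aa="CA*F")
        assert len(airr_io.filter_productive(make_repertoire([rec]))) == 0

    def test_productive_retained(self):
        rec = make_record(cdr3_nt="TGTGCCAGCAGCTTATTTTTT")
        assert len(airr_io.filter_productive(make_repertoire([rec]))) == 1

    def test_empty_cdr3_removed(self):
        rec = make_record(cdr3_nt="", cdr3_aa="")
        assert len(airr_io.filter_productive(make_repertoire([rec]))) == 0

    def test_frameshift_removed(self):
        rec = make_record(cdr3_nt="TGTGCCAGCTT", cdr3_aa="")
        assert len(airr_io.filter_productive(make_repertoire([rec]))) == 0

    def test_incomplete_removed(self):
        rec = make_record(cdr3_nt="TGTGCCAGCTTT", is_complete=False)
        assert len(airr_io.filter_productive(make_repertoire([rec]))) == 0

    def test_idempotent(self, trb_repertoire):
        once = airr_io.filter_productive(trb_repertoire)
        twice = airr_io.filter_productive(once)
        assert [r.sequence_id for r in once] == [r.sequence_id for r in twice]

    def test_order_preserved(self, trb_repertoire):
        filtered = airr_io.filter_productive(trb_repertoire)
        assert [r.sequence_id for r in filtered] == ["a", "b", "c"]


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, trb_repertoire):
        path = tmp_path / "rt.tsv"
        airr_io.write_rearrangements(trb_repertoire, path)
        back = airr_io.read_airr_table(path, "S1", trb_repertoire.library_reads)
        assert len(back) == len(trb_repertoire)
        for orig, new in zip(trb_repertoire, back):
            for attr in (
                "sample_id", "locus", "v_call", "j_call", "cdr3_nt",
                "cdr3_aa", "read_count", "is_complete", "sequence_id", "out_of_frame",
            ):
                assert getattr(orig, attr) == getattr(new, attr), attr

    def test_empty_repertoire_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        airr_io.write_rearrangements(make_repertoire([]), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert len(airr_io.read_airr_table(path, "S1", 1000)) == 0

    def test_one_line_per_record(self, tmp_path, trb_repertoire):
        path = tmp_path / "lines.tsv"
        airr_io.write_rearrangements(trb_repertoire, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + len(trb_repertoire)


class TestRecordInvariants:
    def test_bad_locus_rejected(self):
        with pytest.raises(ValueError, match="locus"):
            make_record(locus="ABC")

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="read_count"):
            make_record(read_count=-1)

    def test_frame_mismatch_autoflagged(self):
        rec = RearrangementRecord(
            sample_id="S1", locus="TRB", v_call="TRBV7-2", j_call="TRBJ2-1",
            cdr3_nt="TGTGCCAGCTTT", cdr3_aa="CASSF", read_count=1,
        )
        assert rec.out_of_frame

    def test_library_smaller_than_reads_rejected(self):
        with pytest.raises(ValueError, match="library_reads"):
            make_repertoire([make_record(read_count=10)], library_reads=5)
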