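import pysam
import pytest

from splicescreen import (
    Junction,
    ScenarioSpec,
    audit_gtf,
    filter_bam,
    judge_all,
    junctions_from_bam,
    make_genome,
    make_spliced_alignments,
    write_junction_bed,
)
from splicescreen.verdict import RETAINED, SPURIOUS, Verdict


def read_records(path):
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        return [r.to_string() for r in af.fetch(until_eof=True)]


@pytest.fixture
def tandem(tmp_path):
    sc = make_genome(ScenarioSpec(kind="TANDEM_REPEAT", seed=4))
    sam = str(tmp_path / "in.sam")
    make_spliced_alignments(sc.genome, sc.junctions, sam,
                            n_per_junction=4, n_background=6, seed=4)
    junctions = junctions_from_bam(sam, sc.genome)
    verdicts = judge_all(junctions, sc.genome)
    return sc, sam, verdicts


class TestFilterBam:
    def test_removed_plus_kept_equals_total(self, tandem, tmp_path):
        sc, sam, verdicts = tandem
        out = str(tmp_path / "out.sam")
        report = filter_bam(sam, verdicts, out)
        assert report.total_records == 10
        assert report.removed_records == 4
        assert report.kept_records == 6
        assert report.removed_records + report.kept_records == report.total_records
        assert len(read_records(out)) == 6

    def test_removed_records_captured(self, tandem, tmp_path):
        sc, sam, verdicts = tandem
        out, removed = str(tmp_path / "out.sam"), str(tmp_path / "removed.sam")
        filter_bam(sam, verdicts, out, removed_out=removed)
        assert len(read_records(removed)) == 4
        assert sorted(read_records(out) + read_records(removed)) == \
            sorted(read_records(sam))

    def test_any_spurious_gap_removes_record(self, tandem, tmp_path):
        # a record with one genuine and one spurious skip is removed
        sc, sam, verdicts = tandem
        (spur,) = [v for v in verdicts if v.status == SPURIOUS]
        c, s, e = spur.key
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": n, "LN": L} for n, L in sc.genome.lengths.items()]}
        two_gap = str(tmp_path / "two_gap.sam")
        with pysam.AlignmentFile(two_gap, "w", header=header) as outf:
            rec = pysam.AlignedSegment()
            rec.query_name = "mixed"
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = 250
            rec.mapping_quality = 60
            mlen = s - 500
            rec.cigarstring = f"50M200N{mlen}M{e - s}N50M"
            rec.query_sequence = "A" * (50 + mlen + 50)
            outf.write(rec)
        report = filter_bam(two_gap, verdicts, str(tmp_path / "tg_out.sam"))
        assert report.removed_records == 1

    def test_zero_spurious_passes_through_identically(self, tandem, tmp_path):
        sc, sam, verdicts = tandem
        retained_only = [v for v in verdicts if v.status == RETAINED]
        out = str(tmp_path / "out.sam")
        report = filter_bam(sam, retained_only, out)
        assert report.removed_records == 0
        assert read_records(out) == read_records(sam)

    def test_filtering_is_idempotent(self, tandem, tmp_path):
        sc, sam, verdicts = tandem
        once = str(tmp_path / "once.sam")
        twice = str(tmp_path / "twice.sam")
        filter_bam(sam, verdicts, once)
        report = filter_bam(once, verdicts, twice)
        assert report.removed_records == 0
        assert read_records(once) == read_records(twice)

    def test_program_line_appended(self, tandem, tmp_path):
        sc, sam, verdicts = tandem
        out = str(tmp_path / "out.sam")
        filter_bam(sam, verdicts, out)
        with pysam.AlignmentFile(out, check_sq=False) as af:
            assert any(pg.get("ID") == "splicescreen"
                       for pg in af.header.to_dict().get("PG", []))


class TestJunctionBed:
    def make_verdicts(self):
        j1 = Junction("chr1", 35, 135, motif="GTAG", support=7)
        j2 = Junction("chr1", 500, 700, motif="CTAC", support=2)
        j3 = Junction("chr2", 10, 90, motif="ATAC", support=1)
        return [
            Verdict(j1, SPURIOUS, "TWO_ANCHOR", "TA_HYBRID"),
            Verdict(j2, RETAINED, "NO_ALIGNMENT", "NOALN"),
            Verdict(j3, RETAINED, "ONE_ANCHOR", "OA_LOWFREQ"),
        ]

    def test_bed6_row_format_and_motif_strand(self, tmp_path):
        path = tmp_path / "j.bed"
        write_junction_bed(self.make_verdicts(), str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "chr1\t35\t135\tTA_HYBRID\t7\t+"
        assert lines[1].endswith("\t-")
        assert lines[2].endswith("\t.")

    def test_which_retained_excludes_spurious(self, tmp_path):
        path = tmp_path / "j.bed"
        write_junction_bed(self.make_verdicts(), str(path), which="retained")
        assert all("TA_HYBRID" not in l for l in path.read_text().splitlines())

    def test_empty_verdicts_empty_file(self, tmp_path):
        path = tmp_path / "j.bed"
        write_junction_bed([], str(path), which="spurious")
        assert path.read_text() == ""


class TestAuditGtf:
    def test_shared_spurious_intron_counted_per_transcript(self, tmp_path):
        # a tandemly duplicated locus annotated as one gene with two spliced
        # transcripts sharing the bridging intron: both transcripts flagged
        sc = make_genome(ScenarioSpec(kind="TANDEM_REPEAT", seed=6))
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(sc.gtf)
        from splicescreen import junctions_from_gtf
        junctions = junctions_from_gtf(str(gtf), sc.genome)
        verdicts = judge_all(junctions, sc.genome)
        rows, summary = audit_gtf(str(gtf), verdicts)
        assert len(rows) == 2
        assert {r.transcript_id for r in rows} == {"t1", "t2"}
        assert summary == {"spurious_introns": 1, "affected_transcripts": 2,
                           "affected_genes": 1}

    def test_no_spurious_introns_empty_table(self, tmp_path):
        sc = make_genome(ScenarioSpec(kind="UNIQUE_INTRON", seed=6))
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(sc.gtf)
        from splicescreen import junctions_from_gtf
        junctions = junctions_from_gtf(str(gtf), sc.genome)
        verdicts = judge_all(junctions, sc.genome)
        rows, summary = audit_gtf(str(gtf), verdicts)
        assert rows == []
        assert summary["spurious_introns"] == 0

    def test_counts_are_consistent(self, tmp_path):
        sc = make_genome(ScenarioSpec(kind="TANDEM_REPEAT", seed=8))
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(sc.gtf)
        from splicescreen import junctions_from_gtf
        junctions = junctions_from_gtf(str(gtf), sc.genome)
        verdicts = judge_all(junctions, sc.genome)
        rows, summary = audit_gtf(str(gtf), verdicts)
        assert summary["spurious_introns"] <= len(rows)
        assert summary["affected_genes"] <= summary["affected_transcripts"]
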