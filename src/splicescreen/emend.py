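"""Apply verdicts: filter alignment files, write junction BEDs, audit GTFs.

Filtering removes an alignment record exactly when one of its reference-skip
gaps matches a SPURIOUS junction key; everything else passes through
unchanged in content (the header gains a @PG provenance line).  Mates of
removed records are kept by default — their own alignments are not evidence
for the spurious junction — with an opt-in to drop them too.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pysam

from . import __version__
from .junctions import Junction, read_gtf_exons, record_gaps
from .verdict import SPURIOUS, Verdict

_PG_ID = "splicescreen"


@dataclass
class EmendReport:
    total_records: int = 0
    total_spliced_records: int = 0
    removed_records: int = 0
    kept_records: int = 0
    spurious_junctions: int = 0
    retained_junctions: int = 0
    removed_support: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "total_records": self.total_records,
            "total_spliced_records": self.total_spliced_records,
            "removed_records": self.removed_records,
            "kept_records": self.kept_records,
            "spurious_junctions": self.spurious_junctions,
            "retained_junctions": self.retained_junctions,
            "removed_support": {
                f"{c}:{s}-{e}": n for (c, s, e), n in sorted(self.removed_support.items())
            },
        }


def _write_mode(path: str) -> str:
    return "wb" if str(path).endswith(".bam") else "w"


def _augmented_header(af: pysam.AlignmentFile, digest: str) -> pysam.AlignmentHeader:
    head = af.header.to_dict()
    head.setdefault("PG", []).append(
        {"ID": _PG_ID, "PN": _PG_ID, "VN": __version__, "CL": f"filter params={digest}"}
    )
    return pysam.AlignmentHeader.from_dict(head)


def filter_bam(
    bam_in: str,
    verdicts: list[Verdict],
    bam_out: str,
    removed_out: str | None = None,
    drop_mates: bool = False,
    params_digest: str = "default",
) -> EmendReport:
    """Write a filtered copy of ``bam_in`` with spurious-junction records removed.

    A record is removed iff any of its reference-skip gaps equals a SPURIOUS
    junction key exactly.  Removed records can be captured in a second file.
    """
    spurious = {v.key for v in verdicts if v.status == SPURIOUS}
    report = EmendReport(
        spurious_junctions=len(spurious),
        retained_junctions=sum(1 for v in verdicts if v.status != SPURIOUS),
    )
    drop_names: set[str] = set()
    if drop_mates and spurious:
        with pysam.AlignmentFile(str(bam_in), check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_paired and any(
                    (rec.reference_name, s, e) in spurious for s, e in record_gaps(rec)
                ):
                    drop_names.add(rec.query_name)

    removed_counts: Counter = Counter()
    with pysam.AlignmentFile(str(bam_in), check_sq=False) as af:
        bam_contigs = set(af.references)
        missing = {c for c, _, _ in spurious} - bam_contigs
        if missing:
            raise ValueError(
                f"verdict contigs absent from alignment header: {sorted(missing)}"
            )
        header = _augmented_header(af, params_digest)
        out = pysam.AlignmentFile(str(bam_out), _write_mode(bam_out), header=header)
        rem = (
            pysam.AlignmentFile(str(removed_out), _write_mode(removed_out), header=header)
            if removed_out
            else None
        )
        try:
            for rec in af.fetch(until_eof=True):
                report.total_records += 1
                gaps = record_gaps(rec)
                if gaps:
                    report.total_spliced_records += 1
                hit_keys = [
                    (rec.reference_name, s, e)
                    for s, e in gaps
                    if (rec.reference_name, s, e) in spurious
                ]
                drop = bool(hit_keys) or (drop_mates and rec.query_name in drop_names)
                if drop:
                    report.removed_records += 1
                    for key in hit_keys:
                        removed_counts[key] += 1
                    if rem is not None:
                        rem.write(rec)
                else:
                    report.kept_records += 1
                    out.write(rec)
        finally:
            out.close()
            if rem is not None:
                rem.close()
    report.removed_support = dict(removed_counts)
    return report


_MOTIF_STRAND = {"GTAG": "+", "CTAC": "-"}


def write_junction_bed(verdicts: list[Verdict], path: str, which: str = "all") -> None:
    """BED6 per junction: name = reason code, score = support, strand from motif."""
    if which not in ("spurious", "retained", "all"):
        raise ValueError(f"which must be spurious|retained|all, got {which!r}")
    with open(path, "w") as fh:
        for v in verdicts:
            if which == "spurious" and v.status != SPURIOUS:
                continue
            if which == "retained" and v.status == SPURIOUS:
                continue
            j = v.junction
            strand = _MOTIF_STRAND.get(j.motif, ".")
            fh.write(f"{j.contig}\t{j.start}\t{j.end}\t{v.reason}\t{j.support}\t{strand}\n")


@dataclass
class AuditRow:
    gene_id: str
    transcript_id: str
    contig: str
    start: int
    end: int
    reason: str
    evidence: str


def audit_gtf(gtf_path: str, verdicts: list[Verdict]):
    """Audit an annotation against verdicts computed from its own introns.

    Returns (rows, summary): one row per (transcript, spurious intron) pair,
    and a summary with distinct spurious intron / transcript / gene counts.
    """
    spurious = {v.key: v for v in verdicts if v.status == SPURIOUS}
    rows: list[AuditRow] = []
    transcripts = read_gtf_exons(gtf_path)
    for tid, tx in sorted(transcripts.items()):
        exons = sorted(tx["exons"])
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            continue
        for (_, prev_end), (next_start, _) in zip(exons, exons[1:]):
            key = (tx["contig"], prev_end, next_start)
            v = spurious.get(key)
            if v is None:
                continue
            ps = v.probes
            evidence = (
                f"score={v.alignment.score};up={ps.up.count};"
                f"down={ps.down.count};hybrid={ps.hybrid.count}"
                if v.alignment and ps
                else "."
            )
            rows.append(
                AuditRow(tx["gene_id"], tid, key[0], prev_end, next_start, v.reason, evidence)
            )
    summary = {
        "spurious_introns": len({(r.contig, r.start, r.end) for r in rows}),
        "affected_transcripts": len({r.transcript_id for r in rows}),
        "affected_genes": len({r.gene_id for r in rows}),
    }
    return rows, summary


def write_audit_tsv(rows, summary, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tcontig\tstart\tend\treason\tevidence\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.transcript_id}\t{r.contig}\t{r.start}\t{r.end}\t"
                f"{r.reason}\t{r.evidence}\n"
            )
        fh.write(
            f"# summary\tspurious_introns={summary['spurious_introns']}\t"
            f"affected_transcripts={summary['affected_transcripts']}\t"
            f"affected_genes={summary['affected_genes']}\n"
        )
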