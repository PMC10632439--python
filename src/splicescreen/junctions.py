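"""Harvest candidate introns from spliced alignments (SAM/BAM), GTF, or BED.

A junction is the genomic gap a spliced aligner reports as a CIGAR
reference-skip (N) operation, or the gap between consecutive exons of an
annotated transcript.  Identity is the strand-free key (contig, start, end):
the repeat-similarity test downstream is strand-symmetric, and aligners may
report the same genomic gap with either or no strand tag.  The splice motif
(donor + acceptor dinucleotides read from the forward strand) is recorded
for reporting only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pysam

from .genome_io import GenomeIndex, fetch

logger = logging.getLogger(__name__)

# CIGAR op codes that consume the reference
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_KNOWN_OPS = {0, 1, 2, 3, 4, 5, 7, 8}  # M, I, D, N, S, H, =, X


@dataclass
class Junction:
    """A candidate intron: 0-based half-open interval [start, end)."""

    contig: str
    start: int
    end: int
    motif: str = ""
    support: int = 1
    sources: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"intron end must exceed start: [{self.start}, {self.end})")


def _motif(genome: GenomeIndex, contig: str, start: int, end: int) -> str:
    donor = fetch(genome, contig, start, start + 2) if end - start >= 2 else ""
    acceptor = fetch(genome, contig, end - 2, end) if end - start >= 2 else ""
    return donor + acceptor


def record_gaps(rec: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference-skip intervals of one alignment record, 0-based half-open."""
    gaps: list[tuple[int, int]] = []
    if rec.is_unmapped or rec.cigartuples is None:
        return gaps
    pos = rec.reference_start
    for op, length in rec.cigartuples:
        if op == 3:  # N
            gaps.append((pos, pos + length))
        if op in _REF_CONSUMING:
            pos += length
    return gaps


def junctions_from_bam(
    bam_path: str,
    genome: GenomeIndex,
    min_support: int = 1,
    primary_only: bool = False,
) -> list[Junction]:
    """One Junction per distinct reference-skip gap, with record support counts.

    Secondary and supplementary records contribute to support by default:
    filtering acts on alignment records, not reads, so every record spanning
    a spurious junction must be discoverable.
    """
    counts: dict[tuple[str, int, int], int] = {}
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            if rec.cigartuples and any(op not in _KNOWN_OPS for op, _ in rec.cigartuples):
                logger.warning("skipping record %s: unsupported CIGAR op", rec.query_name)
                continue
            contig = rec.reference_name
            gaps = record_gaps(rec)
            if gaps and contig not in genome.contigs:
                raise ValueError(f"contig {contig!r} in alignments is absent from the genome")
            for gap in gaps:
                key = (contig, *gap)
                counts[key] = counts.get(key, 0) + 1
    out = [
        Junction(c, s, e, motif=_motif(genome, c, s, e), support=n)
        for (c, s, e), n in sorted(counts.items())
        if n >= min_support
    ]
    return out


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf_exons(gtf_path: str) -> dict[str, dict]:
    """Parse GTF exon features into {transcript_id: {gene_id, contig, strand, exons}}.

    Exons are converted to 0-based half-open intervals.  Exon lines without a
    transcript_id are skipped with a warning.
    """
    transcripts: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            attrs = _gtf_attributes(fields[8])
            tid = attrs.get("transcript_id")
            if not tid:
                logger.warning("%s:%d exon without transcript_id, skipped", gtf_path, lineno)
                continue
            start1, end1 = int(fields[3]), int(fields[4])
            tx = transcripts.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", ""),
                    "contig": fields[0],
                    "strand": fields[6],
                    "exons": [],
                },
            )
            tx["exons"].append((start1 - 1, end1))  # GTF is 1-based inclusive
    return transcripts


def junctions_from_gtf(gtf_path: str, genome: GenomeIndex) -> list[Junction]:
    """Introns between consecutive exons of each transcript, merged across transcripts.

    support = number of transcripts containing the intron; sources accumulate
    transcript ids.  Transcripts with internally overlapping exons are skipped.
    """
    merged: dict[tuple[str, int, int], list[str]] = {}
    for tid, tx in read_gtf_exons(gtf_path).items():
        exons = sorted(tx["exons"])
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            logger.warning("transcript %s has overlapping exons, skipped", tid)
            continue
        for (_, prev_end), (next_start, _) in zip(exons, exons[1:]):
            merged.setdefault((tx["contig"], prev_end, next_start), []).append(tid)
    return [
        Junction(c, s, e, motif=_motif(genome, c, s, e), support=len(tids), sources=tids)
        for (c, s, e), tids in sorted(merged.items())
    ]


def junctions_from_bed(bed_path: str, genome: GenomeIndex) -> list[Junction]:
    """BED3/BED6 intervals taken as introns directly; score column -> support."""
    out: list[Junction] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError):
                logger.warning("%s:%d malformed BED line, skipped", bed_path, lineno)
                continue
            if end <= start:
                logger.warning("%s:%d end <= start, skipped", bed_path, lineno)
                continue
            support = 1
            if len(fields) >= 5:
                try:
                    support = int(float(fields[4]))
                except ValueError:
                    support = 1
            out.append(
                Junction(contig, start, end, motif=_motif(genome, contig, start, end),
                         support=max(support, 1))
            )
    return out
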