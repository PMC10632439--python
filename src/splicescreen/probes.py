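"""30 bp probes and their genomic occurrence counts.

Once the two flank windows of a junction align to each other, the question
becomes how often the aligned sequence occurs in the genome: a repeat that
occurs in many places is the signature of a misalignment-prone locus.
Three probes are taken — one centered on the aligned span of each flank
window, and a *hybrid* probe concatenating the ``hybrid_half`` exonic bases
immediately upstream of the donor with those immediately downstream of the
acceptor.  The hybrid is chimeric across the junction, so any contiguous
genomic occurrence means the "junction" matches a real contiguous sequence
(e.g. the next copy of a tandem repeat).

Occurrence counting is end-to-end Hamming matching on both strands of every
contig: a probe occurs at a position when it matches with at most
``max_mismatches`` mismatches and no gaps.  Overlapping occurrences all
count; counting is capped at ``count_cap`` (above every decision threshold,
so the cap never changes a verdict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flank import FlankAlignment, FlankPair, GeometryParams
from .genome_io import GenomeIndex, fetch, revcomp, _ENCODE
from .junctions import Junction


@dataclass(frozen=True)
class OccurrenceParams:
    """Occurrence-count thresholds for the spurious/retained decision."""

    max_mismatches: int = 1
    two_anchor_multi_threshold: int = 1   # "multi-mapping" means count strictly above this
    one_anchor_repeat_threshold: int = 10  # "high-frequency" means count at/above this
    count_cap: int = 11

    def __post_init__(self) -> None:
        if self.count_cap <= max(self.two_anchor_multi_threshold,
                                 self.one_anchor_repeat_threshold):
            raise ValueError("count_cap must exceed both decision thresholds")


@dataclass
class Probe:
    seq: str
    valid: bool
    count: int = 0


@dataclass
class ProbeSet:
    """The three probes of a junction with occurrence counts."""

    up: Probe
    down: Probe
    hybrid: Probe

    @property
    def all_valid(self) -> bool:
        return self.up.valid and self.down.valid and self.hybrid.valid


def _genome_probe(genome: GenomeIndex, contig: str, start: int, end: int,
                  expected_len: int) -> Probe:
    seq = fetch(genome, contig, start, end) if start < end else ""
    return Probe(seq=seq, valid=len(seq) == expected_len)


def make_probes(j: Junction, a: FlankAlignment, fp: FlankPair,
                genome: GenomeIndex, g: GeometryParams) -> ProbeSet:
    """Build the up/down/hybrid probes for an aligned junction.

    The up (down) probe is the probe_len window centered on the midpoint of
    the aligned span in the donor (acceptor) flank window, re-fetched from
    the genome so that a center near a window edge still yields a full-length
    probe when the contig allows; a probe truncated by a contig edge is
    marked invalid.
    """
    half = g.probe_len // 2
    ref_center = fp.ref_origin + (a.ref_start + a.ref_end) // 2
    query_center = fp.query_origin + (a.query_start + a.query_end) // 2
    up = _genome_probe(genome, j.contig, ref_center - half, ref_center + half, g.probe_len)
    down = _genome_probe(genome, j.contig, query_center - half, query_center + half,
                         g.probe_len)
    left = fetch(genome, j.contig, j.start - g.hybrid_half, j.start) \
        if j.start > 0 else ""
    right = fetch(genome, j.contig, j.end, j.end + g.hybrid_half) \
        if j.end < genome.lengths[j.contig] else ""
    hybrid_seq = left + right
    hybrid = Probe(seq=hybrid_seq, valid=len(hybrid_seq) == g.probe_len)
    return ProbeSet(up=up, down=down, hybrid=hybrid)


def _count_one_strand(probe_arr: np.ndarray, contig_arr: np.ndarray,
                      max_mismatches: int) -> int:
    L = probe_arr.size
    if contig_arr.size < L:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(contig_arr, L)
    mismatches = (windows != probe_arr).sum(axis=1)
    return int((mismatches <= max_mismatches).sum())


def count_occurrences(probe: str, genome: GenomeIndex, p: OccurrenceParams) -> int:
    """Number of end-to-end Hamming occurrences of ``probe`` genome-wide.

    Both strands of every contig are scanned; positions where the probe (or
    its reverse complement) matches with at most ``max_mismatches``
    mismatches each count, overlapping ones included.  Counting stops at
    ``count_cap``.  Probes with more than len/3 ambiguous bases return 0
    (an N never matches an N in the genome: comparison is by character
    identity on the encoded alphabet, where N is its own symbol — two Ns
    compare equal; this only matters for N-rich regions that the validity
    rule already excludes).
    """
    if probe.count("N") > len(probe) / 3:
        return 0
    fwd = _ENCODE[np.frombuffer(probe.encode("ascii"), dtype=np.uint8)]
    rev = _ENCODE[np.frombuffer(revcomp(probe).encode("ascii"), dtype=np.uint8)]
    total = 0
    for contig in genome.contigs:
        arr = genome.encoded(contig)
        total += _count_one_strand(fwd, arr, p.max_mismatches)
        if total >= p.count_cap:
            return p.count_cap
        total += _count_one_strand(rev, arr, p.max_mismatches)
        if total >= p.count_cap:
            return p.count_cap
    return total


def fill_counts(ps: ProbeSet, genome: GenomeIndex, p: OccurrenceParams) -> ProbeSet:
    """Populate occurrence counts for every valid probe in place."""
    for probe in (ps.up, ps.down, ps.hybrid):
        if probe.valid:
            probe.count = count_occurrences(probe.seq, genome, p)
            if probe.seq.count("N") > len(probe.seq) / 3:
                probe.valid = False
    return ps
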