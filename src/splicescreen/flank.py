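"""Flank extraction, seeded two-piece-affine local alignment, and geometric
classification of the alignment.

The screen asks: do the sequences flanking a splice junction's donor and
acceptor resemble each other?  A 2×overhang window is taken around each
splice site (the "reference" window around the donor, the "query" window
around the acceptor, both on the forward genome strand) and the two windows
are locally aligned under a deliberately permissive scheme — +3 match,
−4 mismatch, and a two-piece gap cost

    cost(L) = min(gap_open_short + L·gap_extend_short,
                  gap_open_long  + L·gap_extend_long)

(12 + 2L vs 32 + L by default) so that long gaps in diverged homologous
copies stay affordable.  Alignment search is seeded: exact k-mer matches
(k=3) gate the dynamic programming, and the best local alignment scoring at
least ``min_chain_score`` (25) is reported.  The absence of an alignment is
a meaningful outcome — it is what genuine junctions in unique sequence
produce.

Classification is purely geometric.  An alignment is *two-anchor* when it
covers at least ``anchor`` exonic bases on both sides of both splice sites
with a small start-offset shift — i.e. a read from either side of the
"junction" could have been spuriously splice-aligned.  Everything else is
*one-anchor*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import GenomeIndex, fetch
from .junctions import Junction

TWO_ANCHOR = "TWO_ANCHOR"
ONE_ANCHOR = "ONE_ANCHOR"


@dataclass(frozen=True)
class GeometryParams:
    """Window geometry: exon overhang, minimum anchor, probe sizes (bases)."""

    overhang: int = 50
    anchor: int = 7
    probe_len: int = 30
    hybrid_half: int = 15

    def __post_init__(self) -> None:
        if min(self.overhang, self.anchor, self.probe_len, self.hybrid_half) <= 0:
            raise ValueError("all geometry parameters must be positive")
        if self.anchor >= self.overhang:
            raise ValueError("anchor must be smaller than overhang")
        if self.probe_len != 2 * self.hybrid_half:
            raise ValueError("probe_len must equal 2 * hybrid_half")


@dataclass(frozen=True)
class ScoringParams:
    """Permissive local-alignment scoring with a two-piece gap cost."""

    match: int = 3
    mismatch_penalty: int = 4
    gap_open_short: int = 12
    gap_extend_short: int = 2
    gap_open_long: int = 32
    gap_extend_long: int = 1
    seed_k: int = 3
    seed_window: int = 2
    min_chain_score: int = 25

    def __post_init__(self) -> None:
        pens = (self.mismatch_penalty, self.gap_open_short, self.gap_extend_short,
                self.gap_open_long, self.gap_extend_long)
        if min(pens) <= 0:
            raise ValueError("all penalties must be positive")

    def gap_cost(self, length: int) -> int:
        return min(self.gap_open_short + length * self.gap_extend_short,
                   self.gap_open_long + length * self.gap_extend_long)


@dataclass
class FlankPair:
    """The two flank windows of a junction, forward-strand, donor- and
    acceptor-centered; ``clipped`` flags contig-boundary truncation."""

    ref_seq: str
    query_seq: str
    ref_origin: int
    query_origin: int
    contig: str
    clipped: bool


@dataclass
class FlankAlignment:
    """Best local alignment between the two flank windows.

    Offsets are 0-based within each window, ends exclusive.  ``blocks`` are
    the gap-free runs as (ref_off, query_off, length); ``cigar`` is a
    compact M/I/D string (I = gap in ref, D = gap in query).
    """

    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    score: int
    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    cigar: str = ""


def extract_flanks(j: Junction, genome: GenomeIndex, g: GeometryParams) -> FlankPair:
    """Windows [donor−overhang, donor+overhang) and [acceptor−overhang,
    acceptor+overhang), both from the forward genome strand."""
    ov = g.overhang
    ref_seq = fetch(genome, j.contig, j.start - ov, j.start + ov)
    query_seq = fetch(genome, j.contig, j.end - ov, j.end + ov)
    clipped = len(ref_seq) < 2 * ov or len(query_seq) < 2 * ov
    return FlankPair(
        ref_seq=ref_seq,
        query_seq=query_seq,
        ref_origin=max(0, j.start - ov),
        query_origin=max(0, j.end - ov),
        contig=j.contig,
        clipped=clipped,
    )


def _shared_seed_exists(ref: str, query: str, k: int) -> bool:
    """Any exact N-free k-mer shared between the two sequences?"""
    seeds = set()
    for i in range(len(ref) - k + 1):
        kmer = ref[i : i + k]
        if "N" not in kmer:
            seeds.add(kmer)
    if not seeds:
        return False
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if "N" not in kmer and kmer in seeds:
            return True
    return False


# traceback codes
_STOP, _DIAG, _E1, _E2, _F1, _F2 = 0, 1, 2, 3, 4, 5
_NEG = -(10**9)


def _dp_matrices(ref: str, query: str, s: ScoringParams):
    """Two-piece affine local DP (Smith–Waterman with dual gap states).

    Returns (best score, list of best end cells, ptr, e1x, e2x, f1x, f2x);
    matrices are plain nested lists — faster per-cell access than ndarray
    scalars for this loop.
    """
    m, n = len(ref), len(query)
    width = n + 1
    ptr = [[_STOP] * width for _ in range(m + 1)]
    # gap-state flags: True = extension of an existing gap, False = opened from H
    e1x = [[False] * width for _ in range(m + 1)]
    e2x = [[False] * width for _ in range(m + 1)]
    f1x = [[False] * width for _ in range(m + 1)]
    f2x = [[False] * width for _ in range(m + 1)]

    o1 = s.gap_open_short + s.gap_extend_short
    o2 = s.gap_open_long + s.gap_extend_long
    x1, x2 = s.gap_extend_short, s.gap_extend_long
    match, mis = s.match, -s.mismatch_penalty

    h_prev = [0] * width
    e1_prev = [_NEG] * width
    e2_prev = [_NEG] * width
    best_score = 0
    best_ends: list[tuple[int, int]] = []
    for i in range(1, m + 1):
        ri = ref[i - 1]
        ri_is_n = ri == "N"
        h_row = [0] * width
        e1_row = [_NEG] * width
        e2_row = [_NEG] * width
        f1 = f2 = _NEG
        ptr_i, e1x_i, e2x_i, f1x_i, f2x_i = ptr[i], e1x[i], e2x[i], f1x[i], f2x[i]
        h_diag = h_prev[0]
        for j in range(1, n + 1):
            v = h_prev[j]
            open1 = v - o1
            ext1 = e1_prev[j] - x1
            if ext1 > open1:
                e1 = ext1
                e1x_i[j] = True
            else:
                e1 = open1
            open2 = v - o2
            ext2 = e2_prev[j] - x2
            if ext2 > open2:
                e2 = ext2
                e2x_i[j] = True
            else:
                e2 = open2
            hl = h_row[j - 1]
            open1 = hl - o1
            ext1 = f1 - x1
            if ext1 > open1:
                f1 = ext1
                f1x_i[j] = True
            else:
                f1 = open1
            open2 = hl - o2
            ext2 = f2 - x2
            if ext2 > open2:
                f2 = ext2
                f2x_i[j] = True
            else:
                f2 = open2
            # N never matches, not even N vs N
            best = h_diag + (match if (not ri_is_n and ri == query[j - 1]) else mis)
            code = _DIAG
            if e1 > best:
                best, code = e1, _E1
            if e2 > best:
                best, code = e2, _E2
            if f1 > best:
                best, code = f1, _F1
            if f2 > best:
                best, code = f2, _F2
            if best <= 0:
                best, code = 0, _STOP
            h_row[j] = best
            e1_row[j] = e1
            e2_row[j] = e2
            ptr_i[j] = code
            h_diag = v
            if best > best_score:
                best_score = best
                best_ends = [(i, j)]
            elif best == best_score and best > 0:
                best_ends.append((i, j))
        h_prev, e1_prev, e2_prev = h_row, e1_row, e2_row
    return best_score, best_ends, ptr, e1x, e2x, f1x, f2x


def _traceback(ref_end: int, query_end: int, ptr, e1x, e2x, f1x, f2x):
    """Walk pointers from an end cell back to the local start; return
    (ref_start, query_start, ops) with ops a list of (op_char, length)."""
    i, j = ref_end, query_end
    ops: list[tuple[str, int]] = []

    def push(op: str, length: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    while i > 0 and j > 0:
        code = ptr[i][j]
        if code == _STOP:
            break
        if code == _DIAG:
            push("M")
            i -= 1
            j -= 1
        elif code in (_E1, _E2):
            ext = e1x if code == _E1 else e2x
            while True:
                push("D")  # gap consumes ref
                extended = ext[i][j]
                i -= 1
                if not extended:
                    break
        else:
            ext = f1x if code == _F1 else f2x
            while True:
                push("I")  # gap consumes query
                extended = ext[i][j]
                j -= 1
                if not extended:
                    break
    ops.reverse()
    return i, j, ops


def _blocks_from_ops(ref_start: int, query_start: int, ops) -> list[tuple[int, int, int]]:
    blocks = []
    ri, qi = ref_start, query_start
    for op, length in ops:
        if op == "M":
            blocks.append((ri, qi, length))
            ri += length
            qi += length
        elif op == "D":
            ri += length
        else:
            qi += length
    return blocks


def align_flanks(fp: FlankPair, s: ScoringParams) -> FlankAlignment | None:
    """Best local alignment between the two flank windows, or None.

    Exact seed_k-mer sharing gates the dynamic programming (a full seed
    index — a superset of any minimizer sampling — so no seeded optimum is
    missed); alignments scoring below ``min_chain_score`` are not reported.
    Co-optimal alignments are broken by (smaller ref_start, smaller
    query_start).
    """
    ref, query = fp.ref_seq, fp.query_seq
    if not ref or not query:
        return None
    if not _shared_seed_exists(ref, query, s.seed_k):
        return None
    best, ends, ptr, e1x, e2x, f1x, f2x = _dp_matrices(ref, query, s)
    if best < s.min_chain_score:
        return None
    candidates = []
    for i_end, j_end in ends:
        rs, qs, ops = _traceback(i_end, j_end, ptr, e1x, e2x, f1x, f2x)
        candidates.append((rs, qs, i_end, j_end, ops))
    rs, qs, re_, qe, ops = min(candidates, key=lambda c: (c[0], c[1], c[2], c[3]))
    return FlankAlignment(
        ref_start=rs,
        ref_end=re_,
        query_start=qs,
        query_end=qe,
        score=best,
        blocks=_blocks_from_ops(rs, qs, ops),
        cigar="".join(f"{length}{op}" for op, length in ops),
    )


def classify(a: FlankAlignment, g: GeometryParams) -> str:
    """TWO_ANCHOR when the alignment anchors in the exon overhangs on both
    sides of both splice sites with a small shift; else ONE_ANCHOR.

    With defaults: starts ≤ 43 in both windows, last aligned offset ≥ 56 in
    both (END_RULE: the alignment covers ≥ anchor exonic bases past the
    splice site, 0-based), and |ref_start − query_start| < 14.
    """
    start_max = g.overhang - g.anchor
    last_min = g.overhang + g.anchor - 1  # last aligned 0-based offset
    shift_max = 2 * g.anchor
    ok = (
        a.ref_start <= start_max
        and a.query_start <= start_max
        and a.ref_end - 1 >= last_min
        and a.query_end - 1 >= last_min
        and abs(a.ref_start - a.query_start) < shift_max
    )
    return TWO_ANCHOR if ok else ONE_ANCHOR
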