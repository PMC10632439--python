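"""Assembly/annotation agreement metrics.

Sensitivity = TP / (TP + FN), precision = TP / (TP + FP), with TP/FP/FN
counted by exact-coordinate set comparison at the intron or exon level
(transcript level compares ordered intron chains; mono-exon transcripts
match on ≥1 bp exon overlap).  Percent change between a count before (x_i)
and after (x_f) filtering is (x_f − x_i) / x_i × 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class ComparisonResult:
    TP: int
    FP: int
    FN: int
    level: str
    precision_defined: bool = True
    sensitivity_defined: bool = True

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0


def compare_sets(predicted, reference, level: str = "intron") -> ComparisonResult:
    """Exact-coordinate TP/FP/FN between two interval sets keyed
    (contig, start, end); inputs are deduplicated by construction."""
    pred = set(predicted)
    ref = set(reference)
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    return ComparisonResult(
        TP=tp, FP=fp, FN=fn, level=level,
        precision_defined=bool(pred), sensitivity_defined=bool(ref),
    )


@dataclass
class ChangeResult:
    x_i: int
    x_f: int

    @property
    def percent_change(self) -> float:
        if self.x_i == 0:
            return math.nan
        return (self.x_f - self.x_i) / self.x_i * 100.0


def percent_change(x_i: float, x_f: float) -> float:
    """(x_f − x_i)/x_i × 100; NaN when x_i = 0 (undefined)."""
    if x_i == 0:
        return math.nan
    return (x_f - x_i) / x_i * 100.0


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def compare_transcripts(predicted, reference) -> ComparisonResult:
    """Transcript-level agreement.

    Each transcript is (contig, exon list of 0-based half-open intervals).
    Multi-exon transcripts match iff their ordered intron chains are
    identical; mono-exon transcripts match iff their exon overlaps a
    reference mono-exon transcript's exon by ≥1 bp on the same contig.
    """

    def chains_and_monos(txs):
        chains, monos = set(), []
        for contig, exons in txs:
            exons = sorted(exons)
            if len(exons) == 1:
                monos.append((contig, exons[0]))
            else:
                introns = tuple((e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]))
                chains.add((contig, introns))
        return chains, monos

    p_chains, p_monos = chains_and_monos(predicted)
    r_chains, r_monos = chains_and_monos(reference)
    tp = len(p_chains & r_chains)
    fp_chain = len(p_chains - r_chains)
    fn_chain = len(r_chains - p_chains)

    p_mono_hit = [
        any(c == rc and _overlaps(iv, riv) for rc, riv in r_monos) for c, iv in p_monos
    ]
    r_mono_hit = [
        any(c == pc and _overlaps(iv, piv) for pc, piv in p_monos) for c, iv in r_monos
    ]
    tp += sum(p_mono_hit)
    fp = fp_chain + sum(not h for h in p_mono_hit)
    fn = fn_chain + sum(not h for h in r_mono_hit)
    return ComparisonResult(TP=tp, FP=fp, FN=fn, level="transcript")
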