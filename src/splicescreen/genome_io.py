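"""Reference genome loading and exact subsequence access.

Sequences are normalized to the A/C/G/T/N alphabet on load (lowercase is
uppercased, IUPAC ambiguity codes collapse to N) so that downstream exact
and Hamming matching operate on a fixed alphabet.  All coordinates in this
package are 0-based, half-open; conversion to 1-based formats happens only
in readers and writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A/C/G/T/N -> 0..4 for numpy-encoded scanning
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    up = seq.upper()
    if set(up) <= _VALID:
        return up
    return "".join(c if c in _VALID else "N" for c in up)


@dataclass
class GenomeIndex:
    """In-memory genome: contig name -> normalized sequence."""

    contigs: dict[str, str]
    lengths: dict[str, int] = field(init=False)
    _encoded: dict[str, np.ndarray] = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.lengths = {name: len(seq) for name, seq in self.contigs.items()}

    def encoded(self, contig: str) -> np.ndarray:
        """uint8 encoding of a contig (A=0,C=1,G=2,T=3,N=4), cached."""
        arr = self._encoded.get(contig)
        if arr is None:
            arr = _ENCODE[np.frombuffer(self.contigs[contig].encode("ascii"), dtype=np.uint8)]
            self._encoded[contig] = arr
        return arr


def load_genome(fasta_path: str) -> GenomeIndex:
    """Read a (plain or bgzip) FASTA into a :class:`GenomeIndex`.

    Headers are truncated at the first whitespace.  Duplicate contig names
    and empty files are fatal.
    """
    contigs: dict[str, str] = {}
    try:
        with pysam.FastxFile(str(fasta_path)) as fx:
            for rec in fx:
                name = rec.name
                if name in contigs:
                    raise ValueError(f"duplicate contig name in FASTA: {name!r}")
                contigs[name] = normalize_sequence(rec.sequence or "")
    except OSError as exc:
        raise FileNotFoundError(f"cannot read FASTA {fasta_path!r}: {exc}") from exc
    if not contigs:
        raise ValueError(f"FASTA {fasta_path!r} contains no records")
    return GenomeIndex(contigs)


def fetch(genome: GenomeIndex, contig: str, start: int, end: int, clip: bool = True) -> str:
    """Return genome[contig][start:end].

    With ``clip=True`` (default) requests extending beyond the contig are
    clipped to [0, length); the caller detects clipping by the shorter
    return value.  With ``clip=False`` out-of-range coordinates raise.
    """
    if contig not in genome.contigs:
        raise KeyError(f"unknown contig: {contig!r}")
    if start >= end:
        raise ValueError(f"empty or inverted interval: [{start}, {end})")
    length = genome.lengths[contig]
    if clip:
        start = max(0, start)
        end = min(length, end)
        if start >= end:
            return ""
    elif start < 0 or end > length:
        raise ValueError(f"interval [{start}, {end}) outside contig {contig} (len {length})")
    return genome.contigs[contig][start:end]


def revcomp(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (N maps to N)."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]
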