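"""Independent brute-force oracles used only by the test suite.

These deliberately use different algorithmic formulations than the package:
the alignment oracle enumerates every gap length directly against the
two-piece cost function (no dual gap states), and the occurrence oracle is
a character-by-character sliding scan (no vectorization).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_COMP = str.maketrans("ACGTN", "TGCAN")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=False)
def _sw_two_piece(ref, query, match, mismatch, o1, e1, o2, e2):
    """Local alignment score, gap cost min(o1 + L*e1, o2 + L*e2), by direct
    enumeration of gap lengths.  A base coded 4 (N) never matches."""
    m, n = ref.size, query.size
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if ref[i - 1] == query[j - 1] and ref[i - 1] != 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] - mismatch
            for l in range(1, i + 1):
                cost = min(o1 + l * e1, o2 + l * e2)
                v = H[i - l, j] - cost
                if v > s:
                    s = v
            for l in range(1, j + 1):
                cost = min(o1 + l * e1, o2 + l * e2)
                v = H[i, j - l] - cost
                if v > s:
                    s = v
            if s < 0:
                s = 0
            H[i, j] = s
            if s > best:
                best = s
    return best


def sw_oracle_score(ref: str, query: str, match=3, mismatch=4,
                    gap_open_short=12, gap_extend_short=2,
                    gap_open_long=32, gap_extend_long=1) -> int:
    return int(_sw_two_piece(_encode(ref), _encode(query), match, mismatch,
                             gap_open_short, gap_extend_short,
                             gap_open_long, gap_extend_long))


def hamming_scan_count(probe: str, contigs: dict[str, str], max_mismatches: int,
                       cap: int | None = None) -> int:
    """Both-strand end-to-end Hamming occurrence count by direct scan."""
    total = 0
    L = len(probe)
    for query in (probe, probe.translate(_COMP)[::-1]):
        for seq in contigs.values():
            for pos in range(len(seq) - L + 1):
                mm = 0
                for k in range(L):
                    if seq[pos + k] != query[k]:
                        mm += 1
                        if mm > max_mismatches:
                            break
                else:
                    total += 1
                    if cap is not None and total >= cap:
                        return cap
    return total
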