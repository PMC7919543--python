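"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: plain-Python
dynamic programming for local alignment, direct tallies for assignment
error.  They are slow and simple on purpose.
"""

from __future__ import annotations

NEG = -(10**9)


def sw_score(a: str, b: str, match: int = 2, mismatch: int = -3,
             gap_open: int = -5, gap_extend: int = -2) -> int:
    """Affine-gap Smith-Waterman score by full DP.

    ``gap_open`` is the score of the first base of a gap and ``gap_extend``
    of each further base (a length-k gap scores open + (k-1)*extend).
    """
    n, m = len(a), len(b)
    H = [0] * (m + 1)
    E = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        diag = 0
        F = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[j] = max(H[j] + gap_open, E[j] + gap_extend)
            F = max(H[j - 1] + gap_open, F + gap_extend)
            s = diag + (match if ai == b[j - 1] else mismatch)
            diag = H[j]
            h = max(0, s, E[j], F)
            H[j] = h
            if h > best:
                best = h
    return best


def assignment_error_tally(assignments, truth, species_to_bin) -> tuple[int, int]:
    """(misassigned, mapped) by direct enumeration over reads."""
    wrong = mapped = 0
    for rid, src in truth.items():
        a = assignments.get(rid)
        if a is None:
            continue
        mapped += 1
        if species_to_bin[a] != species_to_bin[src]:
            wrong += 1
    return wrong, mapped
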