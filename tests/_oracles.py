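"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: alignment scores come
from a plain dynamic-programming matrix (numba-jitted), and the assembly
metrics from direct interval arithmetic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def sw_score(q, s, sub, gap_open, gap_extend):
    """Smith-Waterman local score with affine gaps (gap of length g costs
    gap_open + g * gap_extend).  Pass gap_open >= 10**6 for ungapped DP."""
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(
                E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open - gap_extend
            )
            F[i, j] = max(
                F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open - gap_extend
            )
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            h = max(h, E[i, j])
            h = max(h, F[i, j])
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def span_peptides(hit, qseq: str, sseq: str) -> tuple[str, str]:
    """Translations of the aligned segments implied by a translated hit."""
    from endosift._encode import revcomp
    from endosift.homsearch import six_frame_translate

    def seg(seq, span, frame):
        s = seq[span[0] : span[1]]
        if frame < 0:
            s = revcomp(s)
        return six_frame_translate(s + "TT")[1][: (span[1] - span[0]) // 3]

    return seg(qseq, hit.q_span, hit.q_frame), seg(sseq, hit.s_span, hit.s_frame)


def hit_matches_dp(hit, qseq: str, sseq: str) -> bool:
    """Does a hit's raw score equal the DP local score for its span?

    Translated hits are checked against ungapped DP, nucleotide hits against
    affine-gap DP with the engine's +2/-3, open 5 / extend 2 scheme."""
    from endosift._encode import encode_aa, encode_dna, revcomp
    from endosift.homsearch import _SUB_AA, _SUB_NT

    if hit.mode == "translated":
        pq, ps = span_peptides(hit, qseq, sseq)
        oracle = sw_score(
            encode_aa(pq), encode_aa(ps), _SUB_AA.astype(np.int64), 10**6, 0
        )
    else:
        qs = qseq[hit.q_span[0] : hit.q_span[1]]
        ss = sseq[hit.s_span[0] : hit.s_span[1]]
        if hit.q_frame < 0:
            qs = revcomp(qs)
        if hit.s_frame < 0:
            ss = revcomp(ss)
        oracle = sw_score(
            encode_dna(qs), encode_dna(ss), _SUB_NT.astype(np.int64), 5, 2
        )
    return oracle == int(hit.raw_score)


def brute_genome_fraction(blocks: list[tuple[int, int]], target_len: int) -> float:
    """Percent of covered positions, by explicit position sets (circular
    wrap allowed: end may exceed target_len)."""
    covered = set()
    for lo, hi in blocks:
        for p in range(lo, hi):
            covered.add(p % target_len)
    return 100.0 * len(covered) / target_len


def brute_nga50(blocks: list[tuple[int, int]], target_len: int) -> tuple[int, bool]:
    """(value, defined): largest L with blocks >= L cumulatively spanning
    half the target; undefined when coverage < 50%."""
    if not blocks:
        return 0, False
    if brute_genome_fraction(blocks, target_len) < 50.0:
        return 0, False
    lens = sorted((min(hi - lo, target_len) for lo, hi in blocks), reverse=True)
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= 0.5 * target_len:
            return ln, True
    return 0, False
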