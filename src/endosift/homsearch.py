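"""Local homology search in two modes: translated (six-frame x six-frame,
amino-acid scored — the TBLASTX-style mode) and nucleotide (strand x strand —
the megablast-style mode).

Seed-and-extend: exact word matches are grouped into diagonal clusters and a
cheap gapless score screens the clusters.  Surviving translated clusters are
scored exactly as ungapped diagonal segments (translated alignments carry no
gaps, as in the real translated-search program); surviving nucleotide
clusters are extended by exact local dynamic programming on a window around
the cluster (the window plays the role of the band).  Raw scores are
converted to bit scores with fixed Karlin-Altschul constants and to E-values
with a plain m*n search space (no effective-length correction).

E-values here approximate BLAST's; the contract is threshold behavior
(E < evalue_max), not E-value parity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from ._encode import AA_ALPHABET, encode_dna, kmer_codes, revcomp_codes

__all__ = [
    "Hit",
    "SearchParams",
    "six_frame_translate",
    "search",
    "best_hit_table",
    "KARLIN_ALTSCHUL",
]

# fixed, published Karlin-Altschul constants.  Translated alignments are
# ungapped (as in the real translated-search program), hence the ungapped
# BLOSUM62 constants; nucleotide mode is gapped +2/-3 with open 5 / extend 2.
KARLIN_ALTSCHUL = {
    "translated": {"lambda": 0.3176, "K": 0.134},
    "nucleotide": {"lambda": 0.625, "K": 0.41},
}

_GAP_COSTS = {"translated": (11, 1), "nucleotide": (5, 2)}
_NT_MATCH, _NT_MISMATCH = 2, -3


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    mode: str
    raw_score: float
    bit_score: float
    evalue: float
    identity: float
    q_span: tuple[int, int]  # 0-based half-open, forward strand, nt
    s_span: tuple[int, int]
    q_frame: int
    s_frame: int

    def as_row(self) -> dict:
        return {
            "query": self.query_id,
            "subject": self.subject_id,
            "mode": self.mode,
            "bits": self.bit_score,
            "evalue": self.evalue,
            "identity": self.identity,
            "q_start": self.q_span[0],
            "q_end": self.q_span[1],
            "s_start": self.s_span[0],
            "s_end": self.s_span[1],
            "q_frame": self.q_frame,
            "s_frame": self.s_frame,
        }


@dataclass(frozen=True)
class SearchParams:
    mode: str = "translated"
    word_size: int | None = None  # default: 4 aa (translated), 16 nt (nucleotide)
    sub_matrix: str | None = None  # "BLOSUM62" or "nt+2/-3"
    gap_open: int | None = None
    gap_extend: int | None = None
    evalue_max: float = 1e-12
    keep_best_only: bool = True
    # engine knobs (documented simplifications, not claims about BLAST)
    max_seed_gap: int | None = None  # residues; cluster split distance
    gapless_trigger: float | None = None  # raw score to enter gapped extension
    band: int = 15  # nt diagonals of slack either side of a cluster
    window_pad: int | None = None  # residues of context around a cluster

    def __post_init__(self) -> None:
        if self.mode not in ("translated", "nucleotide"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.word_size is not None and self.word_size < 2:
            raise ValueError("word_size must be >= 2")
        if self.sub_matrix is not None and self.sub_matrix not in (
            "BLOSUM62",
            "nt+2/-3",
        ):
            raise ValueError(f"unknown substitution matrix {self.sub_matrix!r}")

    @property
    def is_translated(self) -> bool:
        return self.mode == "translated"

    def resolved(self) -> "_Resolved":
        tr = self.is_translated
        return _Resolved(
            mode=self.mode,
            word_size=self.word_size or (4 if tr else 16),
            gap_open=self.gap_open if self.gap_open is not None else _GAP_COSTS[self.mode][0],
            gap_extend=self.gap_extend
            if self.gap_extend is not None
            else _GAP_COSTS[self.mode][1],
            evalue_max=self.evalue_max,
            keep_best_only=self.keep_best_only,
            max_seed_gap=self.max_seed_gap or (30 if tr else 90),
            gapless_trigger=self.gapless_trigger or (40.0 if tr else 32.0),
            band_res=max(2, self.band // 3) if tr else self.band,
            window_pad=self.window_pad or (60 if tr else 150),
        )


@dataclass(frozen=True)
class _Resolved:
    mode: str
    word_size: int
    gap_open: int
    gap_extend: int
    evalue_max: float
    keep_best_only: bool
    max_seed_gap: int
    gapless_trigger: float
    band_res: int
    window_pad: int


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

_AA_X = AA_ALPHABET.index("X")
_AA_STOP = AA_ALPHABET.index("*")

_CODON_LUT = np.full(125, _AA_X, dtype=np.uint8)  # base-5 codon codes, N -> X
for _c0 in range(4):
    for _c1 in range(4):
        for _c2 in range(4):
            _codon = "ACGT"[_c0] + "ACGT"[_c1] + "ACGT"[_c2]
            _aa = standard_dna_table.forward_table.get(_codon, "*")
            _CODON_LUT[_c0 * 25 + _c1 * 5 + _c2] = AA_ALPHABET.index(_aa)

_AA_CHARS = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)

_B62 = substitution_matrices.load("BLOSUM62")
_SUB_AA = np.zeros((24, 24), dtype=np.int16)
for _i, _a in enumerate(AA_ALPHABET):
    for _j, _b in enumerate(AA_ALPHABET):
        _SUB_AA[_i, _j] = int(_B62[_a, _b])

_SUB_NT = np.full((5, 5), _NT_MISMATCH, dtype=np.int16)
for _i in range(4):
    _SUB_NT[_i, _i] = _NT_MATCH
_SUB_NT[4, :] = _NT_MISMATCH
_SUB_NT[:, 4] = _NT_MISMATCH

_NT_MATRIX = substitution_matrices.Array("ACGTN", dims=2)
for _i, _a in enumerate("ACGTN"):
    for _j, _b in enumerate("ACGTN"):
        _NT_MATRIX[_a, _b] = (
            _NT_MATCH if (_a == _b and _a != "N") else _NT_MISMATCH
        )


def _translate_codes(codes: np.ndarray) -> np.ndarray:
    n = len(codes) // 3
    if n == 0:
        return np.empty(0, dtype=np.uint8)
    c = codes[: 3 * n].reshape(n, 3).astype(np.int32)
    return _CODON_LUT[c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]]


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six conceptual translations of a DNA string.

    Frames +1..+3 read the forward strand at offsets 0..2; frames -1..-3 read
    the reverse complement likewise.  Codons containing N translate to 'X',
    stops to '*'; trailing partial codons are dropped.
    """
    codes = encode_dna(seq)
    rc = revcomp_codes(codes)
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        out[f] = _AA_CHARS[_translate_codes(codes[f - 1 :])].tobytes().decode()
        out[-f] = _AA_CHARS[_translate_codes(rc[f - 1 :])].tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# search engine
# ---------------------------------------------------------------------------

def _norm_seqs(seqs) -> list[tuple[str, str]]:
    if isinstance(seqs, dict):
        return [(str(k), str(v)) for k, v in seqs.items()]
    out = []
    for item in seqs:
        if isinstance(item, str):
            raise TypeError("sequences must be (id, seq) pairs or a dict")
        out.append((str(item[0]), str(item[1])))
    if not out:
        raise ValueError("empty sequence set")
    return out


def _frames_of(seq: str, translated: bool) -> list[tuple[int, np.ndarray]]:
    """Residue code arrays per frame: 6 peptide frames, or the two strands."""
    codes = encode_dna(seq)
    if translated:
        rc = revcomp_codes(codes)
        frames = []
        for f in (1, 2, 3):
            frames.append((f, _translate_codes(codes[f - 1 :])))
            frames.append((-f, _translate_codes(rc[f - 1 :])))
        return frames
    return [(1, codes), (-1, revcomp_codes(codes))]


def _frame_to_forward_nt(
    frame: int, res_start: int, res_end: int, seq_len: int, translated: bool
) -> tuple[int, int]:
    """Map a frame-local residue span to a forward-strand nt span."""
    if translated:
        off = abs(frame) - 1
        lo, hi = off + 3 * res_start, off + 3 * res_end
    else:
        lo, hi = res_start, res_end
    if frame > 0:
        return lo, hi
    return seq_len - hi, seq_len - lo


class _SubjectIndex:
    """Word index over the concatenated frames of a subject set."""

    def __init__(self, subjects: list[tuple[str, str]], r: _Resolved) -> None:
        translated = r.mode == "translated"
        self.base = 24 if translated else 4
        self.frames: list[tuple[int, int]] = []  # (subject idx, frame)
        self.frame_seqs: list[np.ndarray] = []
        self.subject_ids = [sid for sid, _ in subjects]
        self.subject_lens = [len(s) for _, s in subjects]
        self.total_nt = sum(self.subject_lens)
        offsets = [0]
        words, positions = [], []
        for si, (_, seq) in enumerate(subjects):
            for frame, codes in _frames_of(seq, translated):
                fid = len(self.frames)
                self.frames.append((si, frame))
                self.frame_seqs.append(codes)
                w, valid = kmer_codes(codes, r.word_size, base=self.base)
                if translated and len(w):
                    # do not seed across stop/X/B/Z columns
                    bad = codes >= 20
                    if bad.any():
                        cs = np.concatenate([[0], np.cumsum(bad)])
                        valid &= (cs[r.word_size :] - cs[: -r.word_size]) == 0
                idx = np.flatnonzero(valid)
                words.append(w[idx])
                positions.append(idx.astype(np.int64) + offsets[-1])
                offsets.append(offsets[-1] + len(codes))
        self.frame_offsets = np.array(offsets, dtype=np.int64)
        self.concat = (
            np.concatenate(self.frame_seqs)
            if self.frame_seqs
            else np.empty(0, np.uint8)
        )
        all_words = np.concatenate(words) if words else np.empty(0, np.uint64)
        all_pos = np.concatenate(positions) if positions else np.empty(0, np.int64)
        order = np.argsort(all_words, kind="stable")
        self.sorted_words = all_words[order]
        self.sorted_pos = all_pos[order]

    def frame_of_global(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.frame_offsets, gpos, side="right") - 1


def _gapless_batch(
    qcodes: np.ndarray,
    sub: _SubjectIndex,
    qpos: np.ndarray,
    sglob: np.ndarray,
    fids: np.ndarray,
    r: _Resolved,
    sub_matrix: np.ndarray,
) -> np.ndarray:
    """Best gapless score through each seed, on a fixed window, vectorized."""
    w = r.word_size
    pad = 48 if r.mode == "translated" else 120
    offs = np.arange(-pad, w + pad)
    nq = len(qcodes)
    qi = qpos[:, None] + offs[None, :]
    si = sglob[:, None] + offs[None, :]
    flo = sub.frame_offsets[fids][:, None]
    fhi = sub.frame_offsets[fids + 1][:, None]
    ok = (qi >= 0) & (qi < nq) & (si >= flo) & (si < fhi)
    qv = qcodes[np.clip(qi, 0, nq - 1)]
    sv = sub.concat[np.clip(si, 0, max(len(sub.concat) - 1, 0))]
    sc = sub_matrix[qv, sv].astype(np.int32)
    sc[~ok] = -10_000
    cs = np.cumsum(sc, axis=1)
    seed_start, seed_end = pad, pad + w
    left = np.minimum.accumulate(cs, axis=1)[:, seed_start - 1]
    left = np.minimum(left, 0)
    right = np.maximum.accumulate(cs[:, ::-1], axis=1)[:, ::-1][:, seed_end - 1]
    return right - left


def _kadane_through(
    scores: np.ndarray, lo: int, hi: int
) -> float:
    """Max-sum subarray constrained to contain [lo, hi)."""
    cs = np.concatenate([[0], np.cumsum(scores)])
    left = cs[: lo + 1].min()
    right = cs[hi:].max()
    return float(right - left)


def _best_segment(scores: np.ndarray) -> tuple[float, int, int]:
    """Max-sum subarray with 0-based half-open span (Kadane, vectorized)."""
    cs = np.concatenate([[0], np.cumsum(scores, dtype=np.int64)])
    runmin = np.minimum.accumulate(cs[:-1])
    vals = cs[1:] - runmin
    r = int(np.argmax(vals))
    l = int(np.argmin(cs[: r + 1]))
    return float(vals[r]), l, r + 1


def _best_diag_segment(
    qcodes: np.ndarray,
    scodes: np.ndarray,
    diag: int,
    qlo: int,
    qhi: int,
    sub_matrix: np.ndarray,
) -> tuple[float, int, int, int, int, float] | None:
    """Exact best ungapped segment along one diagonal within a query window.

    Returns (score, q0, q1, s0, s1, identity) in frame-local residue
    coordinates, or None if the diagonal does not intersect the window."""
    lo = max(qlo, diag)
    hi = min(qhi, len(scodes) + diag, len(qcodes))
    if hi - lo <= 0:
        return None
    qseg = qcodes[lo:hi]
    sseg = scodes[lo - diag : hi - diag]
    sc = sub_matrix[qseg, sseg].astype(np.int64)
    score, a, b = _best_segment(sc)
    if score <= 0 or b <= a:
        return None
    matches = int(np.count_nonzero(qseg[a:b] == sseg[a:b]))
    identity = matches / (b - a)
    return score, lo + a, lo + b, lo + a - diag, lo + b - diag, identity


def _make_aligner(r: _Resolved) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if r.mode == "translated":
        aligner.substitution_matrix = _B62
    else:
        aligner.substitution_matrix = _NT_MATRIX
    aligner.open_gap_score = -(r.gap_open + r.gap_extend)
    aligner.extend_gap_score = -r.gap_extend
    return aligner


def _decode_res(codes: np.ndarray, translated: bool) -> str:
    chars = _AA_CHARS if translated else np.frombuffer(b"ACGTN", dtype=np.uint8)
    return chars[codes].tobytes().decode()


def _align_window(
    aligner: Align.PairwiseAligner,
    qcodes: np.ndarray,
    scodes: np.ndarray,
    qlo: int,
    qhi: int,
    slo: int,
    shi: int,
    translated: bool,
) -> tuple[float, int, int, int, int, float] | None:
    """Local alignment of a window; returns (score, q0, q1, s0, s1, identity)
    in frame-local residue coordinates."""
    qs = _decode_res(qcodes[qlo:qhi], translated)
    ss = _decode_res(scodes[slo:shi], translated)
    if not qs or not ss:
        return None
    alns = aligner.align(qs, ss)
    if alns.score <= 0:
        return None
    aln = alns[0]
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    s0, s1 = int(sblocks[0][0]), int(sblocks[-1][1])
    matches = 0
    aligned_cols = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        a = np.frombuffer(qs[qa:qb].encode(), np.uint8)
        b = np.frombuffer(ss[sa:sb].encode(), np.uint8)
        matches += int((a == b).sum())
        aligned_cols += qb - qa
    gaps = (q1 - q0 - aligned_cols) + (s1 - s0 - aligned_cols)
    columns = aligned_cols + gaps
    identity = matches / columns if columns else 0.0
    return float(alns.score), qlo + q0, qlo + q1, slo + s0, slo + s1, identity


_MAX_WINDOW_CELLS = 24_000_000


def search(
    queries, subjects, params: SearchParams | None = None
) -> list[Hit]:
    """Seed-and-extend local search of every query against a subject set.

    Returns hits with E < ``evalue_max``; with ``keep_best_only`` (the
    num-alignments=1 behavior) only the best hit per query is kept
    (max bit score, tie -> lower E, tie -> lexicographic subject id).
    """
    params = params or SearchParams()
    r = params.resolved()
    queries = _norm_seqs(queries)
    subjects = _norm_seqs(subjects)
    translated = r.mode == "translated"
    sub = _SubjectIndex(subjects, r)
    sub_matrix = _SUB_AA if translated else _SUB_NT
    aligner = _make_aligner(r)
    ka = KARLIN_ALTSCHUL[r.mode]
    lam, kk = ka["lambda"], ka["K"]
    base = 24 if translated else 4
    hits: list[Hit] = []

    for qid, qseq in queries:
        qlen_nt = len(qseq)
        qhits: list[Hit] = []
        qframes = _frames_of(qseq, translated)
        if not translated:
            qframes = qframes[:1]  # subject strands already cover both senses
        for qframe, qcodes in qframes:
            if len(qcodes) < r.word_size:
                continue
            qwords, qvalid = kmer_codes(qcodes, r.word_size, base=base)
            if translated:
                bad = qcodes >= 20
                if bad.any():
                    cs = np.concatenate([[0], np.cumsum(bad)])
                    qvalid &= (cs[r.word_size :] - cs[: -r.word_size]) == 0
            qv_idx = np.flatnonzero(qvalid)
            if len(qv_idx) == 0:
                continue
            qw = qwords[qv_idx]
            lo = np.searchsorted(sub.sorted_words, qw, side="left")
            hi = np.searchsorted(sub.sorted_words, qw, side="right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            rep = np.repeat(np.arange(len(qw)), counts)
            starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
            flat = lo[rep] + (np.arange(total) - starts[rep])
            seed_q = qv_idx[rep]
            seed_g = sub.sorted_pos[flat]
            fids = sub.frame_of_global(seed_g)
            s_local = seed_g - sub.frame_offsets[fids]
            diag = seed_q.astype(np.int64) - s_local

            # cluster seeds by (frame, diagonal runs)
            order = np.lexsort((seed_q, diag, fids))
            seed_q, seed_g, fids, s_local, diag = (
                a[order] for a in (seed_q, seed_g, fids, s_local, diag)
            )
            new = np.ones(total, dtype=bool)
            if total > 1:
                same = (
                    (fids[1:] == fids[:-1])
                    & (np.abs(diag[1:] - diag[:-1]) <= r.band_res)
                    & (seed_q[1:] - seed_q[:-1] <= r.max_seed_gap)
                )
                new[1:] = ~same
            cluster_id = np.cumsum(new) - 1
            n_clusters = int(cluster_id[-1]) + 1
            cstart = np.flatnonzero(new)
            cend = np.concatenate([cstart[1:], [total]])
            csize = cend - cstart

            # cheap gapless screen
            singles = csize == 1
            keep = np.zeros(n_clusters, dtype=bool)
            if singles.any():
                si = cstart[singles]
                g = _gapless_batch(
                    qcodes, sub, seed_q[si], seed_g[si], fids[si], r, sub_matrix
                )
                keep[singles] = g >= r.gapless_trigger
            multi = np.flatnonzero(~singles)
            for ci in multi:
                a, b = cstart[ci], cend[ci]
                fid = int(fids[a])
                scodes = sub.frame_seqs[fid]
                d = int(np.median(diag[a:b]))
                qlo = max(0, int(seed_q[a]) - r.window_pad, d)
                qhi = min(
                    len(qcodes),
                    int(seed_q[b - 1]) + r.word_size + r.window_pad,
                    len(scodes) + d,
                )
                if qhi <= qlo:
                    continue
                qseg = qcodes[qlo:qhi]
                sseg = scodes[qlo - d : qhi - d]
                sc = sub_matrix[qseg, sseg].astype(np.int64)
                rel_lo = max(0, int(seed_q[a]) - qlo)
                rel_hi = min(qhi - qlo, rel_lo + r.word_size)
                if rel_hi <= rel_lo:
                    continue
                if _kadane_through(sc, rel_lo, rel_hi) >= r.gapless_trigger:
                    keep[ci] = True

            for ci in np.flatnonzero(keep):
                a, b = cstart[ci], cend[ci]
                fid = int(fids[a])
                si_idx, sframe = sub.frames[fid]
                scodes = sub.frame_seqs[fid]
                results: list[tuple[float, int, int, int, int, float]] = []
                if translated:
                    # translated alignments are ungapped: score each distinct
                    # seed diagonal exactly and keep the best segment
                    qlo = max(0, int(seed_q[a]) - r.window_pad)
                    qhi = min(
                        len(qcodes), int(seed_q[b - 1]) + r.word_size + r.window_pad
                    )
                    for d in sorted(set(int(x) for x in diag[a:b])):
                        res = _best_diag_segment(
                            qcodes, scodes, d, qlo, qhi, sub_matrix
                        )
                        if res is not None:
                            results.append(res)
                    if results:
                        results = [max(results, key=lambda t: t[0])]
                else:
                    stack = [(int(seed_q[a]), int(seed_q[b - 1]))]
                    dmin, dmax = int(diag[a:b].min()), int(diag[a:b].max())
                    while stack:
                        qa, qb = stack.pop()
                        qlo = max(0, qa - r.window_pad)
                        qhi = min(len(qcodes), qb + r.word_size + r.window_pad)
                        slo_ = max(0, qlo - dmax - r.band_res)
                        shi_ = min(len(scodes), qhi - dmin + r.band_res)
                        if (
                            (qhi - qlo) * (shi_ - slo_) > _MAX_WINDOW_CELLS
                            and qb - qa > 200
                        ):
                            mid = (qa + qb) // 2
                            stack.append((qa, mid + 100))
                            stack.append((mid - 100, qb))
                            continue
                        res = _align_window(
                            aligner, qcodes, scodes, qlo, qhi, slo_, shi_, translated
                        )
                        if res is not None:
                            results.append(res)
                for score, q0, q1, s0, s1, ident in results:
                    bits = (lam * score - np.log(kk)) / np.log(2)
                    evalue = qlen_nt * sub.total_nt * float(2.0 ** (-bits))
                    if evalue >= r.evalue_max:
                        continue
                    sid = sub.subject_ids[si_idx]
                    slen_nt = sub.subject_lens[si_idx]
                    q_span = _frame_to_forward_nt(qframe, q0, q1, qlen_nt, translated)
                    s_span = _frame_to_forward_nt(sframe, s0, s1, slen_nt, translated)
                    qhits.append(
                        Hit(
                            query_id=qid,
                            subject_id=sid,
                            mode=r.mode,
                            raw_score=score,
                            bit_score=float(bits),
                            evalue=float(evalue),
                            identity=ident,
                            q_span=q_span,
                            s_span=s_span,
                            q_frame=qframe,
                            s_frame=sframe,
                        )
                    )
        hits.extend(_dedupe(qhits, keep_best=r.keep_best_only))
    return hits


def _hit_rank(h: Hit) -> tuple:
    return (-h.bit_score, h.evalue, h.subject_id, h.q_span, h.s_span, h.s_frame)


def _dedupe(qhits: list[Hit], keep_best: bool) -> list[Hit]:
    if not qhits:
        return []
    qhits = sorted(qhits, key=_hit_rank)
    if keep_best:
        return [qhits[0]]
    out: list[Hit] = []
    for h in qhits:
        dup = False
        for o in out:
            if (
                o.subject_id == h.subject_id
                and o.q_frame == h.q_frame
                and o.s_frame == h.s_frame
                and _overlap(o.q_span, h.q_span) > 0.5 * (h.q_span[1] - h.q_span[0])
                and _overlap(o.s_span, h.s_span) > 0.5 * (h.s_span[1] - h.s_span[0])
            ):
                dup = True
                break
        if not dup:
            out.append(h)
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def best_hit_table(hits: Iterable[Hit]) -> dict[str, Hit]:
    """Deterministic best hit per query (max bits, tie -> lower E, then
    lexicographically smaller subject id)."""
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return best


def hits_to_frame(hits: Iterable[Hit]):
    import pandas as pd

    return pd.DataFrame([h.as_row() for h in hits])
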