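"""Greedy overlap-layout-consensus paired-end assembler and read mapper.

Parameterized by the two flags that matter to the downstream strategy:
minimum overlap identity (``mi``, percent) and minimum overlap length
(``ml``, nt).  Assembly is deterministic seed-and-extend unitigging over a
shared-k-mer overlap prefilter: contigs grow by the furthest-reaching
qualifying overlap; conflicting qualifying extensions (two distinct
continuations) are branch points and stop extension.  Paired-end
information joins contig ends that are linked by enough consistently
oriented pairs and actually overlap (no N-gaps are ever emitted).

Mapping classifies each read against a contig set as Full (entire read
aligned at >= mi), Partial (>= ml read bases aligned at >= mi, e.g. a read
overhanging a contig end), or Unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._encode import decode_dna, encode_dna, kmer_codes, revcomp_codes
from .synthdata import ReadPair, ReadRecord

__all__ = [
    "AsmParams",
    "Contig",
    "Assembly",
    "MappingRecord",
    "assemble",
    "map_reads",
    "detect_overlaps",
    "find_overlaps",
]

_K = 21  # overlap-prefilter k-mer
_BRANCH_MIN = 8  # nt of conflicting extension needed to call a branch


@dataclass(frozen=True)
class AsmParams:
    min_overlap_identity: float = 90.0  # percent ("mi")
    min_overlap_len: int = 40  # nt ("ml")
    min_contig_len: int = 100
    use_pairs: bool = True
    insert_mean: float = 230.0
    insert_sd: float = 25.0
    pair_join_min_links: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_identity <= 100):
            raise ValueError("min_overlap_identity must be in (0, 100]")
        if self.min_overlap_len <= 0 or self.min_contig_len <= 0:
            raise ValueError("lengths must be positive")

    @property
    def max_mismatch_frac(self) -> float:
        return 1.0 - self.min_overlap_identity / 100.0


@dataclass
class Contig:
    id: str
    seq: str
    mean_depth: float
    members: list[tuple[str, int, str]]  # (read_id, offset, strand)
    circular_hint: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    contigs: list[Contig]

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def total_len(self) -> int:
        return sum(len(c.seq) for c in self.contigs)

    @property
    def max_len(self) -> int:
        return max((len(c.seq) for c in self.contigs), default=0)

    def as_fasta_records(self) -> list[tuple[str, str]]:
        return [(c.id, c.seq) for c in self.contigs]


class MappingRecord(NamedTuple):
    read_id: str
    contig_id: str | None
    start: int  # contig coordinates of the aligned part, 0-based half-open
    end: int
    strand: str
    cls: str  # "Full" | "Partial" | "Unmapped"
    identity: float

    @property
    def mapped(self) -> bool:
        return self.cls in ("Full", "Partial")


_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


class _ReadSet:
    """Oriented code arrays for a set of sequences (reads or unitigs).

    All forward sequences live in one concatenated array, followed by all
    reverse complements; per-read views keep random access cheap."""

    def __init__(self, ids: list[str], arrays: list[np.ndarray]) -> None:
        self.ids = ids
        self.lens = np.array([len(a) for a in arrays], dtype=np.int64)
        n = len(arrays)
        total = int(self.lens.sum())
        self.total = total
        self.offs = np.concatenate([[0], np.cumsum(self.lens)])
        concat = np.empty(2 * total, dtype=np.uint8)
        pos = 0
        for a in arrays:
            concat[pos : pos + len(a)] = a
            pos += len(a)
        # reverse complement block: complement in one pass, reverse per read
        if total:
            concat[total:] = _COMP[concat[:total]]
            for i in range(n):
                v = concat[total + self.offs[i] : total + self.offs[i + 1]]
                v[:] = v[::-1]
        self.concat = concat
        self.fwd = [concat[self.offs[i] : self.offs[i + 1]] for i in range(n)]
        self.rc = [
            concat[total + self.offs[i] : total + self.offs[i + 1]]
            for i in range(n)
        ]

    @classmethod
    def from_reads(cls, reads: list[ReadRecord]) -> "_ReadSet":
        return cls([r.id for r in reads], [encode_dna(r.seq) for r in reads])

    def __len__(self) -> int:
        return len(self.ids)

    def oriented(self, ridx: int, orient: int) -> np.ndarray:
        return self.fwd[ridx] if orient == 0 else self.rc[ridx]


class _OverlapIndex:
    """Sorted k-mer table of read probe sites.

    Each oriented read is keyed by the k-mers at offsets {0, ml} so that a
    single sequencing error near the read start cannot hide it from the
    overlap prefilter.  Values pack (ridx << 2) | (orient << 1) | probe."""

    def __init__(self, reads: _ReadSet, ml: int) -> None:
        pows = 4 ** np.arange(_K - 1, -1, -1, dtype=np.uint64)
        codes_parts, packed_parts = [], []
        for orient in (0, 1):
            base = 0 if orient == 0 else reads.total
            for oi, off in enumerate((0, ml)):
                ok = reads.lens >= off + _K
                ridx = np.flatnonzero(ok)
                if len(ridx) == 0:
                    continue
                pos = base + reads.offs[ridx] + off
                win = reads.concat[pos[:, None] + np.arange(_K)[None, :]]
                good = (win < 4).all(axis=1)
                ridx, win = ridx[good], win[good]
                codes = (win.astype(np.uint64) * pows[None, :]).sum(axis=1)
                codes_parts.append(codes)
                packed_parts.append(
                    (ridx.astype(np.int64) << 2) | (orient << 1) | oi
                )
        if codes_parts:
            codes = np.concatenate(codes_parts)
            packed = np.concatenate(packed_parts)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.packed = packed[order]
        else:
            self.codes = np.empty(0, np.uint64)
            self.packed = np.empty(0, np.int64)


def _contig_tail_codes(arr: np.ndarray, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    if hi <= lo:
        return np.empty(0, np.uint64), np.empty(0, bool)
    return kmer_codes(arr[lo : hi + _K - 1], _K)


class _Extender:
    def __init__(
        self,
        reads: _ReadSet,
        index: _OverlapIndex,
        used: np.ndarray,
        params: AsmParams,
        strict_branch: bool = False,
    ) -> None:
        self.reads = reads
        self.index = index
        self.used = used
        self.p = params
        self.strict_branch = strict_branch
        self.offsets = (0, params.min_overlap_len)

    def extend_right(
        self, arr: np.ndarray, members: list[tuple[int, int, int]]
    ) -> tuple[np.ndarray, bool]:
        """Grow a contig rightwards until no qualifying extension or a branch.

        ``members`` holds (ridx, orient, contig_offset); returns the grown
        array and whether a branch stopped the extension."""
        reads, p = self.reads, self.p
        ml = p.min_overlap_len
        mmf = p.max_mismatch_frac
        L = len(arr)
        buf = np.empty(max(4 * L, 4096), dtype=np.uint8)
        buf[:L] = arr
        next_scan = 0
        # pending candidate overlaps: key -> [p0, verified_upto, mismatches]
        pending: dict[tuple[int, int], list[int]] = {}
        branched = False

        while True:
            hi = L - ml
            if next_scan <= hi:
                codes, valid = _contig_tail_codes(buf[:L], next_scan, hi)
                lo_a = np.searchsorted(self.index.codes, codes, side="left")
                hi_a = np.searchsorted(self.index.codes, codes, side="right")
                for j in np.flatnonzero(valid & (hi_a > lo_a)):
                    pos = next_scan + int(j)
                    for t in range(lo_a[j], hi_a[j]):
                        packed = int(self.index.packed[t])
                        ridx = packed >> 2
                        if self.used[ridx]:
                            continue
                        orient = (packed >> 1) & 1
                        off = self.offsets[packed & 1]
                        p0 = pos - off
                        key = (ridx, orient)
                        if p0 >= 0 and key not in pending:
                            pending[key] = [p0, p0, 0]
                next_scan = hi + 1

            # verify pending candidates incrementally; absorb contained reads
            qual: list[tuple[int, int, int, int, int]] = []
            drop: list[tuple[int, int]] = []
            for key, state in pending.items():
                ridx, orient = key
                if self.used[ridx]:
                    drop.append(key)
                    continue
                p0, upto, mism = state
                rlen = int(reads.lens[ridx])
                end = min(L, p0 + rlen)
                if end > upto:
                    rarr = reads.oriented(ridx, orient)
                    mism += int(
                        np.count_nonzero(
                            buf[upto:end] != rarr[upto - p0 : end - p0]
                        )
                    )
                    state[1], state[2] = end, mism
                ov = end - p0
                if mism > int(mmf * ov):
                    drop.append(key)
                    continue
                if p0 + rlen <= L:
                    self.used[ridx] = True
                    members.append((ridx, orient, p0))
                    drop.append(key)
                    continue
                qual.append((p0 + rlen - L, mism, ridx, orient, p0))
            for key in drop:
                del pending[key]

            if not qual:
                break
            qual.sort(key=lambda t: (-t[0], t[1], reads.ids[t[2]], t[3]))

            def _ext_of(entry):
                _, _, r2, o2, q0 = entry
                return self.reads.oriented(r2, o2)[L - q0 :]

            def _conflict(x: np.ndarray, y: np.ndarray) -> bool | None:
                n = min(len(x), len(y))
                if n < _BRANCH_MIN:
                    return None  # too short to vote
                return int(np.count_nonzero(x[:n] != y[:n])) > int(mmf * n)

            # pick an extension; a lone conflicting read is treated as noise,
            # but an alternative continuation supported by >=2 reads against a
            # chosen continuation supported by >=2 reads is a branch point
            # (in strict mode - used when merging polished unitigs, where
            # there is no error noise - any conflict is a branch)
            while qual:
                ext_len, _, ridx, orient, p0 = qual[0]
                cext = _ext_of(qual[0])
                conflicts, agree_chosen = [], 1
                for entry in qual[1:]:
                    c = _conflict(cext, _ext_of(entry))
                    if c is True:
                        conflicts.append(entry)
                    elif c is False:
                        agree_chosen += 1
                if not conflicts:
                    break
                if self.strict_branch:
                    branched = True
                    break
                alt = _ext_of(conflicts[0])
                alt_support = sum(
                    1
                    for entry in conflicts
                    if _conflict(alt, _ext_of(entry)) is False
                )
                if alt_support >= 2 and agree_chosen >= 2:
                    branched = True
                    break
                if alt_support >= 2:
                    # the chosen read itself looks erroneous; discard it
                    del pending[(ridx, orient)]
                    qual.pop(0)
                    continue
                break  # lone conflicting read: ignore it and extend
            if branched or not qual:
                break
            ext_len, _, ridx, orient, p0 = qual[0]
            cext = _ext_of(qual[0])
            if L + ext_len > len(buf):
                grown = np.empty(2 * (L + ext_len), dtype=np.uint8)
                grown[:L] = buf[:L]
                buf = grown
            buf[L : L + ext_len] = cext
            L += ext_len
            self.used[ridx] = True
            members.append((ridx, orient, p0))
            del pending[(ridx, orient)]

        return buf[:L].copy(), branched


def _flip_members(
    members: list[tuple[int, int, int]], L: int, lens: np.ndarray
) -> list[tuple[int, int, int]]:
    return [
        (ridx, 1 - orient, L - (off + int(lens[ridx])))
        for ridx, orient, off in members
    ]


def _consensus(
    arr: np.ndarray,
    members: list[tuple[int, int, int]],
    reads: _ReadSet,
) -> np.ndarray:
    """Per-column majority vote; ties keep the current base."""
    L = len(arr)
    if not members:
        return arr
    ridx = np.array([m[0] for m in members], dtype=np.int64)
    orient = np.array([m[1] for m in members], dtype=np.int64)
    off = np.array([m[2] for m in members], dtype=np.int64)
    rlen = reads.lens[ridx]
    src0 = np.where(orient == 0, reads.offs[ridx], reads.total + reads.offs[ridx])
    rep = np.repeat(np.arange(len(members)), rlen)
    within = np.arange(int(rlen.sum())) - np.repeat(
        np.concatenate([[0], np.cumsum(rlen)])[:-1], rlen
    )
    src = reads.concat[src0[rep] + within]
    tpos = off[rep] + within
    good = (tpos >= 0) & (tpos < L) & (src < 4)
    counts = np.bincount(
        tpos[good] * 4 + src[good], minlength=4 * L
    ).reshape(L, 4)
    winner = counts.argmax(axis=1).astype(np.uint8)
    cur = np.minimum(arr, 3)
    keep_cur = counts[np.arange(L), cur] >= counts[np.arange(L), winner]
    winner[keep_cur] = cur[keep_cur]
    covered = counts.sum(axis=1) > 0
    out = arr.copy()
    out[covered] = winner[covered]
    return out


def _circular_hint(arr: np.ndarray, params: AsmParams) -> bool:
    """Terminal self-overlap (prefix == suffix at >= mi over >= ml)."""
    L = len(arr)
    mmf = params.max_mismatch_frac
    for ov in range(min(L // 2, 2 * int(params.insert_mean)), params.min_overlap_len - 1, -1):
        if int(np.count_nonzero(arr[:ov] != arr[L - ov :])) <= int(mmf * ov):
            return True
    return False


def _pair_links(
    reads: _ReadSet,
    pair_of: np.ndarray,
    placements: dict[int, tuple[int, int, int]],
    contig_lens: list[int],
    params: AsmParams,
):
    """Collect cross-contig mate links as (cA, cB, flipB, gap) evidence."""
    links: dict[tuple[int, int, int], list[int]] = {}
    seen = set()
    for ridx, (ci, orient, off) in placements.items():
        mate = int(pair_of[ridx])
        if mate < 0 or mate in seen:
            continue
        seen.add(ridx)
        if mate not in placements:
            continue
        cj, orient2, off2 = placements[mate]
        if ci == cj:
            continue
        rlen, mlen = int(reads.lens[ridx]), int(reads.lens[mate])
        # distance from the read to the contig end the fragment points at
        if orient == 0:
            dA, endA = contig_lens[ci] - off, 1  # points right
        else:
            dA, endA = off + rlen, 0  # points left
        if orient2 == 0:
            dB, endB = contig_lens[cj] - off2, 1
        else:
            dB, endB = off2 + mlen, 0
        gap = int(params.insert_mean) - dA - dB
        # canonical key: join end A to end B; flipB when both ends face the
        # same direction (head-head or tail-tail)
        a, b = (ci, cj) if ci < cj else (cj, ci)
        if ci < cj:
            ea, eb = endA, endB
        else:
            ea, eb = endB, endA
        flip = 1 if ea == eb else 0
        links.setdefault((a, b, (ea << 1) | (eb ^ (0 if not flip else 0))), []).append(gap)
    return links


def _exact_join(
    a: np.ndarray, b: np.ndarray, max_ov: int, min_ov: int = 8
) -> int:
    """Largest exact suffix(a)/prefix(b) overlap in [min_ov, max_ov], or 0."""
    top = min(max_ov, len(a), len(b))
    for ov in range(top, min_ov - 1, -1):
        if np.array_equal(a[len(a) - ov :], b[:ov]):
            return ov
    return 0


def assemble(
    pairs: list[ReadPair] | list[ReadRecord], params: AsmParams | None = None
) -> Assembly:
    """Greedy OLC assembly of a paired-end read set (or bare reads)."""
    params = params or AsmParams()
    if not pairs:
        return Assembly(contigs=[])
    reads_list: list[ReadRecord] = []
    pair_of_list: list[int] = []
    for p in pairs:
        if isinstance(p, ReadRecord):
            reads_list.append(p)
            pair_of_list.append(-1)
            continue
        i = len(reads_list)
        reads_list.append(p.fwd)
        reads_list.append(p.rev)
        pair_of_list.extend([i + 1, i])
    reads = _ReadSet.from_reads(reads_list)
    pair_of = np.array(pair_of_list)
    index = _OverlapIndex(reads, params.min_overlap_len)
    used = np.zeros(len(reads), dtype=bool)
    ext = _Extender(reads, index, used, params)

    raw: list[tuple[np.ndarray, list[tuple[int, int, int]]]] = []
    for seed in range(len(reads)):
        if used[seed]:
            continue
        used[seed] = True
        arr = reads.fwd[seed].copy()
        members = [(seed, 0, 0)]
        arr, _ = ext.extend_right(arr, members)
        # extend the other end: reverse-complement and grow rightwards again
        arr = revcomp_codes(arr)
        members = _flip_members(members, len(arr), reads.lens)
        arr, _ = ext.extend_right(arr, members)
        arr = revcomp_codes(arr)
        members = _flip_members(members, len(arr), reads.lens)
        raw.append((arr, members))

    # polish unitigs, then merge unitigs whose ends overlap (greedy read
    # consumption leaves adjacent unitigs abutting with read-length overlaps)
    raw = [(_consensus(arr, members, reads), members) for arr, members in raw]
    raw = _merge_unitigs(raw, reads, params)

    if params.use_pairs:
        raw = _join_by_pairs(raw, reads, pair_of, params)

    raw = _absorb_redundant(raw, reads, params)

    contigs: list[Contig] = []
    for arr, members in raw:
        if len(arr) < params.min_contig_len:
            continue
        arr = _consensus(arr, members, reads)
        depth = sum(
            min(len(arr), off + int(reads.lens[r])) - max(0, off)
            for r, _, off in members
        ) / max(len(arr), 1)
        contigs.append(
            Contig(
                id="",
                seq=decode_dna(arr),
                mean_depth=depth,
                members=[
                    (reads.ids[r], off, "+" if o == 0 else "-")
                    for r, o, off in members
                ],
                circular_hint=_circular_hint(arr, params),
            )
        )
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    for i, c in enumerate(contigs):
        c.id = f"contig{i + 1:05d}"
    return Assembly(contigs=contigs)


def _compose_member(
    outer: tuple[int, int, int],
    inner_members: list[tuple[int, int, int]],
    inner_len: int,
    lens: np.ndarray,
) -> list[tuple[int, int, int]]:
    """Project members of a placed unitig into super-contig coordinates."""
    _, o, p0 = outer
    out = []
    for ridx, ro, roff in inner_members:
        if o == 0:
            out.append((ridx, ro, p0 + roff))
        else:
            out.append(
                (ridx, 1 - ro, p0 + inner_len - (roff + int(lens[ridx])))
            )
    return out


def _merge_unitigs(raw, reads: _ReadSet, params: AsmParams):
    """Greedy end-overlap merging of polished unitigs (strict branching)."""
    if len(raw) < 2:
        return raw
    order = sorted(range(len(raw)), key=lambda i: (-len(raw[i][0]), i))
    ids = [f"u{i:06d}" for i in range(len(raw))]
    cset = _ReadSet(ids, [arr for arr, _ in raw])
    index = _OverlapIndex(cset, params.min_overlap_len)
    used = np.zeros(len(cset), dtype=bool)
    ext = _Extender(cset, index, used, params, strict_branch=True)
    merged: list[tuple[np.ndarray, list[tuple[int, int, int]]]] = []
    for seed in order:
        if used[seed]:
            continue
        used[seed] = True
        arr = cset.fwd[seed].copy()
        cmembers = [(seed, 0, 0)]
        arr, _ = ext.extend_right(arr, cmembers)
        arr = revcomp_codes(arr)
        cmembers = _flip_members(cmembers, len(arr), cset.lens)
        arr, _ = ext.extend_right(arr, cmembers)
        arr = revcomp_codes(arr)
        cmembers = _flip_members(cmembers, len(arr), cset.lens)
        members: list[tuple[int, int, int]] = []
        for cm in cmembers:
            ci = cm[0]
            members.extend(
                _compose_member(cm, raw[ci][1], len(raw[ci][0]), reads.lens)
            )
        merged.append((arr, members))
    return merged


def _join_by_pairs(raw, reads: _ReadSet, pair_of: np.ndarray, params: AsmParams):
    """Join contig ends linked by >= pair_join_min_links consistently oriented
    pairs whose implied gap is within insert_mean +/- 4*insert_sd, when the
    ends actually overlap exactly (no gap filling)."""
    if len(raw) < 2:
        return raw
    placements: dict[int, tuple[int, int, int]] = {}
    for ci, (_, members) in enumerate(raw):
        for ridx, orient, off in members:
            placements[ridx] = (ci, orient, off)
    contig_lens = [len(arr) for arr, _ in raw]
    links = _pair_links(reads, pair_of, placements, contig_lens, params)

    tol = 4 * params.insert_sd
    merged: dict[int, int] = {}
    arrs = [arr for arr, _ in raw]
    membs = [list(m) for _, m in raw]
    for (a, b, endcode), gaps in sorted(links.items()):
        if len(gaps) < params.pair_join_min_links:
            continue
        gap = float(np.median(gaps))
        if not (-params.insert_mean - tol <= gap <= params.insert_mean + tol):
            continue
        ra, rb = merged.get(a, a), merged.get(b, b)
        if ra == rb:
            continue
        ea, eb = (endcode >> 1) & 1, endcode & 1
        A, B = arrs[ra], arrs[rb]
        # orient so that we join right end of A to left end of B
        if ea == 0:
            A = revcomp_codes(A)
            membs[ra] = _flip_members(membs[ra], len(A), reads.lens)
        if eb == 1:
            B = revcomp_codes(B)
            membs[rb] = _flip_members(membs[rb], len(B), reads.lens)
        max_ov = int(params.insert_mean + tol - gap) if gap < 0 else int(
            params.insert_mean + tol
        )
        ov = _exact_join(A, B, max_ov=min(max_ov, len(A), len(B)))
        if ov == 0:
            arrs[ra], membs[ra] = A, membs[ra]
            arrs[rb], membs[rb] = B, membs[rb]
            continue
        joined = np.concatenate([A, B[ov:]])
        shift = len(A) - ov
        membs[ra] = membs[ra] + [
            (r, o, off + shift) for r, o, off in membs[rb]
        ]
        arrs[ra] = joined
        arrs[rb] = np.empty(0, np.uint8)
        membs[rb] = []
        merged[b] = ra
        for k, v in list(merged.items()):
            if v == rb:
                merged[k] = ra
        merged[rb] = ra
    return [
        (arrs[i], membs[i]) for i in range(len(arrs)) if len(arrs[i]) > 0
    ]


def _absorb_redundant(raw, reads: _ReadSet, params: AsmParams):
    """Fold short contigs that align fully inside a longer contig (redundant
    unitigs seeded by error-bearing reads) into their host."""
    if len(raw) < 2:
        return raw
    order = sorted(range(len(raw)), key=lambda i: -len(raw[i][0]))
    mmf = params.max_mismatch_frac
    big_index: dict[int, list[tuple[int, int]]] = {}
    indexed: set[int] = set()
    out_flags = [True] * len(raw)

    def _index_contig(ci: int) -> None:
        arr = raw[ci][0]
        codes, valid = kmer_codes(arr, _K)
        for pos in np.flatnonzero(valid):
            big_index.setdefault(int(codes[pos]), []).append((ci, int(pos)))
        indexed.add(ci)

    for ci in order:
        arr, members = raw[ci]
        n = len(arr)
        absorbed = False
        if indexed:
            # dense probes: a handful of scattered errors must not be able
            # to break every anchor of a redundant error-bearing unitig
            probes = sorted({*range(0, max(1, n - _K + 1), 15), max(0, n - _K)})
            cands: set[tuple[int, int]] = set()
            for arrq in (arr, revcomp_codes(arr)):
                strand = 0 if arrq is arr else 1
                for off in probes:
                    if off + _K > n:
                        continue
                    w = arrq[off : off + _K]
                    if (w >= 4).any():
                        continue
                    code = 0
                    for v in w:
                        code = code * 4 + int(v)
                    for cj, pos in big_index.get(code, []):
                        cands.add((cj, pos - off, strand))
            for cj, p0, strand in sorted(cands):
                host = raw[cj][0]
                if p0 < 0 or p0 + n > len(host) or len(host) <= n:
                    continue
                q = arr if strand == 0 else revcomp_codes(arr)
                if int(np.count_nonzero(host[p0 : p0 + n] != q)) <= int(mmf * n):
                    host_members = raw[cj][1]
                    for r, o, off in members:
                        if strand == 0:
                            host_members.append((r, o, p0 + off))
                        else:
                            host_members.append(
                                (r, 1 - o, p0 + n - (off + int(reads.lens[r])))
                            )
                    out_flags[ci] = False
                    absorbed = True
                    break
        if not absorbed and len(arr) >= _K:
            _index_contig(ci)
    return [raw[i] for i in range(len(raw)) if out_flags[i]]


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def map_reads(
    reads: list[ReadRecord],
    contigs: list[Contig] | Assembly,
    params: AsmParams | None = None,
) -> list[MappingRecord]:
    """Map each read (both strands) to its best contig position.

    Full: the whole read aligns at >= mi.  Partial: >= ml read bases align at
    >= mi but not the whole read (overhanging an end or diverging).  Best
    position maximizes aligned-length x identity; ties go to the leftmost
    position on the lexicographically smallest contig id.
    """
    params = params or AsmParams()
    if isinstance(contigs, Assembly):
        contigs = contigs.contigs
    if not contigs:
        raise ValueError("map_reads requires a non-empty contig set")
    max_clen = max(len(c.seq) for c in contigs)
    max_rlen = max((len(r.seq) for r in reads), default=0)
    if len(contigs) > 4095 or max_clen + max_rlen >= (1 << 20):
        # fall back to chunked mapping to keep the packed candidate keys valid
        mid = len(contigs) // 2
        left = map_reads(reads, contigs[:mid], params)
        right = map_reads(reads, contigs[mid:], params)
        out = []
        for a, b in zip(left, right):
            ka = (-(a.end - a.start) * a.identity, a.contig_id or "~", a.start)
            kb = (-(b.end - b.start) * b.identity, b.contig_id or "~", b.start)
            out.append(a if ka <= kb else b)
        return out
    order = sorted(range(len(contigs)), key=lambda i: contigs[i].id)
    arrs = [encode_dna(contigs[i].seq) for i in order]
    ids = [contigs[i].id for i in order]
    # concatenated contig k-mer index, sorted by code for vectorized lookup
    offs = np.cumsum([0] + [len(a) for a in arrs])
    words, positions = [], []
    for ci, arr in enumerate(arrs):
        codes, valid = kmer_codes(arr, _K)
        vi = np.flatnonzero(valid)
        words.append(codes[vi])
        positions.append(vi.astype(np.int64) + offs[ci])
    all_words = np.concatenate(words) if words else np.empty(0, np.uint64)
    all_pos = np.concatenate(positions) if positions else np.empty(0, np.int64)
    sorder = np.argsort(all_words, kind="stable")
    s_words, s_pos = all_words[sorder], all_pos[sorder]

    n_reads = len(reads)
    lens = np.array([len(r.seq) for r in reads])
    maxlen = int(lens.max()) if n_reads else 0
    fwd_mat = np.full((n_reads, maxlen), 4, dtype=np.uint8)
    rc_mat = np.full((n_reads, maxlen), 4, dtype=np.uint8)
    fwd_arrs, rc_arrs = [], []
    for i, r in enumerate(reads):
        a = encode_dna(r.seq)
        fwd_arrs.append(a)
        b = revcomp_codes(a)
        rc_arrs.append(b)
        fwd_mat[i, : len(a)] = a
        rc_mat[i, : len(b)] = b

    # probe k-mers at a handful of read offsets (error tolerance: one bad
    # base cannot hide the read from every probe)
    base_offs = np.array([0, 20, 40, 60])
    cand_keys: list[np.ndarray] = []
    kidx = np.arange(_K)
    pows = (4 ** np.arange(_K - 1, -1, -1, dtype=np.uint64))
    for strand, mat in ((0, fwd_mat), (1, rc_mat)):
        for j in range(len(base_offs) + 1):
            if j < len(base_offs):
                po = np.minimum(base_offs[j], np.maximum(lens - _K, 0))
            else:
                po = np.maximum(lens - _K, 0)
            win = mat[np.arange(n_reads)[:, None], po[:, None] + kidx[None, :]]
            ok = (win < 4).all(axis=1) & (lens >= _K)
            codes = (win.astype(np.uint64) * pows[None, :]).sum(axis=1)
            ridx = np.flatnonzero(ok)
            if len(ridx) == 0:
                continue
            qc = codes[ridx]
            lo = np.searchsorted(s_words, qc, side="left")
            hi = np.searchsorted(s_words, qc, side="right")
            counts = hi - lo
            tot = int(counts.sum())
            if tot == 0:
                continue
            rep = np.repeat(np.arange(len(ridx)), counts)
            starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
            flat = lo[rep] + (np.arange(tot) - starts[rep])
            gpos = s_pos[flat]
            ci_arr = np.searchsorted(offs, gpos, side="right") - 1
            p0 = (gpos - offs[ci_arr]) - po[ridx][rep]
            # pack (read, strand, contig, local p0) for dedup
            key = (
                (ridx[rep].astype(np.int64) << 33)
                | (np.int64(strand) << 32)
                | (ci_arr.astype(np.int64) << 20)
                | (p0 + maxlen).astype(np.int64)
            )
            cand_keys.append(key)

    ml = params.min_overlap_len
    mmf = params.max_mismatch_frac
    best: dict[int, tuple] = {}
    if cand_keys:
        uniq = np.unique(np.concatenate(cand_keys))
        u_r = (uniq >> 33).astype(np.int64)
        u_strand = ((uniq >> 32) & 1).astype(np.int64)
        u_ci = ((uniq >> 20) & 0xFFF).astype(np.int64)
        u_p0 = (uniq & ((1 << 20) - 1)).astype(np.int64) - maxlen
        for i in range(len(uniq)):
            ridx = int(u_r[i])
            strand = int(u_strand[i])
            ci = int(u_ci[i])
            n = int(lens[ridx])
            carr = arrs[ci]
            p0 = int(u_p0[i])
            lo_, hi_ = max(0, p0), min(len(carr), p0 + n)
            ov = hi_ - lo_
            if ov < ml:
                continue
            arrq = fwd_arrs[ridx] if strand == 0 else rc_arrs[ridx]
            mism = int(np.count_nonzero(carr[lo_:hi_] != arrq[lo_ - p0 : hi_ - p0]))
            if mism > int(mmf * ov):
                continue
            identity = 1.0 - mism / ov
            full = p0 >= 0 and p0 + n <= len(carr)
            cls = "Full" if full else "Partial"
            cand = (-ov * identity, ci, lo_, cls, identity, hi_, strand)
            cur = best.get(ridx)
            if cur is None or cand < cur:
                best[ridx] = cand
    out: list[MappingRecord] = []
    for i, r in enumerate(reads):
        b = best.get(i)
        if b is None:
            out.append(MappingRecord(r.id, None, 0, 0, ".", "Unmapped", 0.0))
        else:
            _, ci, lo_, cls, identity, hi_, strand = b
            out.append(
                MappingRecord(
                    r.id, ids[ci], lo_, hi_, "+" if strand == 0 else "-", cls, identity
                )
            )
    return out


# ---------------------------------------------------------------------------
# overlap enumeration
# ---------------------------------------------------------------------------

def detect_overlaps(
    reads: list[ReadRecord], params: AsmParams | None = None
) -> set[tuple[str, str, int, int]]:
    """Qualifying suffix/prefix overlaps found through the k-mer prefilter.

    Same output shape as :func:`find_overlaps` (id_a, id_b, longest
    qualifying overlap, orientation); on error-free reads the two agree
    exactly, which is the audit the assembler's prefilter rests on."""
    params = params or AsmParams()
    ml, mmf = params.min_overlap_len, params.max_mismatch_frac
    rs = _ReadSet.from_reads(reads)
    index = _OverlapIndex(rs, ml)
    out: set[tuple[str, str, int, int]] = set()
    for ia in range(len(rs)):
        a = rs.fwd[ia]
        la = len(a)
        codes, valid = kmer_codes(a, _K)
        if len(codes) == 0:
            continue
        lo = np.searchsorted(index.codes, codes, side="left")
        hi = np.searchsorted(index.codes, codes, side="right")
        best: dict[tuple[int, int], int] = {}
        for j in np.flatnonzero(valid & (hi > lo)):
            for t in range(lo[j], hi[j]):
                packed = int(index.packed[t])
                ib = packed >> 2
                if ib == ia:
                    continue
                orient = (packed >> 1) & 1
                off = (0, ml)[packed & 1]
                p0 = int(j) - off
                lb = int(rs.lens[ib])
                ov = la - p0
                if p0 < 0 or ov < ml or ov > lb:
                    continue
                b = rs.oriented(ib, orient)
                if int(np.count_nonzero(a[p0:] != b[:ov])) <= int(mmf * ov):
                    key = (ib, orient)
                    if ov > best.get(key, 0):
                        best[key] = ov
        for (ib, orient), ov in best.items():
            out.add((rs.ids[ia], rs.ids[ib], ov, orient))
    return out


def find_overlaps(
    reads: list[ReadRecord], params: AsmParams | None = None
) -> set[tuple[str, str, int, int]]:
    """All-pairs qualifying suffix/prefix overlaps (id_a, id_b, length,
    orientation) by direct comparison.  Quadratic; intended for small inputs
    and as the ground truth the k-mer prefilter is audited against."""
    params = params or AsmParams()
    ml, mmf = params.min_overlap_len, params.max_mismatch_frac
    arrs = [(r.id, encode_dna(r.seq)) for r in reads]
    out: set[tuple[str, str, int, int]] = set()
    for ia, (ida, a) in enumerate(arrs):
        for ib, (idb, b) in enumerate(arrs):
            if ia == ib:
                continue
            for orient in (0, 1):
                bb = b if orient == 0 else revcomp_codes(b)
                top = min(len(a), len(bb))
                for ov in range(top, ml - 1, -1):
                    m = int(np.count_nonzero(a[len(a) - ov :] != bb[:ov]))
                    if m <= int(mmf * ov):
                        out.add((ida, idb, ov, orient))
                        break
    return out
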