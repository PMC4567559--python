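"""Truth-based evaluation of selections and assemblies.

Origin assignment uses the >99.0%-identity criterion: a contig is credited
to the target genome when an alignment covering at least 95% of the contig
is more than 99.0% identical to it (both strands; circular rotations of the
target are honored by aligning against a doubled target).  Selection quality
is reported as TP/FN/FP in total nucleotides; assembly quality as genome
fraction and NGA50 over reference-aligned blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._encode import encode_dna, kmer_codes, revcomp
from .microasm import Assembly, AsmParams, Contig, map_reads
from .synthdata import ReadPair

__all__ = [
    "EvalReport",
    "assign_origin",
    "confusion_lengths",
    "aligned_blocks",
    "genome_fraction",
    "nga50",
    "estimate_purity",
]

IDENTITY_THRESHOLD = 0.99  # ">99.0% similar" criterion (strict)
COVERAGE_CLAUSE = 0.95  # fraction of the contig the alignment must cover


@dataclass
class EvalReport:
    tp_nt: int
    fn_nt: int
    fp_nt: int
    genome_fraction: float  # percent
    nga50: int
    nga50_defined: bool
    purity: float | None  # percent, library-level (if reads supplied)
    assignments: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in vars(self).items() if k != "assignments"}
        return pd.DataFrame([d])


def _identity_vs(contig: str, genome: str, circular: bool) -> float:
    """Best semi-global identity of the contig inside a truth genome."""
    if not contig or not genome:
        return 0.0
    subject = genome + genome[: len(contig)] if circular else genome
    best = 0.0
    for q in (contig, revcomp(contig)):
        if len(q) > len(subject):
            # contig longer than genome (e.g. circular wrap): align genome in
            # contig instead so the infix semantics still hold
            r = edlib.align(subject, q, mode="HW", task="distance")
            span = len(subject)
        else:
            r = edlib.align(q, subject, mode="HW", task="distance")
            span = len(q)
        d = r["editDistance"]
        if d >= 0:
            cov = span / len(contig) if span < len(contig) else 1.0
            if cov >= COVERAGE_CLAUSE:
                best = max(best, 1.0 - d / max(span, 1))
    return best


def assign_origin(
    contig: str | Contig,
    truth_genomes: dict[str, str],
    target_key: str = "target",
    circular_target: bool = True,
) -> str:
    """Label a contig ``target``, ``other`` or ``unassigned``.

    ``truth_genomes`` maps labels to sequences and must contain
    ``target_key``.
    """
    seq = contig.seq if isinstance(contig, Contig) else contig
    if target_key not in truth_genomes:
        raise ValueError(f"truth genomes lack {target_key!r}")
    if (
        _identity_vs(seq, truth_genomes[target_key], circular_target)
        > IDENTITY_THRESHOLD
    ):
        return "target"
    for label, genome in sorted(truth_genomes.items()):
        if label == target_key or genome is None:
            continue
        if _identity_vs(seq, genome, False) > IDENTITY_THRESHOLD:
            return "other"
    return "unassigned"


def assign_origins(
    contigs, truth_genomes: dict[str, str], circular_target: bool = True
) -> dict[str, str]:
    if isinstance(contigs, Assembly):
        contigs = contigs.contigs
    return {
        c.id: assign_origin(c, truth_genomes, circular_target=circular_target)
        for c in contigs
    }


def confusion_lengths(
    selection, assignments: dict[str, str], contig_lens: dict[str, int]
) -> tuple[int, int, int]:
    """(tp_nt, fn_nt, fp_nt) of a selection outcome under truth assignments.

    Kept non-target contigs (including unassigned ones) count as FP — the
    conservative reading, matching the treatment of contaminant contigs.
    """
    tp = fn = fp = 0
    kept = set(selection.kept)
    for cid in selection.all_ids():
        if cid not in assignments:
            raise KeyError(f"contig {cid} missing from truth assignments")
        length = contig_lens[cid]
        is_target = assignments[cid] == "target"
        if cid in kept:
            if is_target:
                tp += length
            else:
                fp += length
        elif is_target:
            fn += length
    return tp, fn, fp


# ---------------------------------------------------------------------------
# reference-aligned blocks, genome fraction, NGA50
# ---------------------------------------------------------------------------

_ANCHOR_K = 31
_BLOCK_SPLIT_GAP = 10_000  # nt; anchors further apart break a contig block


@dataclass(frozen=True)
class AlignedBlock:
    contig_id: str
    t_start: int  # target coordinates (may exceed target length on a circle
    t_end: int  # before reduction; length == t_end - t_start)

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


def aligned_blocks(
    contigs, target: str, circular: bool = True
) -> list[AlignedBlock]:
    """Project contigs onto the target as maximal collinear anchor runs.

    Contigs are anchored by exact 31-mers; runs on a consistent diagonal
    (split at misassembly/unaligned gaps) become blocks in target
    coordinates.  Substitution-level divergence only shortens anchors'
    density, not the run.
    """
    if isinstance(contigs, Assembly):
        contigs = contigs.contigs
    t_codes = encode_dna(target + target[: min(len(target), 1000)] if circular else target)
    tk, tv = kmer_codes(t_codes, _ANCHOR_K)
    order = np.argsort(tk, kind="stable")
    tk_sorted = tk[order]
    blocks: list[AlignedBlock] = []
    L = len(target)
    for c in contigs:
        best: list[AlignedBlock] = []
        for strand in ("+", "-"):
            seq = c.seq if strand == "+" else revcomp(c.seq)
            qc = encode_dna(seq)
            qk, qv = kmer_codes(qc, _ANCHOR_K)
            vi = np.flatnonzero(qv)
            if len(vi) == 0:
                continue
            lo = np.searchsorted(tk_sorted, qk[vi], side="left")
            hi = np.searchsorted(tk_sorted, qk[vi], side="right")
            counts = hi - lo
            hitq = np.repeat(vi, counts)
            starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
            total = int(counts.sum())
            if total == 0:
                continue
            flat = lo[np.repeat(np.arange(len(vi)), counts)] + (
                np.arange(total) - starts[np.repeat(np.arange(len(vi)), counts)]
            )
            hitt = order[flat]
            diag = hitt.astype(np.int64) - hitq.astype(np.int64)
            o2 = np.lexsort((hitq, diag))
            hitq, hitt, diag = hitq[o2], hitt[o2], diag[o2]
            runs: list[AlignedBlock] = []
            run_start = 0
            for i in range(1, total + 1):
                if (
                    i == total
                    or abs(diag[i] - diag[i - 1]) > 50
                    or hitq[i] - hitq[i - 1] > _BLOCK_SPLIT_GAP
                ):
                    t0 = int(hitt[run_start])
                    t1 = int(hitt[i - 1]) + _ANCHOR_K
                    if t1 - t0 >= _ANCHOR_K:
                        runs.append(AlignedBlock(c.id, t0, t1))
                    run_start = i
            if sum(b.length for b in runs) > sum(b.length for b in best):
                best = runs
        # clip block lengths to the target size (a circular wrap cannot
        # legitimately cover more than the whole chromosome)
        for b in best:
            if b.length > L:
                b = AlignedBlock(b.contig_id, b.t_start, b.t_start + L)
            blocks.append(b)
    return blocks


def _coverage(blocks: list[AlignedBlock], target_len: int) -> np.ndarray:
    cov = np.zeros(target_len, dtype=bool)
    for b in blocks:
        lo, hi = b.t_start, b.t_end
        if hi <= target_len:
            cov[lo:hi] = True
        else:  # wraps the origin
            cov[lo:target_len] = True
            cov[: min(hi - target_len, target_len)] = True
    return cov


def genome_fraction(blocks_or_contigs, target: str | int, **kw) -> float:
    """Percent of target positions covered by at least one aligned block.

    Accepts either precomputed blocks with an integer target length, or
    contigs with the target sequence (blocks are computed first).
    """
    blocks, target_len = _resolve_blocks(blocks_or_contigs, target, **kw)
    if not blocks:
        return 0.0
    return 100.0 * float(_coverage(blocks, target_len).sum()) / target_len


def nga50(blocks_or_contigs, target: str | int, **kw) -> tuple[int, bool]:
    """(NGA50, defined?) — the largest L such that aligned blocks of length
    >= L together span >= 50% of the target.  Undefined (0, False) when the
    blocks cover less than half the target."""
    blocks, target_len = _resolve_blocks(blocks_or_contigs, target, **kw)
    if not blocks:
        return 0, False
    if float(_coverage(blocks, target_len).sum()) < 0.5 * target_len:
        return 0, False
    lens = sorted((min(b.length, target_len) for b in blocks), reverse=True)
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= 0.5 * target_len:
            return ln, True
    return 0, False


def _resolve_blocks(blocks_or_contigs, target, **kw):
    if isinstance(target, int):
        return list(blocks_or_contigs), target
    blocks = aligned_blocks(blocks_or_contigs, target, **kw)
    return blocks, len(target)


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------

def estimate_purity(
    pairs: list[ReadPair],
    target: str,
    params: AsmParams | None = None,
    circular: bool = True,
) -> float:
    """Percent of reads with a Full/Partial mapping onto the target genome."""
    if not pairs:
        raise ValueError("empty read set")
    reads = [r for p in pairs for r in (p.fwd, p.rev)]
    ext = target + target[:300] if circular else target
    contig = Contig(id="target", seq=ext, mean_depth=0.0, members=[])
    mapping = map_reads(reads, [contig], params or AsmParams())
    mapped = sum(1 for m in mapping if m.mapped)
    return 100.0 * mapped / len(mapping)


def evaluate(
    assembly,
    truth_genomes: dict[str, str],
    selection=None,
    pairs: list[ReadPair] | None = None,
) -> EvalReport:
    """Full report for an assembly (and optionally a selection) vs truth."""
    target = truth_genomes["target"]
    assignments = assign_origins(assembly, truth_genomes)
    contigs = assembly.contigs if isinstance(assembly, Assembly) else assembly
    lens = {c.id: len(c.seq) for c in contigs}
    if selection is not None:
        tp, fn, fp = confusion_lengths(selection, assignments, lens)
    else:
        tp = sum(lens[c] for c, a in assignments.items() if a == "target")
        fn = 0
        fp = sum(lens[c] for c, a in assignments.items() if a != "target")
    target_contigs = [c for c in contigs if assignments[c.id] == "target"]
    gf = genome_fraction(target_contigs, target)
    n50, defined = nga50(target_contigs, target)
    purity = estimate_purity(pairs, target) if pairs else None
    return EvalReport(
        tp_nt=tp,
        fn_nt=fn,
        fp_nt=fp,
        genome_fraction=gf,
        nga50=n50,
        nga50_defined=defined,
        purity=purity,
        assignments=assignments,
    )
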