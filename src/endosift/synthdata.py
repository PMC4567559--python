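"""Truth-labeled synthetic genomes and mixed paired-end libraries.

The generator emulates the sequencing situation of an obligate intracellular
symbiont living in host tissue: a small, AT-rich, gene-dense circular target
chromosome; a panel of reference genomes at graded amino-acid divergence from
the target (sharing the gene complement but with randomized synonymous codons
and intergenic DNA); host nuclear DNA carrying an rRNA gene; an AT-rich
mitochondrial genome sharing one degenerate gene family with the target; and
an optional trace contaminant with partial similarity to a small-subunit
rRNA present in the reference panel.

Libraries are paired-end, ~100-nt reads, ~230-nt inserts, with a controlled
fraction ("purity") of target-derived read pairs and substitution-only
sequencing errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._encode import decode_dna, encode_dna, kmer_codes, revcomp

__all__ = [
    "SimScenario",
    "GenomeSet",
    "ReadRecord",
    "ReadPair",
    "InvalidScenarioError",
    "make_genome_set",
    "simulate_library",
    "write_fastq",
    "write_truth",
    "read_fastq_pairs",
    "write_fasta",
    "read_fasta",
]


class InvalidScenarioError(ValueError):
    """Scenario parameters cannot produce a consistent genome set / library."""


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated sequencing experiment.

    ``purity`` is the fraction of read *pairs* drawn from the target
    chromosome; ``target_depth`` the requested fold-coverage of the target.
    Non-target mass is split host:mito:rRNA:contaminant by
    ``nontarget_weights`` (the real composition of such libraries is not
    knowable in general, so this is an explicit knob).
    """

    seed: int = 0
    target_len: int = 50_000
    target_gc: float = 0.26
    host_len: int = 250_000
    mito_len: int = 15_000
    rrna_len: int = 1_800
    contaminant_16s_len: int = 1_550  # 0 disables the contaminant
    ref_aa_divergences: tuple[float, ...] = (0.02, 0.17, 0.21, 0.26)
    purity: float = 0.285
    target_depth: float = 20.0
    read_len: int = 100
    insert_mean: float = 230.0
    insert_sd: float = 25.0
    per_base_error: float = 0.002
    indel_rate: float = 0.0
    nontarget_weights: tuple[float, float, float, float] = (0.90, 0.07, 0.02, 0.01)
    qc_fail_frac: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise InvalidScenarioError(f"purity must be in (0, 1], got {self.purity}")
        if self.target_depth <= 0:
            raise InvalidScenarioError("target_depth must be positive")
        if self.insert_mean < self.read_len:
            raise InvalidScenarioError("insert_mean must be at least read_len")
        for name in ("target_len", "host_len", "mito_len", "rrna_len", "read_len"):
            if getattr(self, name) <= 0:
                raise InvalidScenarioError(f"{name} must be positive")
        if any(not (0.0 <= d < 1.0) for d in self.ref_aa_divergences):
            raise InvalidScenarioError("reference divergences must lie in [0, 1)")
        if self.target_len < 5 * (_MIN_GENE_CODONS * 3 + 3):
            raise InvalidScenarioError(
                "target_len too small to host at least 5 ORFs"
            )
        if self.contaminant_16s_len < 0:
            raise InvalidScenarioError("contaminant_16s_len must be >= 0")
        object.__setattr__(
            self, "ref_aa_divergences", tuple(self.ref_aa_divergences)
        )
        object.__setattr__(
            self, "nontarget_weights", tuple(self.nontarget_weights)
        )


@dataclass(frozen=True)
class GenomeSet:
    """The truth genomes of one scenario.

    ``gene_table`` holds 0-based half-open ``(start, end, strand, peptide)``
    records on the (circular) target; minus-strand genes are stored with
    ``start < end`` and a strand flag.
    """

    target: str
    refs: dict[str, str]
    host: str
    mito: str
    host_rrna: str
    contaminant: str | None
    gene_table: list[tuple[int, int, str, str]]

    @property
    def target_circular(self) -> bool:
        return True


@dataclass(slots=True)
class ReadRecord:
    id: str
    mate: int
    seq: str
    qual: np.ndarray  # per-base Phred integers
    truth: str | None = None

    def mean_quality(self) -> float:
        return float(self.qual.mean()) if len(self.qual) else 0.0


@dataclass(slots=True)
class ReadPair:
    pair_id: str
    fwd: ReadRecord
    rev: ReadRecord


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_MIN_GENE_CODONS = 120
_MAX_GENE_CODONS = 420
_MIN_GAP = 30
_MAX_GAP = 120
_SSU_CORE_LEN = 1_500
_CONTAMINANT_NT_DIV = 0.08
_HOST_RRNA_NT_DIV = 0.30
_MITO_GENE_AA_DIV = 0.40

_CODON_TABLE = standard_dna_table
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.forward_table.items():
    if set(_codon) <= set("ACGT"):
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()

_AA20 = sorted(_AA_TO_CODONS)

# Amino-acid sampling weights biased toward residues with AT-rich codons,
# mimicking the proteome composition of AT-rich reduced genomes.
_AA_WEIGHTS = {
    "K": 9.0, "I": 9.0, "N": 7.0, "F": 6.0, "L": 9.0, "Y": 5.0, "E": 6.0,
    "S": 6.0, "T": 4.0, "D": 4.0, "V": 4.0, "Q": 2.5, "R": 2.5, "G": 3.0,
    "A": 3.0, "P": 2.0, "H": 1.5, "M": 2.0, "C": 1.0, "W": 0.8,
}

_B62 = substitution_matrices.load("BLOSUM62")
# similarity-biased replacement distributions: P(b | a) ~ exp(B62[a,b]/2), b != a
_SUBST_PROBS: dict[str, np.ndarray] = {}
for _a in _AA20:
    w = np.array(
        [0.0 if _b == _a else float(np.exp(_B62[_a, _b] / 2.0)) for _b in _AA20]
    )
    _SUBST_PROBS[_a] = w / w.sum()


class _GCSteer:
    """Greedy synonymous-codon chooser steering cumulative GC to a target."""

    def __init__(self, gc_target: float) -> None:
        self.gc_target = gc_target
        self.gc = 0
        self.n = 0

    def feed(self, seq: str) -> None:
        self.gc += sum(1 for b in seq if b in "GC")
        self.n += len(seq)

    def pick(self, aa: str, rng: np.random.Generator) -> str:
        codons = _AA_TO_CODONS[aa]
        best, best_err = [], None
        for c in codons:
            g = sum(1 for b in c if b in "GC")
            err = abs((self.gc + g) / (self.n + 3) - self.gc_target)
            if best_err is None or err < best_err - 1e-12:
                best, best_err = [c], err
            elif abs(err - best_err) <= 1e-12:
                best.append(c)
        codon = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
        self.feed(codon)
        return codon


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode_dna(rng.choice(4, size=n, p=p).astype(np.uint8))


def _random_peptide(rng: np.random.Generator, n_codons: int) -> str:
    aas = sorted(_AA_WEIGHTS)
    w = np.array([_AA_WEIGHTS[a] for a in aas])
    w = w / w.sum()
    body = "".join(np.array(aas)[rng.choice(len(aas), size=n_codons - 1, p=w)])
    return "M" + body


def _backtranslate_steered(
    peptide: str, steer: _GCSteer, rng: np.random.Generator
) -> str:
    return "".join(steer.pick(aa, rng) for aa in peptide)


def _backtranslate_uniform(peptide: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
        for aa in peptide
    )


def _mutate_peptide(
    peptide: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return peptide
    out = list(peptide)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        a = out[i]
        if a not in _SUBST_PROBS:
            continue
        out[i] = _AA20[int(rng.choice(len(_AA20), p=_SUBST_PROBS[a]))]
    return "".join(out)


def _mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = encode_dna(seq).copy()
    mask = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=len(codes)).astype(np.uint8)
    codes[mask] = (codes[mask] + shift[mask]) % 4
    return decode_dna(codes)


def _build_target(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int, str, str]]]:
    steer = _GCSteer(scenario.target_gc)
    parts: list[str] = []
    genes: list[tuple[int, int, str, str]] = []
    pos = 0
    stop = "TAA"  # AT-rich stop, consistent with the genome's base bias
    while True:
        gap = int(rng.integers(_MIN_GAP, _MAX_GAP + 1))
        n_codons = int(rng.integers(_MIN_GENE_CODONS, _MAX_GENE_CODONS + 1))
        gene_nt_len = 3 * n_codons + 3
        if pos + gap + gene_nt_len > scenario.target_len:
            break
        inter = _random_seq(rng, gap, scenario.target_gc)
        steer.feed(inter)
        parts.append(inter)
        pos += gap
        peptide = _random_peptide(rng, n_codons)
        cds = _backtranslate_steered(peptide, steer, rng) + stop
        steer.feed(stop)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(cds if strand == "+" else revcomp(cds))
        genes.append((pos, pos + gene_nt_len, strand, peptide))
        pos += gene_nt_len
    tail = scenario.target_len - pos
    if tail > 0:
        parts.append(_random_seq(rng, tail, scenario.target_gc))
    target = "".join(parts)
    if len(genes) < 5:
        raise InvalidScenarioError("target too short to host at least 5 ORFs")
    return target, genes


def _build_ref(
    target_len: int,
    genes: list[tuple[int, int, str, str]],
    divergence: float,
    ssu_core: str | None,
    rng: np.random.Generator,
) -> str:
    """A reference genome sharing the target's gene complement at a given
    amino-acid divergence, with randomized synonymous codons and intergenic
    DNA; carries its own copy of the SSU-rRNA-like core."""
    out: list[str] = []
    pos = 0
    for start, end, strand, peptide in genes:
        if start > pos:
            out.append(_random_seq(rng, start - pos, 0.40))
        mutated = _mutate_peptide(peptide, divergence, rng)
        cds = _backtranslate_uniform(mutated, rng) + "TAA"
        out.append(cds if strand == "+" else revcomp(cds))
        pos = end
    if target_len > pos:
        out.append(_random_seq(rng, target_len - pos, 0.40))
    if ssu_core is not None:
        nt_div = max(0.05, divergence / 2.0)
        out.append(_random_seq(rng, 30, 0.40))
        out.append(_mutate_nt(ssu_core, nt_div, rng))
    return "".join(out)


def _audit_no_cross_identity(
    target: str, other: str, label: str, k: int = 21
) -> None:
    """Construction check: no >=60-nt window of >=95% identity between the
    target and a non-target genome.  Shared exact k-mers are used as anchors;
    any anchor is extended along its diagonal and the best 60-nt window
    identity is measured (a qualifying window at <5% divergence necessarily
    contains a clean >=21-nt run)."""
    t_codes = encode_dna(target)
    o_codes = encode_dna(other)
    tk, tv = kmer_codes(t_codes, k)
    ok_, ov = kmer_codes(o_codes, k)
    t_sorted = np.sort(tk[tv])
    o_valid = np.flatnonzero(ov)
    idx = np.searchsorted(t_sorted, ok_[o_valid])
    idx = np.clip(idx, 0, len(t_sorted) - 1)
    hits = o_valid[t_sorted[idx] == ok_[o_valid]]
    for opos in hits[:200]:
        code = ok_[opos]
        tpos_all = np.flatnonzero(tk == code)
        for tpos in tpos_all:
            lo = 60 - k
            a0, b0 = int(tpos), int(opos)
            s = max(0, min(a0, b0, lo))
            a, b = a0 - s, b0 - s
            n = min(len(t_codes) - a, len(o_codes) - b, 2 * 60)
            if n < 60:
                continue
            eq = (t_codes[a : a + n] == o_codes[b : b + n]).astype(np.int32)
            cs = np.concatenate([[0], np.cumsum(eq)])
            win = cs[60:] - cs[:-60]
            if win.size and win.max() >= 57:  # 95% of 60
                raise AssertionError(
                    f"construction check failed: target shares a >=95%-identity "
                    f"60-nt window with {label}"
                )


def make_genome_set(scenario: SimScenario) -> GenomeSet:
    """Deterministically forge the truth genomes for a scenario."""
    rng = np.random.default_rng(scenario.seed)
    target, genes = _build_target(scenario, rng)

    ssu_core = _random_seq(rng, min(_SSU_CORE_LEN, scenario.rrna_len), 0.45)

    refs: dict[str, str] = {}
    for d in scenario.ref_aa_divergences:
        refs[f"{d:g}"] = _build_ref(len(target), genes, d, ssu_core, rng)

    # host rRNA gene: a heavily diverged SSU-like core plus random tail
    rr_core = _mutate_nt(ssu_core, _HOST_RRNA_NT_DIV, rng)
    tail = scenario.rrna_len - len(rr_core)
    host_rrna = rr_core + (_random_seq(rng, tail, 0.50) if tail > 0 else "")
    host_rrna = host_rrna[: scenario.rrna_len]

    # host nuclear DNA with one embedded rRNA copy
    host_bg = _random_seq(rng, scenario.host_len, 0.40)
    ins = int(rng.integers(0, max(1, scenario.host_len - scenario.rrna_len)))
    host = (host_bg[:ins] + host_rrna + host_bg[ins + len(host_rrna):])[
        : scenario.host_len
    ]

    # mitochondrion: AT-rich, shares one degenerate gene family with the target
    mito_bg = _random_seq(rng, scenario.mito_len, 0.20)
    longest = max(genes, key=lambda g: len(g[3]))
    deg_pep = _mutate_peptide(longest[3], _MITO_GENE_AA_DIV, rng)
    deg_cds = _backtranslate_uniform(deg_pep, rng) + "TAA"
    mpos = int(rng.integers(0, max(1, scenario.mito_len - len(deg_cds))))
    mito = (mito_bg[:mpos] + deg_cds + mito_bg[mpos + len(deg_cds):])[
        : scenario.mito_len
    ]

    contaminant: str | None = None
    if scenario.contaminant_16s_len > 0:
        core = _mutate_nt(ssu_core, _CONTAMINANT_NT_DIV, rng)
        extra = scenario.contaminant_16s_len - len(core)
        contaminant = (core + (_random_seq(rng, extra, 0.45) if extra > 0 else ""))[
            : scenario.contaminant_16s_len
        ]

    _audit_no_cross_identity(target, host, "host")
    _audit_no_cross_identity(target, mito, "mito")
    if contaminant is not None:
        _audit_no_cross_identity(target, contaminant, "contaminant")

    return GenomeSet(
        target=target,
        refs=refs,
        host=host,
        mito=mito,
        host_rrna=host_rrna,
        contaminant=contaminant,
        gene_table=genes,
    )


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_library(
    gs: GenomeSet, scenario: SimScenario
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate the mixed paired-end library of a scenario.

    Returns the shuffled list of read pairs and the truth sidecar table
    (``pair_id``, ``truth``).  Number of target pairs is
    ``round(depth * target_len / (2 * read_len))``; total pairs is
    ``round(target_pairs / purity)``.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    rl = scenario.read_len
    n_target = int(round(scenario.target_depth * scenario.target_len / (2 * rl)))
    if n_target < 1:
        raise InvalidScenarioError("target_depth too low: no target pairs")
    n_total = int(round(n_target / scenario.purity))

    sources: list[tuple[str, str, bool]] = [("target", gs.target, True)]
    weights = []
    labels = ["host", "mito", "rrna", "contaminant"]
    seqs = [gs.host, gs.mito, gs.host_rrna, gs.contaminant]
    for lab, seq, w in zip(labels, seqs, scenario.nontarget_weights):
        if seq is not None and w > 0:
            sources.append((lab, seq, False))
            weights.append(w)
    n_rest = n_total - n_target
    counts = [n_target]
    if n_rest > 0 and weights:
        counts.extend(_largest_remainder(n_rest, np.array(weights, float)).tolist())
    else:
        counts.extend([0] * len(weights))

    frag_seqs: list[np.ndarray] = []
    truths: list[str] = []
    fwd_rows, rev_rows = [], []
    for (label, seq, circular), n in zip(sources, counts):
        if n == 0:
            continue
        codes = encode_dna(seq)
        L = len(codes)
        insert = np.rint(
            rng.normal(scenario.insert_mean, scenario.insert_sd, size=n)
        ).astype(int)
        insert = np.clip(insert, rl, int(3 * scenario.insert_mean))
        if circular:
            ext = np.concatenate([codes, codes[: int(insert.max())]])
            start = rng.integers(0, L, size=n)
        else:
            insert = np.minimum(insert, L)
            ext = codes
            start = (rng.random(n) * (L - insert + 1)).astype(int)
        idx = np.arange(rl)
        fwd = ext[start[:, None] + idx]
        rev_src = ext[(start + insert - rl)[:, None] + idx]
        rev = (3 - rev_src)[:, ::-1]  # reverse complement (no N in genomes)
        fwd_rows.append(fwd.astype(np.uint8))
        rev_rows.append(rev.astype(np.uint8))
        truths.extend([label] * n)

    fwd_mat = np.concatenate(fwd_rows)
    rev_mat = np.concatenate(rev_rows)
    n = len(truths)

    # substitution errors
    if scenario.per_base_error > 0:
        for mat in (fwd_mat, rev_mat):
            mask = rng.random(mat.shape) < scenario.per_base_error
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[mask] = (mat[mask] + shift[mask]) % 4

    # qualities: mostly high, with a small tail of QC-failing reads
    def _make_quals(shape) -> np.ndarray:
        q = rng.integers(33, 41, size=shape).astype(np.int16)
        if scenario.qc_fail_frac > 0:
            fail = rng.random(shape[0]) < scenario.qc_fail_frac
            kind = rng.random(shape[0]) < 0.5
            tail_len = rng.integers(25, 61, size=shape[0])
            for i in np.flatnonzero(fail):
                if kind[i]:  # low-quality 3' tail -> trimmed, then too short
                    t = int(tail_len[i])
                    q[i, shape[1] - t :] = rng.integers(2, 25, size=t)
                else:  # depressed overall mean
                    q[i] = rng.integers(18, 29, size=shape[1])
        return q

    fwd_q = _make_quals(fwd_mat.shape)
    rev_q = _make_quals(rev_mat.shape)

    order = rng.permutation(n)
    from ._encode import _DNA_CHARS  # local import to keep hot path simple

    fwd_bytes = _DNA_CHARS[fwd_mat[order]].tobytes()
    rev_bytes = _DNA_CHARS[rev_mat[order]].tobytes()
    fwd_q = fwd_q[order]
    rev_q = rev_q[order]
    truth_arr = np.array(truths)[order]

    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(n):
        pid = f"p{i:07d}"
        seq_f = fwd_bytes[i * rl : (i + 1) * rl].decode("ascii")
        seq_r = rev_bytes[i * rl : (i + 1) * rl].decode("ascii")
        t = str(truth_arr[i])
        pairs.append(
            ReadPair(
                pair_id=pid,
                fwd=ReadRecord(f"{pid}/1", 1, seq_f, fwd_q[i], t),
                rev=ReadRecord(f"{pid}/2", 2, seq_r, rev_q[i], t),
            )
        )
        truth_rows.append((pid, t))
    truth_df = pd.DataFrame(truth_rows, columns=["pair_id", "truth"])
    return pairs, truth_df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _phred_str(qual: np.ndarray) -> str:
    return (qual.astype(np.uint8) + 33).tobytes().decode("ascii")


def write_fastq(pairs: list[ReadPair], r1_path, r2_path) -> None:
    """Write mates to two 4-line-record FASTQ files (Phred+33)."""
    if not pairs:
        raise ValueError("no read pairs to write")
    try:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for p in pairs:
                f1.write(f"@{p.fwd.id}\n{p.fwd.seq}\n+\n{_phred_str(p.fwd.qual)}\n")
                f2.write(f"@{p.rev.id}\n{p.rev.seq}\n+\n{_phred_str(p.rev.qual)}\n")
    except OSError as exc:
        raise OSError(f"failed writing FASTQ to {r1_path} / {r2_path}: {exc}") from exc


def write_truth(pairs: list[ReadPair], path) -> None:
    df = pd.DataFrame(
        [(p.pair_id, p.fwd.truth) for p in pairs], columns=["pair_id", "truth"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Read two mate FASTQ files back into ReadPair objects (truth unknown)."""
    pairs = []
    with open(r1_path) as f1, open(r2_path) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            pid = id1.split("/")[0].split()[0]
            qual1 = np.frombuffer(q1.encode(), dtype=np.uint8).astype(np.int16) - 33
            qual2 = np.frombuffer(q2.encode(), dtype=np.uint8).astype(np.int16) - 33
            pairs.append(
                ReadPair(
                    pair_id=pid,
                    fwd=ReadRecord(id1.split()[0], 1, s1, qual1),
                    rev=ReadRecord(id2.split()[0], 2, s2, qual2),
                )
            )
    return pairs


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_genome_set(gs: GenomeSet, outdir) -> None:
    """Write all truth genomes of a set as FASTA plus the gene table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([("target", gs.target)], outdir / "target.fa")
    for label, seq in gs.refs.items():
        write_fasta([(f"ref_d{label}", seq)], outdir / f"ref_d{label}.fa")
    write_fasta([("host", gs.host)], outdir / "host.fa")
    write_fasta([("mito", gs.mito)], outdir / "mito.fa")
    write_fasta([("host_rrna", gs.host_rrna)], outdir / "host_rrna.fa")
    if gs.contaminant is not None:
        write_fasta([("contaminant", gs.contaminant)], outdir / "contaminant.fa")
    pd.DataFrame(
        gs.gene_table, columns=["start", "end", "strand", "peptide"]
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)


def realized_purity(truth_df: pd.DataFrame) -> float:
    return float((truth_df["truth"] == "target").mean())
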