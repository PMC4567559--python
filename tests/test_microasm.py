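"""The greedy OLC assembler and single-end mapper: exact reconstruction,
branching at repeats, overlap-set audits and Full/Partial semantics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endosift._encode import revcomp
from endosift.microasm import (
    AsmParams,
    Contig,
    assemble,
    detect_overlaps,
    find_overlaps,
    map_reads,
)
from endosift.synthdata import ReadRecord

from conftest import random_dna, tiling_pairs


def reads_from(source: str, starts, rl=100, prefix="r") -> list[ReadRecord]:
    return [
        ReadRecord(f"{prefix}{i:04d}", 1, source[s : s + rl], np.full(rl, 38))
        for i, s in enumerate(starts)
    ]


class TestAssemble:
    def test_tiling_pairs_reconstruct_source_exactly(self):
        rng = np.random.default_rng(7)
        src = random_dna(rng, 2000)
        asm = assemble(tiling_pairs(src, depth=30), AsmParams(min_contig_len=100))
        assert asm.n_contigs == 1
        assert asm.contigs[0].seq in (src, revcomp(src))

    def test_single_read_passes_through(self):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 100)
        asm = assemble(
            [ReadRecord("r1", 1, seq, np.full(100, 38))],
            AsmParams(min_contig_len=100),
        )
        assert asm.n_contigs == 1
        assert asm.contigs[0].seq in (seq, revcomp(seq))

    def test_empty_input(self):
        assert assemble([], AsmParams()).n_contigs == 0

    def test_exact_repeat_splits_assembly(self):
        rng = np.random.default_rng(9)
        rep = random_dna(rng, 300)
        src = (
            random_dna(rng, 800) + rep + random_dna(rng, 900) + rep + random_dna(rng, 700)
        )
        asm = assemble(tiling_pairs(src, depth=30), AsmParams(min_contig_len=100))
        # a 300-nt repeat cannot be bridged by 100-nt reads nor by 230-nt
        # inserts: the assembly stays split at the branch
        assert asm.n_contigs >= 2
        for c in asm.contigs:
            assert c.seq not in (src, revcomp(src)) or len(c.seq) < len(src)

    def test_stats_consistent(self):
        rng = np.random.default_rng(10)
        src = random_dna(rng, 1500)
        asm = assemble(tiling_pairs(src, depth=20), AsmParams(min_contig_len=100))
        assert asm.total_len == sum(len(c.seq) for c in asm.contigs)
        assert asm.max_len == max(len(c.seq) for c in asm.contigs)

    def test_members_support_their_contig(self):
        rng = np.random.default_rng(11)
        src = random_dna(rng, 1200)
        params = AsmParams(min_contig_len=100)
        asm = assemble(tiling_pairs(src, depth=25), params)
        contig = asm.contigs[0]
        by_id = {
            r.id: r
            for p in tiling_pairs(src, depth=25)
            for r in (p.fwd, p.rev)
        }
        mmf = params.max_mismatch_frac
        for read_id, offset, strand in contig.members[:50]:
            read = by_id[read_id]
            seq = read.seq if strand == "+" else revcomp(read.seq)
            lo, hi = max(0, offset), min(len(contig.seq), offset + len(seq))
            window = contig.seq[lo:hi]
            aligned = seq[lo - offset : hi - offset]
            mism = sum(a != b for a, b in zip(window, aligned))
            assert mism <= int(mmf * len(window))

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        src = random_dna(rng, 3000)
        pairs = tiling_pairs(src, depth=20)
        a = assemble(pairs, AsmParams(min_contig_len=100))
        b = assemble(pairs, AsmParams(min_contig_len=100))
        assert [c.seq for c in a.contigs] == [c.seq for c in b.contigs]

    @given(st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_repeat_free_sources_reconstruct(self, seed):
        rng = np.random.default_rng(seed)
        src = random_dna(rng, 1000 + int(rng.integers(0, 1000)))
        asm = assemble(tiling_pairs(src, depth=25), AsmParams(min_contig_len=100))
        assert asm.n_contigs == 1
        assert asm.contigs[0].seq in (src, revcomp(src))


class TestOverlapSets:
    def test_prefilter_matches_exhaustive_overlaps(self):
        rng = np.random.default_rng(13)
        src = random_dna(rng, 600)
        starts = sorted(rng.integers(0, 500, size=40))
        reads = reads_from(src, starts)
        params = AsmParams()
        assert detect_overlaps(reads, params) == find_overlaps(reads, params)

    def test_monotone_stringency(self):
        rng = np.random.default_rng(14)
        src = random_dna(rng, 400)
        reads = reads_from(src, sorted(rng.integers(0, 300, size=25)))
        base = find_overlaps(reads, AsmParams())
        stricter_len = find_overlaps(reads, AsmParams(min_overlap_len=60))
        stricter_id = find_overlaps(
            reads, AsmParams(min_overlap_identity=99.0)
        )
        assert len(stricter_len) <= len(base)
        assert len(stricter_id) <= len(base)
        assert {(a, b, o) for a, b, _, o in stricter_len} <= {
            (a, b, o) for a, b, _, o in base
        }


@pytest.fixture(scope="module")
def contig():
    rng = np.random.default_rng(15)
    return Contig(id="c1", seq=random_dna(rng, 2000), mean_depth=1.0, members=[])


class TestMapReads:

    def test_interior_exact_read_is_full(self, contig):
        read = ReadRecord("r", 1, contig.seq[500:600], np.full(100, 38))
        (m,) = map_reads([read], [contig])
        assert m.cls == "Full" and m.start == 500 and m.identity == 1.0

    def test_end_overhang_is_partial(self, contig):
        # read overlaps the contig start by 60 of its 100 nt
        seq = random_dna(np.random.default_rng(16), 40) + contig.seq[:60]
        (m,) = map_reads([ReadRecord("r", 1, seq, np.full(100, 38))], [contig])
        assert m.cls == "Partial"
        assert m.start == 0 and m.end == 60

    def test_reverse_strand_read_maps(self, contig):
        read = ReadRecord("r", 1, revcomp(contig.seq[800:900]), np.full(100, 38))
        (m,) = map_reads([read], [contig])
        assert m.cls == "Full" and m.strand == "-"

    def test_random_reads_unmapped(self, contig):
        rng = np.random.default_rng(17)
        reads = [
            ReadRecord(f"r{i}", 1, random_dna(rng, 100), np.full(100, 38))
            for i in range(50)
        ]
        assert all(m.cls == "Unmapped" for m in map_reads(reads, [contig]))

    def test_requires_contigs(self):
        with pytest.raises(ValueError):
            map_reads([], [])
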