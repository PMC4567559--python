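"""Six-frame translation and the seed-and-extend search engine, checked
against an independent dynamic-programming aligner."""

from __future__ import annotations

import numpy as np
import pytest

from endosift._encode import encode_aa, encode_dna, revcomp
from endosift.homsearch import (
    Hit,
    SearchParams,
    best_hit_table,
    search,
    six_frame_translate,
)
from endosift.synthdata import SimScenario, make_genome_set

from _oracles import sw_score
from endosift.homsearch import _SUB_AA, _SUB_NT

from conftest import random_dna


class TestSixFrameTranslate:
    def test_standard_code_forward(self):
        assert six_frame_translate("ATGGCC")[1] == "MA"

    def test_reverse_frame_reads_reverse_complement(self):
        # revcomp("ATGGCC") == "GGCCAT" -> frame -1 reads GGC CAT -> "GH"
        assert six_frame_translate("ATGGCC")[-1] == "GH"

    def test_partial_codons_dropped(self):
        frames = six_frame_translate("ATGG")
        assert len(frames[2]) == 1
        assert frames[3] == ""

    def test_n_translates_to_x_and_stops_to_star(self):
        assert six_frame_translate("TAANAA")[1] == "*X"

    def test_too_short_input(self):
        assert all(p == "" for p in six_frame_translate("AT").values())


class TestSearch:
    def test_self_hit_full_span_identity_one(self):
        rng = np.random.default_rng(0)
        s = random_dna(rng, 3000)
        hits = search([("q", s)], [("s", s)], SearchParams(mode="nucleotide"))
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0
        assert h.q_span == (0, 3000) and h.s_span == (0, 3000)

    def test_diverged_orf_found_translated(self):
        sc = SimScenario(seed=1, target_len=20_000, host_len=20_000,
                         ref_aa_divergences=(0.25,))
        gs = make_genome_set(sc)
        params = SearchParams(mode="translated")
        found = 0
        orfs = [g for g in gs.gene_table if g[1] - g[0] >= 300][:10]
        for start, end, strand, _ in orfs:
            hits = search(
                [("orf", gs.target[start:end])], [("ref", gs.refs["0.25"])], params
            )
            found += bool(hits and hits[0].evalue < 1e-12)
        assert found == len(orfs)

    def test_random_sequences_no_hits(self):
        rng = np.random.default_rng(42)
        subject = random_dna(rng, 50_000)
        n_hits = 0
        for _ in range(100):
            q = random_dna(rng, 1000)
            n_hits += len(
                search([("q", q)], [("s", subject)], SearchParams(mode="nucleotide"))
            )
        assert n_hits == 0

    def test_detection_symmetry(self):
        sc = SimScenario(seed=2, target_len=12_000, host_len=20_000,
                         ref_aa_divergences=(0.2,))
        gs = make_genome_set(sc)
        start, end, _, _ = max(gs.gene_table, key=lambda g: g[1] - g[0])
        a, b = gs.target[start:end], gs.refs["0.2"]
        pab = search([("A", a)], [("B", b)], SearchParams(mode="translated"))
        pba = search([("B", b)], [("A", a)], SearchParams(mode="translated"))
        assert bool(pab) == bool(pba)
        assert pab[0].raw_score == pba[0].raw_score
        assert pab[0].q_span == pba[0].s_span and pab[0].s_span == pba[0].q_span

    def test_evalue_monotonicity(self):
        sc = SimScenario(seed=3, target_len=12_000, host_len=20_000,
                         ref_aa_divergences=(0.25,))
        gs = make_genome_set(sc)
        loose = search(
            [("t", gs.target)], [("r", gs.refs["0.25"])],
            SearchParams(mode="translated", evalue_max=1e-3, keep_best_only=False),
        )
        tight = search(
            [("t", gs.target)], [("r", gs.refs["0.25"])],
            SearchParams(mode="translated", evalue_max=1e-20, keep_best_only=False),
        )
        loose_keys = {(h.q_span, h.s_span, h.q_frame, h.s_frame) for h in loose}
        tight_keys = {(h.q_span, h.s_span, h.q_frame, h.s_frame) for h in tight}
        assert tight_keys <= loose_keys
        assert all(h.evalue < 1e-20 for h in tight)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError):
            SearchParams(sub_matrix="PAM250")
        with pytest.raises(ValueError):
            SearchParams(mode="protein")


def span_peptides(hit: Hit, qseq: str, sseq: str) -> tuple[str, str]:
    """Extract the aligned segment translations implied by a translated hit."""
    def seg(seq, span, frame):
        s = seq[span[0] : span[1]]
        if frame < 0:
            s = revcomp(s)
        return six_frame_translate(s + "TT")[1][: (span[1] - span[0]) // 3]

    return seg(qseq, hit.q_span, hit.q_frame), seg(sseq, hit.s_span, hit.s_frame)


class TestScoreOracle:
    def test_translated_scores_match_ungapped_dp(self):
        sc = SimScenario(seed=4, target_len=15_000, host_len=20_000,
                         ref_aa_divergences=(0.2,))
        gs = make_genome_set(sc)
        hits = search(
            [("t", gs.target)], [("r", gs.refs["0.2"])],
            SearchParams(mode="translated", keep_best_only=False),
        )
        assert hits
        for h in hits[:25]:
            pq, ps = span_peptides(h, gs.target, gs.refs["0.2"])
            oracle = sw_score(
                encode_aa(pq), encode_aa(ps), _SUB_AA.astype(np.int64), 10**6, 0
            )
            assert oracle == int(h.raw_score)

    def test_nucleotide_scores_match_affine_dp(self):
        rng = np.random.default_rng(9)
        base = random_dna(rng, 1500)
        codes = encode_dna(base).copy()
        mask = rng.random(len(codes)) < 0.05
        codes[mask] = (codes[mask] + rng.integers(1, 4, len(codes))[mask].astype(np.uint8)) % 4
        mutated = "".join("ACGTN"[c] for c in codes)
        hits = search(
            [("q", mutated)], [("s", base)],
            SearchParams(mode="nucleotide", keep_best_only=False),
        )
        assert hits
        for h in hits:
            qs = mutated[h.q_span[0] : h.q_span[1]]
            ss = base[h.s_span[0] : h.s_span[1]]
            qseg = encode_dna(revcomp(qs) if h.q_frame < 0 else qs)
            sseg = encode_dna(revcomp(ss) if h.s_frame < 0 else ss)
            oracle = sw_score(qseg, sseg, _SUB_NT.astype(np.int64), 5, 2)
            assert oracle == int(h.raw_score)


class TestBestHitTable:
    def h(self, q, s, bits, ev):
        return Hit(q, s, "translated", bits, bits, ev, 1.0, (0, 3), (0, 3), 1, 1)

    def test_empty(self):
        assert best_hit_table([]) == {}

    def test_highest_bits_wins(self):
        t = best_hit_table([self.h("q", "a", 50, 1e-20), self.h("q", "b", 60, 1e-22)])
        assert t["q"].subject_id == "b"

    def test_tie_breaks_to_lexicographic_subject(self):
        t = best_hit_table([self.h("q", "z", 50, 1e-20), self.h("q", "a", 50, 1e-20)])
        assert t["q"].subject_id == "a"
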