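"""Truth-based evaluation: the >99.0% origin criterion, TP/FN/FP length
accounting, and the genome-fraction / NGA50 metrics against brute-force
oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endosift._encode import encode_dna, revcomp
from endosift.asmeval import (
    AlignedBlock,
    aligned_blocks,
    assign_origin,
    confusion_lengths,
    estimate_purity,
    genome_fraction,
    nga50,
)
from endosift.microasm import Contig
from endosift.synthdata import SimScenario, make_genome_set, simulate_library
from endosift.tcsf import SelectionOutcome

from _oracles import brute_genome_fraction, brute_nga50
from conftest import random_dna


@pytest.fixture(scope="module")
def truth(small_genomes):
    gs = small_genomes
    return {
        "target": gs.target,
        "host": gs.host,
        "mito": gs.mito,
        "rrna": gs.host_rrna,
        "contaminant": gs.contaminant,
    }


class TestAssignOrigin:
    def test_exact_target_slice(self, truth):
        assert assign_origin(truth["target"][2000:5000], truth) == "target"

    def test_wrapping_slice_of_circular_target(self, truth):
        t = truth["target"]
        assert assign_origin(t[-1500:] + t[:1500], truth) == "target"

    def test_reverse_complement_slice(self, truth):
        assert assign_origin(revcomp(truth["host"][3000:6000]), truth) == "other"

    def test_two_percent_mutated_slice_fails_threshold(self, truth):
        rng = np.random.default_rng(0)
        codes = encode_dna(truth["target"][1000:4000]).copy()
        k = int(0.02 * len(codes))
        pos = rng.choice(len(codes), size=k, replace=False)
        codes[pos] = (codes[pos] + 1) % 4
        seq = "".join("ACGT"[c] for c in codes)
        assert assign_origin(seq, truth) != "target"

    def test_random_sequence_unassigned(self, truth):
        seq = random_dna(np.random.default_rng(1), 1000)
        assert assign_origin(seq, truth) == "unassigned"


class TestConfusionLengths:
    def sel(self, kept, no_hit=(), mito=(), rrna=()):
        return SelectionOutcome(
            kept=list(kept),
            removed_no_hit=list(no_hit),
            removed_mito=list(mito),
            removed_rrna=list(rrna),
        )

    def test_all_kept_all_target(self):
        tp, fn, fp = confusion_lengths(
            self.sel(["a", "b"]),
            {"a": "target", "b": "target"},
            {"a": 1000, "b": 500},
        )
        assert (tp, fn, fp) == (1500, 0, 0)

    def test_removed_target_counts_fn(self):
        tp, fn, fp = confusion_lengths(
            self.sel([], no_hit=["a"]), {"a": "target"}, {"a": 1000}
        )
        assert (tp, fn, fp) == (0, 1000, 0)

    def test_kept_host_counts_fp(self):
        tp, fn, fp = confusion_lengths(
            self.sel(["h"]), {"h": "other"}, {"h": 700}
        )
        assert fp == 700

    def test_kept_unassigned_counts_fp(self):
        _, _, fp = confusion_lengths(
            self.sel(["x"]), {"x": "unassigned"}, {"x": 300}
        )
        assert fp == 300

    def test_missing_assignment_is_error(self):
        with pytest.raises(KeyError):
            confusion_lengths(self.sel(["a"]), {}, {"a": 10})

    def test_tp_plus_fn_invariant_across_selections(self):
        assignments = {"a": "target", "b": "target", "c": "other"}
        lens = {"a": 100, "b": 200, "c": 300}
        for kept in (["a"], ["a", "b"], [], ["a", "b", "c"]):
            rest = [x for x in lens if x not in kept]
            tp, fn, _ = confusion_lengths(self.sel(kept, no_hit=rest), assignments, lens)
            assert tp + fn == 300


class TestMetrics:
    def test_single_contig_whole_target(self, truth):
        t = truth["target"]
        contigs = [Contig("c", t, 1.0, [])]
        assert genome_fraction(contigs, t) == pytest.approx(100.0)
        val, defined = nga50(contigs, t)
        assert defined and val == len(t)

    def test_hand_example_two_blocks(self):
        blocks = [AlignedBlock("a", 0, 30_000), AlignedBlock("b", 30_000, 50_000)]
        assert genome_fraction(blocks, 50_000) == pytest.approx(100.0)
        val, defined = nga50(blocks, 50_000)
        assert defined and val == 30_000

    def test_low_coverage_undefined(self):
        blocks = [AlignedBlock("a", 0, 20_000)]
        val, defined = nga50(blocks, 50_000)
        assert not defined and val == 0

    def test_empty_contigs(self, truth):
        assert genome_fraction([], truth["target"]) == 0.0
        assert nga50([], truth["target"]) == (0, False)

    def test_monotone_under_added_contigs(self, truth):
        t = truth["target"]
        pieces = [t[:3000], t[5000:9000], t[2000:6000]]
        fractions = []
        for i in range(1, len(pieces) + 1):
            contigs = [Contig(f"c{j}", s, 1.0, []) for j, s in enumerate(pieces[:i])]
            fractions.append(genome_fraction(contigs, t))
        assert fractions == sorted(fractions)

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_oracle_identity_on_random_block_sets(self, data):
        target_len = data.draw(st.integers(1000, 40_000))
        n = data.draw(st.integers(0, 12))
        blocks = []
        for i in range(n):
            lo = data.draw(st.integers(0, target_len - 1))
            ln = data.draw(st.integers(31, max(32, target_len // 2)))
            blocks.append(AlignedBlock(f"b{i}", lo, lo + ln))
        tuples = [(b.t_start, b.t_end) for b in blocks]
        assert genome_fraction(blocks, target_len) == pytest.approx(
            brute_genome_fraction(tuples, target_len)
        )
        assert nga50(blocks, target_len) == brute_nga50(tuples, target_len)

    def test_aligned_blocks_of_rotated_contig(self, truth):
        t = truth["target"]
        rotated = t[4000:] + t[:4000]
        blocks = aligned_blocks([Contig("c", rotated, 1.0, [])], t)
        assert blocks
        assert genome_fraction(blocks, len(t)) == pytest.approx(100.0, abs=0.5)


class TestEstimatePurity:
    def test_pure_error_free_library_maps_fully(self):
        sc = SimScenario(seed=31, target_len=10_000, host_len=20_000, purity=1.0,
                         target_depth=4, per_base_error=0.0, qc_fail_frac=0.0)
        gs = make_genome_set(sc)
        pairs, _ = simulate_library(gs, sc)
        assert estimate_purity(pairs, gs.target) == pytest.approx(100.0)

    def test_mixture_estimate_matches_truth(self, small_scenario, small_genomes,
                                            small_library):
        pairs, truth_df = small_library
        est = estimate_purity(pairs, small_genomes.target)
        true_pct = 100.0 * (truth_df["truth"] == "target").mean()
        assert abs(est - true_pct) <= 1.0

    def test_empty_reads_rejected(self, truth):
        with pytest.raises(ValueError):
            estimate_purity([], truth["target"])
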