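from __future__ import annotations

import numpy as np
import pytest

from endosift._encode import revcomp
from endosift.synthdata import (
    GenomeSet,
    ReadPair,
    ReadRecord,
    SimScenario,
    make_genome_set,
    simulate_library,
)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def make_pair(i: int, fwd_seq: str, rev_seq: str, q: int = 38) -> ReadPair:
    pid = f"p{i:05d}"
    return ReadPair(
        pair_id=pid,
        fwd=ReadRecord(f"{pid}/1", 1, fwd_seq, np.full(len(fwd_seq), q, dtype=np.int16)),
        rev=ReadRecord(f"{pid}/2", 2, rev_seq, np.full(len(rev_seq), q, dtype=np.int16)),
    )


def tiling_pairs(
    source: str,
    depth: float = 30,
    insert: int = 230,
    read_len: int = 100,
) -> list[ReadPair]:
    """Error-free pairs whose fragments tile the source end to end."""
    L = len(source)
    n = max(2, int(L * depth / (2 * read_len)))
    starts = np.linspace(0, L - insert, n).astype(int)
    out = []
    for i, s in enumerate(starts):
        frag = source[s : s + insert]
        out.append(make_pair(i, frag[:read_len], revcomp(frag[-read_len:])))
    return out


@pytest.fixture(scope="session")
def small_scenario() -> SimScenario:
    return SimScenario(
        seed=11,
        target_len=12_000,
        host_len=30_000,
        mito_len=6_000,
        purity=0.4,
        target_depth=18,
        ref_aa_divergences=(0.0, 0.25),
    )


@pytest.fixture(scope="session")
def small_genomes(small_scenario) -> GenomeSet:
    return make_genome_set(small_scenario)


@pytest.fixture(scope="session")
def small_library(small_scenario, small_genomes):
    return simulate_library(small_genomes, small_scenario)
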