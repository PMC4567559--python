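"""Low-level DNA/peptide encodings shared by the simulator, assembler and search engine.

Sequences travel through the public API as Python strings; hot loops work on
``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4 for DNA; index into a fixed
alphabet for peptides).
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGTN"

_DNA_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _DNA_LUT[ord(_b)] = _i
    _DNA_LUT[ord(_b.lower())] = _i

_DNA_CHARS = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMP_LUT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

# Protein alphabet used across the search engine; '*' is a stop, 'X' unknown.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_LUT = np.full(256, AA_ALPHABET.index("X"), dtype=np.uint8)
for _i, _a in enumerate(AA_ALPHABET):
    _AA_LUT[ord(_a)] = _i


def encode_dna(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string to uint8 codes (unknown characters become N)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _DNA_LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    return _DNA_CHARS[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_LUT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode_dna(revcomp_codes(encode_dna(seq)))


def encode_aa(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _AA_LUT[np.frombuffer(seq, dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int, base: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes of a code array.

    Returns ``(codes64, valid)`` of length ``len(codes) - k + 1``; ``valid`` is
    False for windows containing an out-of-alphabet symbol (e.g. N for DNA with
    ``base=4``).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    c = codes.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        out = out * base + c[i : i + n]
    bad = (codes >= base).astype(np.int32)
    if bad.any():
        cs = np.concatenate([[0], np.cumsum(bad)])
        valid = (cs[k:] - cs[:-k]) == 0
    else:
        valid = np.ones(n, dtype=bool)
    return out, valid


def mismatches(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two equal-length code arrays."""
    return int(np.count_nonzero(a != b))


def gc_fraction(seq: str) -> float:
    codes = encode_dna(seq)
    return float(np.count_nonzero((codes == 1) | (codes == 2)) / max(len(codes), 1))
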