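"""Quality filtering of raw paired reads.

The rule set: bases with Phred quality < 27 are trimmed from the 3' end;
after trimming, a read is discarded when its overall mean quality is < 27
or its length is < 80 nt; a pair survives only when both mates survive
(unpaired single reads are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthdata import ReadPair, ReadRecord

__all__ = ["QCParams", "QCReport", "trim_3prime", "filter_pairs"]


@dataclass(frozen=True)
class QCParams:
    trim_q: int = 27
    min_mean_q: float = 27.0
    min_len: int = 80

    def __post_init__(self) -> None:
        if self.trim_q < 0 or self.min_mean_q < 0 or self.min_len < 0:
            raise ValueError("QC parameters must be non-negative")


@dataclass
class QCReport:
    n_pairs_in: int = 0
    n_pairs_out: int = 0
    n_reads_trimmed: int = 0
    n_dropped_low_mean: int = 0
    n_dropped_short: int = 0
    n_dropped_unpaired: int = 0  # surviving mates discarded because the partner failed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def trim_3prime(read: ReadRecord, trim_q: int = 27) -> ReadRecord:
    """Drop the maximal 3' suffix in which every base has quality < trim_q."""
    q = read.qual
    n = len(q)
    while n > 0 and q[n - 1] < trim_q:
        n -= 1
    if n == len(q):
        return read
    return ReadRecord(read.id, read.mate, read.seq[:n], q[:n], read.truth)


def _passes(read: ReadRecord, params: QCParams) -> tuple[bool, str | None]:
    if len(read.seq) < params.min_len:
        return False, "short"
    if read.mean_quality() < params.min_mean_q:
        return False, "low_mean"
    return True, None


def filter_pairs(
    pairs: list[ReadPair], params: QCParams | None = None
) -> tuple[list[ReadPair], QCReport]:
    """Trim both mates, then keep only pairs in which both mates pass.

    A read passes when (post-trim) mean quality >= min_mean_q AND length
    >= min_len.  Ties at the thresholds are kept (the discard rules use
    strict '<').
    """
    params = params or QCParams()
    report = QCReport(n_pairs_in=len(pairs))
    kept: list[ReadPair] = []
    for pair in pairs:
        fwd = trim_3prime(pair.fwd, params.trim_q)
        rev = trim_3prime(pair.rev, params.trim_q)
        report.n_reads_trimmed += (len(fwd.seq) < len(pair.fwd.seq)) + (
            len(rev.seq) < len(pair.rev.seq)
        )
        ok_f, why_f = _passes(fwd, params)
        ok_r, why_r = _passes(rev, params)
        for why in (why_f, why_r):
            if why == "short":
                report.n_dropped_short += 1
            elif why == "low_mean":
                report.n_dropped_low_mean += 1
        if ok_f and ok_r:
            kept.append(ReadPair(pair.pair_id, fwd, rev))
        else:
            report.n_dropped_unpaired += int(ok_f) + int(ok_r)
    report.n_pairs_out = len(kept)
    return kept, report
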