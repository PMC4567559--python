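"""TBLASTX Contig Selection and Filtering.

Step 1: contigs are searched (translated mode by default, nucleotide mode
for the comparison method) against the reference genome of a related
organism; contigs without any hit at E < 1e-12 are filtered out.
Step 2: surviving contigs are searched against decoy sequences — the host
mitochondrial genome (translated) and the host rRNA gene (nucleotide) — and
a contig whose best decoy bit score strictly exceeds its best reference bit
score is evicted.  Ties retain the contig (favoring sensitivity); bit scores
are used as the comparator because they are search-space independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .homsearch import Hit, SearchParams, best_hit_table, search
from .microasm import Assembly, Contig

__all__ = ["SelectionOutcome", "select_contigs", "compare_selection_modes"]

logger = logging.getLogger(__name__)


@dataclass
class SelectionOutcome:
    kept: list[str]
    removed_no_hit: list[str]
    removed_mito: list[str]
    removed_rrna: list[str]
    ref_hits: dict[str, Hit] = field(default_factory=dict)
    mito_hits: dict[str, Hit] = field(default_factory=dict)
    rrna_hits: dict[str, Hit] = field(default_factory=dict)

    def all_ids(self) -> list[str]:
        return (
            list(self.kept)
            + list(self.removed_no_hit)
            + list(self.removed_mito)
            + list(self.removed_rrna)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.all_ids():
            if cid in self.removed_no_hit:
                fate = "removed_no_hit"
            elif cid in self.removed_mito:
                fate = "removed_mito"
            elif cid in self.removed_rrna:
                fate = "removed_rrna"
            else:
                fate = "kept"
            h = self.ref_hits.get(cid)
            rows.append(
                {
                    "contig": cid,
                    "fate": fate,
                    "ref_bits": h.bit_score if h else float("nan"),
                    "ref_evalue": h.evalue if h else float("nan"),
                    "mito_bits": (
                        self.mito_hits[cid].bit_score
                        if cid in self.mito_hits
                        else float("nan")
                    ),
                    "rrna_bits": (
                        self.rrna_hits[cid].bit_score
                        if cid in self.rrna_hits
                        else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows)


def _as_seqs(contigs) -> list[tuple[str, str]]:
    if isinstance(contigs, Assembly):
        return [(c.id, c.seq) for c in contigs.contigs]
    if contigs and isinstance(contigs[0], Contig):
        return [(c.id, c.seq) for c in contigs]
    return [(str(a), str(b)) for a, b in contigs]


def select_contigs(
    contigs,
    reference,
    mito=None,
    host_rrna=None,
    evalue_max: float = 1e-12,
    comparison_mode: str = "translated",
) -> SelectionOutcome:
    """Partition contigs into kept / no-hit / mito-better / rrna-better.

    ``reference`` (required) and the decoys are (id, seq) iterables, dicts or
    single strings; the reference may be multi-FASTA (best hit across
    records).  ``comparison_mode`` selects the reference search mode:
    translated is the selection method proper, nucleotide the comparison
    method; decoy searches always use translated (mito) and nucleotide
    (rRNA) modes.
    """
    qseqs = _as_seqs(contigs)
    ref = _single_or_seqs(reference, "reference")
    if not ref or all(not s for _, s in ref):
        raise ValueError("empty reference genome")

    ref_hits = best_hit_table(
        search(
            qseqs,
            ref,
            SearchParams(
                mode=comparison_mode, evalue_max=evalue_max, keep_best_only=True
            ),
        )
    )
    survivors = [(cid, seq) for cid, seq in qseqs if cid in ref_hits]
    removed_no_hit = [cid for cid, _ in qseqs if cid not in ref_hits]

    mito_hits: dict[str, Hit] = {}
    rrna_hits: dict[str, Hit] = {}
    if survivors:
        mito_seqs = _single_or_seqs(mito, "mito")
        if mito_seqs:
            # the mito decoy is compared in the same mode as the reference
            # search so the "better hit" bit scores share one scale
            mito_hits = best_hit_table(
                search(
                    survivors,
                    mito_seqs,
                    SearchParams(
                        mode=comparison_mode,
                        evalue_max=evalue_max,
                        keep_best_only=True,
                    ),
                )
            )
        else:
            logger.warning("no mitochondrial decoy supplied; mito filter skipped")
        rrna_seqs = _single_or_seqs(host_rrna, "host_rrna")
        if rrna_seqs:
            rrna_hits = best_hit_table(
                search(
                    survivors,
                    rrna_seqs,
                    SearchParams(
                        mode="nucleotide", evalue_max=evalue_max, keep_best_only=True
                    ),
                )
            )
        else:
            logger.warning("no host rRNA decoy supplied; rRNA filter skipped")

    kept, removed_mito, removed_rrna = [], [], []
    for cid, _ in survivors:
        ref_bits = ref_hits[cid].bit_score
        mito_bits = mito_hits[cid].bit_score if cid in mito_hits else None
        rrna_bits = rrna_hits[cid].bit_score if cid in rrna_hits else None
        if mito_bits is not None and mito_bits > ref_bits:
            removed_mito.append(cid)
        elif rrna_bits is not None and rrna_bits > ref_bits:
            removed_rrna.append(cid)
        else:
            kept.append(cid)
    return SelectionOutcome(
        kept=kept,
        removed_no_hit=removed_no_hit,
        removed_mito=removed_mito,
        removed_rrna=removed_rrna,
        ref_hits=ref_hits,
        mito_hits=mito_hits,
        rrna_hits=rrna_hits,
    )


def _single_or_seqs(obj, default_id: str):
    if obj is None:
        return None
    if isinstance(obj, str):
        return [(default_id, obj)]
    return _as_seqs(obj)


def compare_selection_modes(
    contigs,
    reference_panel: dict[str, str],
    assignments: dict[str, str],
    contig_lens: dict[str, int],
    mito=None,
    host_rrna=None,
    evalue_max: float = 1e-12,
    modes: tuple[str, ...] = ("translated", "nucleotide"),
) -> tuple[pd.DataFrame, dict[tuple[str, str], SelectionOutcome]]:
    """Run selection for every (mode, reference) cell and tabulate TP/FN/FP
    total lengths against truth assignments (contig id -> origin label)."""
    from .asmeval import confusion_lengths

    rows = []
    outcomes: dict[tuple[str, str], SelectionOutcome] = {}
    for mode in modes:
        for ref_label, ref_seq in reference_panel.items():
            outcome = select_contigs(
                contigs,
                ref_seq,
                mito=mito,
                host_rrna=host_rrna,
                evalue_max=evalue_max,
                comparison_mode=mode,
            )
            tp, fn, fp = confusion_lengths(outcome, assignments, contig_lens)
            outcomes[(mode, ref_label)] = outcome
            rows.append(
                {
                    "mode": mode,
                    "reference": ref_label,
                    "tp_nt": tp,
                    "fn_nt": fn,
                    "fp_nt": fp,
                    "n_kept": len(outcome.kept),
                }
            )
    return pd.DataFrame(rows), outcomes
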