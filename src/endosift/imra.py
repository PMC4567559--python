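"""Iterative Mapping and ReAssembling.

Loop: map *all* QC-passed reads (single-end) onto the current contig set;
rescue every read pair with at least one Full/Partial mate; reassemble the
rescued pairs from scratch in paired-end mode; discard contigs shorter than
the cutoff (500 nt by default, 1000 nt as the strict option); repeat until
the total contig length and the contig count have both saturated.

The cutoff doubles as the guard against elongation of contaminant sequences:
reads recruited around a sub-cutoff contig cannot elongate it past the
cutoff within one iteration when the cutoff comfortably exceeds twice the
library insert size, so such contigs are discarded again each round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .asmeval import EvalReport, evaluate
from .microasm import AsmParams, Assembly, Contig, MappingRecord, assemble, map_reads
from .readqc import QCParams, QCReport, filter_pairs
from .synthdata import ReadPair
from .tcsf import SelectionOutcome, select_contigs

__all__ = ["ImraParams", "IterationStats", "ImraResult", "recruit_pairs", "iterate", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImraParams:
    min_contig_len: int = 500  # strict option: 1000
    saturation_len_tol: int = 0
    saturation_window: int = 2
    max_iter: int = 30
    asm: AsmParams = field(default_factory=lambda: AsmParams(min_contig_len=500))

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.saturation_window < 1:
            raise ValueError("saturation_window must be >= 1")
        # keep the assembler's own length filter in lockstep with ours
        object.__setattr__(
            self, "asm", replace(self.asm, min_contig_len=self.min_contig_len)
        )
        if self.min_contig_len < 2 * self.asm.insert_mean:
            logger.warning(
                "min_contig_len (%d) is below twice the insert size (%.0f); "
                "contaminant contigs may survive elongation",
                self.min_contig_len,
                self.asm.insert_mean,
            )


@dataclass(frozen=True)
class IterationStats:
    iter: int
    n_contigs: int
    total_len: int
    n_pairs_recruited: int
    delta_len: int
    delta_count: int


@dataclass
class ImraResult:
    assembly: Assembly
    stats: list[IterationStats]
    converged: bool

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stats])


def recruit_pairs(
    mapping: list[MappingRecord], all_pairs: list[ReadPair]
) -> list[ReadPair]:
    """Pairs with at least one Full/Partial mate, in pair-id order."""
    mapped_ids = {m.read_id for m in mapping if m.mapped}
    out = [
        p
        for p in all_pairs
        if p.fwd.id in mapped_ids or p.rev.id in mapped_ids
    ]
    out.sort(key=lambda p: p.pair_id)
    return out


def iterate(
    seed_contigs: list[Contig] | Assembly,
    all_pairs: list[ReadPair],
    params: ImraParams | None = None,
) -> ImraResult:
    """Run IMRA to saturation from a seed contig set.

    Stops when, over ``saturation_window`` consecutive iterations, the
    contig count is unchanged and |delta total length| <= tolerance; or on a
    single-contig fixed point; or at ``max_iter`` (logged as non-converged).
    Returns the assembly of the best iteration (largest total length among
    the minimal-contig-count iterations).
    """
    params = params or ImraParams()
    if isinstance(seed_contigs, Assembly):
        seed_contigs = seed_contigs.contigs
    if not seed_contigs:
        raise ValueError("TCSF produced no contigs")
    all_reads = [r for p in all_pairs for r in (p.fwd, p.rev)]

    current = list(seed_contigs)
    stats: list[IterationStats] = [
        IterationStats(
            iter=0,
            n_contigs=len(current),
            total_len=sum(len(c.seq) for c in current),
            n_pairs_recruited=0,
            delta_len=0,
            delta_count=0,
        )
    ]
    best: tuple[int, int, Assembly] | None = None
    converged = False
    sat_streak = 0
    for it in range(1, params.max_iter + 1):
        mapping = map_reads(all_reads, current, params.asm)
        recruited = recruit_pairs(mapping, all_pairs)
        if not recruited:
            logger.warning("IMRA iteration %d recruited no pairs; stopping", it)
            break
        asm = assemble(recruited, params.asm)
        prev = stats[-1]
        st = IterationStats(
            iter=it,
            n_contigs=asm.n_contigs,
            total_len=asm.total_len,
            n_pairs_recruited=len(recruited),
            delta_len=asm.total_len - prev.total_len,
            delta_count=asm.n_contigs - prev.n_contigs,
        )
        stats.append(st)
        if asm.n_contigs == 0:
            logger.warning("IMRA iteration %d produced no contigs; stopping", it)
            break
        cand = (asm.n_contigs, -asm.total_len, asm)
        if best is None or cand[:2] <= best[:2]:
            best = cand
        current = asm.contigs
        if (
            st.delta_count == 0
            and abs(st.delta_len) <= params.saturation_len_tol
        ):
            sat_streak += 1
        else:
            sat_streak = 0
        if sat_streak >= params.saturation_window or (
            asm.n_contigs == 1 and st.delta_len == 0 and it > 1
        ):
            converged = True
            break
    if not converged:
        logger.warning("IMRA did not converge within %d iterations", params.max_iter)
    assembly = best[2] if best is not None else Assembly(contigs=[])
    return ImraResult(assembly=assembly, stats=stats, converged=converged)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    qc_report: QCReport
    de_novo: Assembly
    selection: SelectionOutcome
    imra: ImraResult
    final: Assembly
    eval_de_novo: EvalReport | None = None
    eval_final: EvalReport | None = None

    def summary(self) -> str:
        lines = [
            "pipeline summary",
            f"  QC: {self.qc_report.n_pairs_out}/{self.qc_report.n_pairs_in} pairs kept",
            f"  de novo: {self.de_novo.n_contigs} contigs, {self.de_novo.total_len} nt",
            f"  TCSF: kept {len(self.selection.kept)}, no-hit {len(self.selection.removed_no_hit)}, "
            f"mito {len(self.selection.removed_mito)}, rRNA {len(self.selection.removed_rrna)}",
            f"  IMRA: {len(self.imra.stats) - 1} iterations, converged={self.imra.converged}",
            f"  final: {self.final.n_contigs} contigs, {self.final.total_len} nt",
        ]
        if self.eval_final is not None:
            lines.append(
                f"  genome fraction {self.eval_final.genome_fraction:.2f}%, "
                f"NGA50 {self.eval_final.nga50}"
            )
        return "\n".join(lines)


def run_pipeline(
    pairs: list[ReadPair],
    reference,
    mito=None,
    host_rrna=None,
    qc_params: QCParams | None = None,
    de_novo_params: AsmParams | None = None,
    imra_params: ImraParams | None = None,
    evalue_max: float = 1e-12,
    comparison_mode: str = "translated",
    truth_genomes: dict[str, str] | None = None,
) -> PipelineResult:
    """QC -> de novo assembly (100-nt cutoff) -> TCSF -> IMRA."""
    qc_params = qc_params or QCParams()
    de_novo_params = de_novo_params or AsmParams(min_contig_len=100)
    imra_params = imra_params or ImraParams()

    kept_pairs, qc_report = filter_pairs(pairs, qc_params)
    de_novo = assemble(kept_pairs, de_novo_params)
    selection = select_contigs(
        de_novo,
        reference,
        mito=mito,
        host_rrna=host_rrna,
        evalue_max=evalue_max,
        comparison_mode=comparison_mode,
    )
    seed = [c for c in de_novo.contigs if c.id in set(selection.kept)]
    if not seed:
        raise RuntimeError("TCSF produced no contigs")
    imra_result = iterate(seed, kept_pairs, imra_params)
    final = imra_result.assembly

    eval_dn = eval_fin = None
    if truth_genomes is not None:
        eval_dn = evaluate(de_novo, truth_genomes, selection=selection)
        eval_fin = evaluate(final, truth_genomes, pairs=kept_pairs)
    return PipelineResult(
        qc_report=qc_report,
        de_novo=de_novo,
        selection=selection,
        imra=imra_result,
        final=final,
        eval_de_novo=eval_dn,
        eval_final=eval_fin,
    )
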