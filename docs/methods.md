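# Methods

`endosift` re-creates, end to end and at desk scale, a strategy for
assembling the genome of an obligate intracellular symbiont directly from a
shotgun library of crude host tissue, in which the target genome is only a
small fraction ("purity") of the reads.  The strategy has five stages:

1. **Quality filtering** of raw paired reads;
2. **De novo assembly** of the whole mixed library with a greedy
   overlap-layout-consensus (OLC) assembler;
3. **TCSF** — contig selection by translated (six-frame) homology to a
   related reference genome at E < 10⁻¹², followed by eviction of contigs
   that hit a mitochondrial-genome or host-rRNA decoy better than the
   reference;
4. **IMRA** — iterative mapping of *all* reads onto the selected contigs
   (single-end), rescue of every pair with ≥ 1 Full/Partial mate,
   reassembly from the rescued pairs, and discarding of contigs below a
   length cutoff, repeated to saturation;
5. **Evaluation** — truth-based TP/FN/FP by total length, genome fraction,
   NGA50, and library-purity estimation.

The premise of stage 3 is that endosymbiont proteomes stay conserved at the
amino-acid level across large nucleotide distances, so a translated search
keeps its sensitivity where a nucleotide search loses it.  Stage 4 exploits
two effects: *debranching* (non-target reads that caused branch points are
excluded, letting split contigs merge) and *elongation* (rescued mates whose
unmapped ends overhang contig ends extend them, closing gaps at roughly
twice the insert size per iteration — a rate we observe directly in the
iteration statistics).

## Quality filtering

Bases with Phred quality < 27 are trimmed from the 3′ end; after trimming a
read is discarded when its overall mean quality is < 27 *or* its length is
< 80 nt, and a pair survives only if both mates survive.  The mean is
computed on the post-trim read, and ties at the thresholds are kept (the
rules use strict `<`).  Adapter handling is out of scope: simulated reads
carry no adapters.

## The assembler (`microasm`)

A deterministic greedy OLC assembler parameterized by minimum overlap
identity `mi` (default 90%) and minimum overlap length `ml` (default
40 nt) — parameter set A; set B is 85/35, and an `ml`=45 variant is
supported.  Overlap candidates come from a k-mer prefilter (k = 21, keyed
at read offsets {0, `ml`} per orientation so that one sequencing error
cannot hide a read); candidates are verified by direct mismatch counting
(the error model is substitution-dominated, so overlap verification needs
no indel alignment).  Contigs grow by the furthest-reaching qualifying
overlap.  A **branch** is declared when an alternative continuation is
supported by ≥ 2 mutually consistent reads against a chosen continuation
also supported by ≥ 2 reads; a lone conflicting read is treated as noise
(erroneous read), and when the *chosen* read is the lone dissenter it is
discarded instead.  After unitig construction each contig is polished by
per-column majority vote, and polished unitigs are merged by end overlap
under a strict branch rule (any conflict stops the merge) — this removes
the read-consumption artifact in which adjacent unitigs abut with
read-length overlaps.  Paired-end information then joins contig ends linked
by ≥ 3 consistently oriented pairs whose implied gap lies within
insert ± 4 SD, only when the ends actually overlap exactly (no N gaps are
ever emitted).  Finally, short contigs that align fully inside a longer
contig at ≥ `mi` (redundant unitigs seeded by error-bearing reads) are
absorbed into their host, and contigs below the stage cutoff (100 nt de
novo, 500 nt inside IMRA) are dropped.  Output order is deterministic
(length, then sequence).

Mapping (used by IMRA and the purity estimator) classifies each read
against its best contig position as **Full** (whole read aligned at ≥ `mi`),
**Partial** (≥ `ml` read bases aligned at ≥ `mi`, e.g. overhanging a contig
end), or **Unmapped**; best position maximizes aligned length × identity
with deterministic tie-breaks.

## The search engine (`homsearch`)

Two modes share one seed-and-extend engine:

* **translated** (the TBLASTX-style mode): all 6 × 6 conceptual-translation
  frame pairs, exact 4-residue amino-acid words as seeds (words containing
  stops or X do not seed), BLOSUM62 scoring, and — as in the real
  translated search program — **ungapped** extension: each seed diagonal is
  scored exactly by a maximum-sum segment.  Gapped extension was tried and
  rejected: two AT-biased random DNA sequences translate into similarly
  biased peptides, and gapped alignment can chain chance matches across
  stop codons into supercritical scores (the failure mode real BLAST
  counters with composition-based statistics and SEG masking, both of which
  are out of scope).  Ungapped extension with stops scoring −4 keeps random
  biased pairs subcritical while conserved regions still score freely.
* **nucleotide** (the megablast-style mode): exact 16-mers on both subject
  strands, +2/−3 scoring with affine gaps (open 5, extend 2), extension by
  exact local dynamic programming on a window around the seed cluster (the
  window plays the role of the band; windows above ~24 M cells are split).

Raw scores convert to bits with fixed Karlin–Altschul constants (ungapped
BLOSUM62 λ = 0.3176, K = 0.134; nucleotide λ = 0.625, K = 0.41) and
E = m·n·2^(−bits) with the plain product search space — no effective-length
correction.  E-values therefore approximate BLAST's; every consumer of the
engine depends only on threshold behavior at E < 10⁻¹² and on bit-score
comparisons, not on E-value parity.  One best hit per query is kept
(num-alignments = 1 behavior) with deterministic tie-breaks (bits, then
E-value, then subject id).

## Selection (`tcsf`)

Contigs without any reference hit at E < 10⁻¹² are removed.  Among
survivors, a contig is evicted when its best bit score against the
mitochondrial decoy or the host-rRNA decoy strictly exceeds its best
reference bit score; ties retain the contig (favoring sensitivity).  Bit
scores are the comparator because they are search-space independent.  The
mito decoy is searched in the same mode as the reference (translated in
TCSF proper, nucleotide in the nucleotide comparison method) so that the
"better hit" comparison never mixes scales; the rRNA decoy is always
nucleotide.  Missing decoys skip their filter with a logged warning.

## Iteration (`imra`)

Saturation is quantified as Δ(contig count) = 0 **and** |Δ(total length)| ≤
tolerance (default 0) over a window of 2 consecutive iterations, with a
single-contig fixed point as an early exit and `max_iter` (default 30) as a
logged non-convergence bound.  The returned assembly is the best iteration
(largest total length among minimal-contig-count iterations).  Reassembly
is from scratch each round from the rescued pairs, not incremental
extension.  The contig-length cutoff (default 500 nt, strict option
1000 nt) is applied after each reassembly; because one iteration can
elongate a contig by at most about twice the insert size (~460 nt here),
a cutoff comfortably above that bound keeps sparse contaminant sequences
from ratcheting past it — the package warns when the cutoff is below twice
the insert mean.

## Evaluation (`asmeval`)

A contig is credited to the target when an alignment covering ≥ 95% of the
contig is > 99.0% identical to it (the 95% coverage clause guards against a
short perfect island mislabeling a chimera; the identity threshold alone
does not pin down a coverage requirement, so 95% is this package's declared
contract).  Identity is computed with edlib in infix
mode on both strands, against a doubled target so circular rotations are
honored.  Kept non-target contigs — including unassignable ones — count as
FP, matching the conservative treatment of contaminant contigs.  Genome
fraction counts each target position once (set coverage).  NGA50 is the
largest L such that reference-aligned blocks of length ≥ L together span
≥ 50% of the target, undefined (reported 0 + flag) below 50% coverage;
blocks are maximal collinear runs of exact 31-mer anchors, split at
diagonal jumps or > 10 kb gaps, so a contig wrapping the circular origin
contributes two blocks.  Purity is estimated as the percentage of reads
with a Full/Partial mapping onto the (doubled) target at default
stringency.

## The simulator (`synthdata`)

The generator emulates the structure of a fat-body shotgun library:

* **Target**: circular, default 50 kb (a scaled-down stand-in for a ~0.6 Mb
  reduced chromosome), GC 0.26, ≥ 80% coding density.  Genes are random
  peptides with an AT-rich-proteome residue bias, back-translated with a
  greedy GC-steering codon chooser so realized GC lands within ±0.02 of the
  request; intergenic DNA is random at the same GC.
* **Reference panel**: for each requested amino-acid divergence *d*, gene
  peptides are mutated at rate *d* (replacements drawn ∝ exp(BLOSUM62/2)),
  back-translated with uniformly random synonymous codons, and intergenic
  DNA fully randomized — so nucleotide divergence emerges from the
  amino-acid model.  The default panel (0.02, 0.17, 0.21, 0.26) spans the
  close-relative-to-distant-free-living range.
* **Host** (250 kb, GC 0.40) with one embedded host-rRNA gene; **mito**
  (15 kb, GC 0.20) sharing one gene family with the target at ~60%
  amino-acid identity (to exercise the mito filter); **host rRNA** built
  from a shared "SSU-rRNA-like core" at 30% nucleotide divergence; and an
  optional **contaminant** (1,550 nt) carrying the core at 8% divergence.
  Every reference carries its own copy of the core (divergence
  max(0.05, d/2)), so contaminant and host-rRNA contigs genuinely hit the
  reference in translated mode — the trap the decoy filters and the IMRA
  cutoff exist for.  The target itself carries no core; a construction
  audit verifies no ≥ 60-nt window of ≥ 95% identity between the target and
  any non-target genome (via shared-21-mer anchors).
* **Library**: target pairs = round(depth·L/(2·read_len)); total pairs =
  target pairs / purity; non-target mass split host:mito:rRNA:contaminant
  = 0.90:0.07:0.02:0.01 by default (a knob — real compositions are not
  derivable from purity alone).  Fragments are uniform with wraparound on
  the circular target; insert ~ Normal(230, 25) truncated to
  [read_len, 3·mean]; errors are i.i.d. substitutions at 0.002/base
  (indel-rate option present, default 0); a 2% tail of reads gets degraded
  qualities so the QC rules have work to do.  Same seed ⇒ byte-identical
  output.

What the simulator does *not* emulate: real Illumina error profiles and
quality ladders, PCR duplicates, chimeric fragments, adapter read-through,
repeat families beyond a single shared gene, and genome-scale base
composition heterogeneity.  Passing tests therefore demonstrate the
*logic* of the strategy — selection sensitivity versus divergence, decoy
filtering, recruit-reassemble convergence, cutoff-based contaminant
suppression — at a 50 kb scale, not performance on real tissue libraries.

## Problem sizes and defaults

Simulated studies use a 50 kb target with libraries of ~17.5 k pairs
(28.5% purity at 20×) up to ~208 k pairs (2.4% purity at 20×); these sizes
keep every experiment deterministic and fast on a single CPU while leaving
the read-accounting, depth and purity arithmetic identical to the
full-scale setting.  The depth threshold experiments use 18× (completes)
versus 6× (fragmented, non-converged).  Five fixed seeds are used wherever
a claim is "in ≥ 4 of 5 seeds".

## Known limitations

* E-values are approximations (fixed K-A constants, no length adjustment,
  no composition statistics); only threshold behavior is contractual.
* The mapper and overlap verifier are substitution-only; with a nonzero
  indel rate the assembler would need gapped verification (the option
  exists in the scenario but defaults to 0).
* Origin assignment relies on edit distance over ≥ 95% of a contig; a
  contig that is a 50/50 chimera of two genomes is labeled `unassigned`
  rather than split.
* NGA50 blocks split at the circular origin, so a single wrapping contig
  reports an NGA50 below the target length even at 100% genome fraction.
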