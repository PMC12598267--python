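# Methods

## The reconstruction model

`castatlas` reconstructs coding sequences of a target species (no genome
available) by anchoring on two closely related, annotated species. The
chain of assumptions is:

- **CDS-level conservation across the genus is high** (observed anchor
  pairwise identities in the high-90s), so a merged anchor consensus is a
  usable mapping reference for target-species reads.
- **Orthology can be established by reciprocal best hits** on translated
  proteins. RBH is a conservative ortholog proxy: a gene whose best hit
  is not reciprocated is left unpaired rather than mispaired, and genes
  annotated as several fragments in one species are detected as "split
  homologs" when two or more genes tile ≥ 80% of one partner with
  essentially non-overlapping best local hits.
- **Where the anchors disagree, the reference should not take sides.**
  Mismatch columns in the anchor consensus become two-base IUPAC
  ambiguity codes; the read mapper treats an ambiguity code as matching
  any base of its set, so the base actually called at such a site comes
  from the target reads, not from either anchor. Columns gapped in one
  anchor keep the base of the longer-CDS template and are recorded in an
  indel mask.
- **Base calling is evidence-gated, not maximum-likelihood.** A site is
  written as `N` (abstention) unless at least `min_depth = 2` reads
  contribute an actual base there and the majority base reaches
  `min_agreement = 0.65` of the column. The agreement boundary is
  *inclusive* (13 of 20 reads call the base): the per-column majority
  fraction is the only per-base reading of a "65% identity" calling
  threshold, and the inclusive boundary makes the stated fraction itself
  sufficient. Reads that delete the reference base do not count toward
  `min_depth` but do enter the agreement denominator, so deletion-riddled
  columns abstain.

## Mapping

References are gene-scale (≤ a few kb), so the mapper is deliberately
simple: exact k-mer seeding (default k = 15; ambiguity positions expanded
over their base sets, capped at 64 variants per window) serves only as a
cheap rejection filter, and every surviving read/strand is aligned
semi-globally over the whole gene by edit distance (edlib, ambiguity-aware).
The better strand wins; ties prefer the leftmost position, then the plus
strand. A placement is kept only if its identity (1 − edits/read length)
reaches `min_identity = 0.8`. On small references this is equivalent to a
full scan over every offset and strand, which the test suite asserts
against an independent dynamic-programming oracle.

Quality scores are parsed from FASTQ but ignored: calling is purely
count-based, so the pipeline's behaviour is fully determined by the read
sequences.

## Metrics and the variability flag

All reliability metrics are computed over the **annotated CDS columns**
of the reference (references may carry flanking sequence; reads in the
motivating data are genomic, so flanks both receive and donate
alignments, and restricting metrics to the CDS avoids edge artifacts):

- *mapping coverage* — % of CDS positions spanned by ≥ 1 read;
- *mapping identity* — % of covered columns whose mapped read bases are
  unanimous (reference base excluded; any second base or read-gap breaks
  unanimity);
- *depth* — mean ± SD of per-column read counts over covered positions
  (population SD).

A gene is flagged **variable** iff mapping identity or coverage is
strictly below `variability_cutoff = 85`. The flag's value is diagnostic:
a genotype lacking a region the consensus carries produces junction reads
that cannot be placed (their edit distance blows past the identity
floor), so the missing region stays uncovered and coverage drops —
presence/absence variation announces itself without any SV caller.

Reconstruction **accuracy vs truth** (used on synthetic data) is
agreement over alignment columns where a base was actually called, with
the called fraction reported separately; `N` positions are abstentions,
not errors. This mirrors judging a reconstruction by identity and
coverage as two separate numbers.

## Primer design

Constraints: primer length 19–23 nt, GC 40–80%, Tm 60 ± 3 °C, amplicon
300–850 bp preferring ~750, successive amplicons overlapping 100 ± 30 bp.
Tm uses the GC-content formula Tm = 64.9 + 41·(nGC − 16.4)/N — a fixed,
transparent choice adequate for ranking candidates within a narrow length
band (nearest-neighbour thermodynamics is out of scope). Candidate
primers are ranked by the mean per-column conservation of their annealing
window across the aligned anchor and target rows, ties by closeness of
the amplicon to 750 bp; windows containing ambiguity codes are excluded.
Tiling is greedy left-to-right: the tile count is the smallest n for
which n·750 − (n−1)·100 covers the CDS with slack, the first forward
primer must end by the CDS start, each subsequent forward primer is
constrained into the overlap band behind the previous reverse primer, and
the last reverse primer must clear the CDS end. Failure is structured
(the offending window is named), not silent. Self-complementarity is not
a hard constraint.

## SSR screening

Maximal perfect tandem repeats of primitive motifs (1–6 nt) with
per-motif-size minimum whole-copy lengths: mono/di ≥ 10 bp, tri ≥ 9 bp,
tetra–hexa ≥ 12 bp (common EST-SSR screening practice; configurable).
`N` breaks runs; non-primitive motifs are suppressed so a dinucleotide
run is not re-reported at period four. Motifs are canonicalised to their
lexicographically smallest rotation for cross-sequence matching.
Cross-sequence variability projects every detected locus through a global
alignment onto a reference sequence and counts motif copies at the
homologous position in each sequence directly (so a contraction below the
detection threshold still yields its true, smaller count rather than a
spurious absence); a locus is variable iff any two copy counts differ.

## Conservation calls and interval arithmetic

Pairwise CDS identity (global alignment; gaps count as mismatches)
against haplotype reference CDS is classified conserved/divergent at 90%,
**boundary inclusive** — "at least 90%" is the reading that keeps the
threshold itself meaningful. Interval spans are end − start + 1 on
1-based inclusive coordinates, reported in bp and Mb rounded to one
decimal; haplotype size differences are plain absolute differences.

## The synthetic generator

`simulate.make_family` emulates the study system per gene: a random
ancestral locus (ORF of 300 codons between 150 bp flanks, uniform base
composition), one substitution/indel branch to each anchor
(`sub_rate = 0.01` per branch → ≈ 2% pairwise anchor divergence, matching
the observed high-90s identities), one branch to the target lineage, then
a split into two haplotypes at `het_rate = 0.002` (within-individual
heterozygosity, an order of magnitude below species divergence). Reads:
Poisson count at `depth = 15` mean coverage, 100 nt, per-base substitution
errors at `error_rate = 0.005`, haplotype/strand/start uniform, true
origin recorded.

Modelling choices and what they imply:

- Substitutions are uniform over the three alternatives (no
  transition/transversion bias) — sufficient for the recovery properties;
  a bias hook can be added without changing interfaces.
- The CDS is kept translatable by construction: start/stop codons are
  protected, substitutions never create an in-frame stop, CDS indels are
  codon-aligned with length 3 × Geometric(0.5). This is a strong
  purifying-selection assumption, appropriate for conserved candidate
  genes and required for protein-level RBH to be well-defined on every
  simulated gene.
- Mutation logs are complete: replaying a branch's log on the ancestor
  reproduces the descendant byte-for-byte, which the tests use as an
  exact inverse check.
- Structural-variant genes (by default the last two of a family set) are
  applied to **both** target haplotypes — the sequenced genotype lacks
  what the anchors carry: a planted 240 bp repeat block deleted from the
  target ("repeat_deletion"), or a ~⅓-of-CDS region deleted
  ("region_loss"). A deletion present in only one haplotype of a diploid
  would leave the region covered at half depth and would *not* drop
  mapping coverage; the coverage-drop signature requires the sequenced
  individual to lack the region, and that is what the generator models.
  Haplotype presence/absence of the *reference assembly* kind is handled
  downstream as interval arithmetic and conservation calls, not read
  simulation.

What the simulator does **not** model — hence what passing tests do not
show about real data: sequencing-quality profiles and indel read errors,
paired-end structure, non-uniform coverage (GC bias, mappability),
paralogy and repeat families beyond the planted SSR blocks, alternative
splicing/annotation error in the anchors, and contamination. The
parameter-recovery results bound behaviour under the modelled regime
only.

## Problem sizes and determinism

Default test and acceptance runs use 20 families of ~900 bp CDS at depth
15 — roughly the scale of the motivating 26-gene atlas — and complete in
seconds. Every stochastic step draws from a seeded NumPy generator; a
fixed seed makes simulation, mapping and the whole pipeline byte-stable
(reruns produce identical output files). With the default per-branch
indel rate (5 × 10⁻⁴/site), an occasional simulated gene draws several
CDS indels and its mapping identity can dip toward the 85% cutoff; such
a flag is a genuine detection of indel-rich divergence, not a calling
artifact.

## Degenerate inputs and tie-breaks

Empty FASTA → empty list with a warning; duplicate FASTA ids → error.
Zero covered positions → coverage 0 and identity reported 0 with a
warning. Tied majority bases → `N`. Alignment tracebacks use the
aligner's deterministic ordering; placement ties prefer leftmost, then
plus strand. Genes without a reciprocal ortholog are reported unpaired
and skipped, never fatal; per-gene primer-design failures are collected
in the run manifest.
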