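"""Short-read mapping onto per-gene consensus references.

Reads are seeded by exact k-mer lookup (ambiguity codes in the reference
are expanded over their base sets) and placed by semi-global edit-distance
alignment of the read against the reference, both strands tried.  Base
calling is purely count-based: a site needs at least ``min_depth``
informative reads and a majority base reaching ``min_agreement`` of the
column, else it is written as ``N``.  A gene whose mapping identity or
coverage falls strictly below the variability cutoff (default 85%) is
flagged as substantially variable — the pipeline's signal for alleles or
structural variants that diverge from the anchor consensus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence, Union

import edlib

from .homology import ConsensusSequence, IUPAC_BASES
from .seqio import ShortRead

__all__ = [
    "CallThresholds",
    "ReadPlacement",
    "PileupColumn",
    "ReconstructionResult",
    "SeedIndex",
    "index_reference",
    "map_read",
    "build_pileup",
    "call_base",
    "mapping_metrics",
    "reconstruct_cds",
    "flag_variability",
]

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# read/reference equivalences for ambiguity-aware alignment
_EQUALITIES = tuple(
    (code, base)
    for code, bases in IUPAC_BASES.items()
    if len(bases) > 1
    for base in bases
)


@dataclass
class CallThresholds:
    """Base-calling and variability thresholds.

    ``min_depth``: informative (non-gap) reads required at a site, else N.
    ``min_agreement``: majority-base fraction of the column required to
    call, boundary inclusive (0.65 means 13 of 20 suffices).
    ``variability_cutoff``: percent; a gene with mapping identity or
    coverage strictly below it is flagged variable.
    """

    min_depth: int = 2
    min_agreement: float = 0.65
    variability_cutoff: float = 85.0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 < self.min_agreement <= 1):
            raise ValueError("min_agreement must be in (0, 1]")


@dataclass
class ReadPlacement:
    """A read's placement on a reference.

    ``aligned_pairs`` holds ``(read_offset, ref_pos)`` tuples where either
    side may be ``None`` for a gap; read offsets are 0-based on the
    oriented read (``oriented_seq``), reference positions 1-based.
    """

    read_id: str
    ref_id: str
    ref_start: int
    strand: str
    aligned_pairs: list[tuple[Optional[int], Optional[int]]]
    edit_distance: int
    oriented_seq: str

    def __post_init__(self) -> None:
        last = 0
        for _, rp in self.aligned_pairs:
            if rp is not None:
                if rp <= last:
                    raise ValueError("reference positions must strictly increase")
                last = rp
        if self.ref_start < 1:
            raise ValueError("ref_start must be >= 1")


@dataclass
class PileupColumn:
    ref_pos: int
    base_counts: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in "ACGTN-"}
    )

    @property
    def depth(self) -> int:
        """Reads spanning this column (including those deleting the base)."""
        return sum(self.base_counts.values())

    @property
    def informative_depth(self) -> int:
        """Reads contributing an actual base at this column."""
        return self.depth - self.base_counts.get("-", 0)


@dataclass
class ReconstructionResult:
    """Called sequence plus mapping reliability metrics for one gene.

    ``called_seq`` spans the whole consensus; metrics (identity, coverage,
    depth) are computed over the annotated CDS columns only, and
    ``called_cds`` slices the call down to them."""

    gene_id: str
    called_seq: str
    mapping_identity_pct: float
    mapping_coverage_pct: float
    mean_depth: float
    sd_depth: float
    variable: bool
    cds_interval: tuple[int, int] = (0, 0)
    n_mapped: int = 0
    pileup: Optional[list[PileupColumn]] = None

    @property
    def called_cds(self) -> str:
        s, e = self.cds_interval
        return self.called_seq[s - 1 : e]


class SeedIndex:
    """Exact k-mer → 1-based position lookup over one reference sequence.

    Reference ambiguity codes are expanded over their base sets, capped at
    ``max_expansion`` variants per k-mer window (windows denser in
    ambiguity than that are simply not seeded; the extension alignment
    still matches them)."""

    def __init__(self, ref_id: str, seq: str, k: int = 15, max_expansion: int = 64):
        if k < 4:
            raise ValueError("k must be >= 4")
        if len(seq) < k:
            raise ValueError(f"reference {ref_id} shorter than k={k}")
        self.ref_id = ref_id
        self.seq = seq.upper()
        self.k = k
        self.lookup: dict[str, list[int]] = {}
        for i in range(len(self.seq) - k + 1):
            window = self.seq[i : i + k]
            choices = [IUPAC_BASES.get(c, c) for c in window]
            n_var = 1
            for ch in choices:
                n_var *= len(ch)
                if n_var > max_expansion:
                    break
            if n_var > max_expansion:
                continue
            for variant in product(*choices):
                self.lookup.setdefault("".join(variant), []).append(i + 1)

    def positions(self, kmer: str) -> list[int]:
        return self.lookup.get(kmer, [])


def index_reference(
    ref: Union[ConsensusSequence, str], k: int = 15, ref_id: str = "ref",
    max_expansion: int = 64,
) -> SeedIndex:
    if isinstance(ref, ConsensusSequence):
        return SeedIndex(ref.gene_id, ref.seq, k=k, max_expansion=max_expansion)
    return SeedIndex(ref_id, ref, k=k, max_expansion=max_expansion)


def _has_seed(seq: str, index: SeedIndex) -> bool:
    k = index.k
    step = max(1, k // 2)
    offsets = list(range(0, len(seq) - k + 1, step))
    if offsets and offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)
    return any(index.positions(seq[i : i + k]) for i in offsets)


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _align_oriented(seq: str, index: SeedIndex):
    """Best semi-global placement of an oriented read over the whole
    reference; returns (edit_distance, 0-based start, cigar) or None."""
    res = edlib.align(
        seq, index.seq, mode="HW", task="path",
        additionalEqualities=list(_EQUALITIES),
    )
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    # leftmost co-optimal location
    loc = min(res["locations"], key=lambda l: (l[0] if l[0] is not None else 0))
    start = loc[0] if loc[0] is not None else 0
    return res["editDistance"], start, res["cigar"]


def map_read(
    read: ShortRead,
    index: SeedIndex,
    min_identity: float = 0.8,
) -> Optional[ReadPlacement]:
    """Place a read on the indexed reference, or return None (unmapped).

    A strand is attempted only if it shares at least one exact k-mer with
    the reference (cheap rejection); the surviving candidates are aligned
    semi-globally over the gene with ambiguity-aware edit distance.  The
    better strand wins; ties prefer the leftmost position, then the plus
    strand.  The placement is kept only if its aligned identity
    (1 − edits/read length) reaches ``min_identity``.
    """
    candidates = []
    for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
        if len(seq) < index.k or not _has_seed(seq, index):
            continue
        hit = _align_oriented(seq, index)
        if hit is None:
            continue
        dist, start, cigar = hit
        candidates.append((dist, start, 0 if strand == "+" else 1, strand, seq, cigar))
    if not candidates:
        return None
    dist, start, _, strand, oriented, cigar = min(candidates)
    if 1.0 - dist / len(read.seq) < min_identity:
        return None
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    r_off, ref_pos = 0, start + 1
    for n, op in _parse_cigar(cigar):
        if op in ("=", "X", "M"):
            for _ in range(n):
                pairs.append((r_off, ref_pos))
                r_off += 1
                ref_pos += 1
        elif op == "I":  # read base absent from reference
            for _ in range(n):
                pairs.append((r_off, None))
                r_off += 1
        elif op == "D":  # reference base deleted in read
            for _ in range(n):
                pairs.append((None, ref_pos))
                ref_pos += 1
        else:  # pragma: no cover
            raise ValueError(f"unexpected cigar op {op!r}")
    return ReadPlacement(
        read_id=read.read_id,
        ref_id=index.ref_id,
        ref_start=start + 1,
        strand=strand,
        aligned_pairs=pairs,
        edit_distance=dist,
        oriented_seq=oriented,
    )


def build_pileup(
    placements: Iterable[ReadPlacement], ref: Union[ConsensusSequence, str]
) -> list[PileupColumn]:
    """One column per reference position.  A read's deletion of a
    reference base is tallied under ``-``; read insertions (bases with no
    reference position) contribute to no column."""
    ref_seq = ref.seq if isinstance(ref, ConsensusSequence) else ref
    columns = [PileupColumn(ref_pos=i + 1) for i in range(len(ref_seq))]
    for pl in placements:
        for r_off, ref_pos in pl.aligned_pairs:
            if ref_pos is None:
                continue
            if r_off is None:
                columns[ref_pos - 1].base_counts["-"] += 1
            else:
                base = pl.oriented_seq[r_off]
                if base not in "ACGTN":
                    base = "N"
                columns[ref_pos - 1].base_counts[base] += 1
    return columns


def call_base(col: PileupColumn, t: CallThresholds) -> str:
    """Count-based consensus call for one pileup column.

    Reads deleting the base do not count toward ``min_depth`` but they do
    enter the agreement denominator, so a deletion-riddled column cannot
    be called confidently.  The majority-fraction boundary is inclusive
    (exactly 65% of 20 reads calls the base)."""
    if col.informative_depth < t.min_depth:
        return "N"
    counts = {b: col.base_counts.get(b, 0) for b in "ACGT"}
    top = max(counts.values())
    if top == 0:
        return "N"
    winners = [b for b, c in counts.items() if c == top]
    f = top / col.depth
    if len(winners) == 1 and f >= t.min_agreement:
        return winners[0]
    return "N"


def mapping_metrics(
    pileup: Sequence[PileupColumn],
) -> tuple[float, float, float, float]:
    """(identity %, coverage %, mean depth, sd depth) over the pileup.

    Coverage: reference positions spanned by ≥1 read.  Identity: fraction
    of covered columns whose mapped read bases are unanimous (reference
    base excluded; any gap or second base breaks unanimity).  Depth
    moments are over covered positions only.
    """
    covered = [c for c in pileup if c.depth >= 1]
    n_ref = len(pileup)
    if n_ref == 0:
        raise ValueError("empty pileup")
    coverage = 100.0 * len(covered) / n_ref
    if not covered:
        warnings.warn("no covered positions; identity reported as 0", stacklevel=2)
        return 0.0, 0.0, 0.0, 0.0
    unanimous = 0
    for c in covered:
        bases_present = [b for b in "ACGTN" if c.base_counts.get(b, 0) > 0]
        if (
            len(bases_present) == 1
            and c.base_counts.get("-", 0) == 0
        ):
            unanimous += 1
    identity = 100.0 * unanimous / len(covered)
    depths = [c.depth for c in covered]
    mean_depth = sum(depths) / len(depths)
    var = sum((d - mean_depth) ** 2 for d in depths) / len(depths)
    return identity, coverage, mean_depth, math.sqrt(var)


def flag_variability(
    identity_pct: float, coverage_pct: float, cutoff: float = 85.0
) -> bool:
    """True iff mapping identity or coverage is strictly below the cutoff."""
    return identity_pct < cutoff or coverage_pct < cutoff


def reconstruct_cds(
    consensus: ConsensusSequence,
    reads: Iterable[ShortRead],
    thresholds: Optional[CallThresholds] = None,
    k: int = 15,
    min_identity: float = 0.8,
) -> ReconstructionResult:
    """Full per-gene reconstruction: index → map → pileup → call → metrics."""
    t = thresholds or CallThresholds()
    index = index_reference(consensus, k=k)
    placements = []
    for read in reads:
        pl = map_read(read, index, min_identity=min_identity)
        if pl is not None:
            placements.append(pl)
    pileup = build_pileup(placements, consensus)
    called = "".join(call_base(col, t) for col in pileup)
    s, e = consensus.cds_interval
    identity, coverage, mean_depth, sd_depth = mapping_metrics(pileup[s - 1 : e])
    return ReconstructionResult(
        gene_id=consensus.gene_id,
        called_seq=called,
        mapping_identity_pct=identity,
        mapping_coverage_pct=coverage,
        mean_depth=mean_depth,
        sd_depth=sd_depth,
        variable=flag_variability(identity, coverage, t.variability_cutoff),
        cds_interval=(s, e),
        n_mapped=len(placements),
        pileup=pileup,
    )
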