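"""Anchor-species homology: pairing, conservation metrics, consensus.

Candidate genes are anchored on two closely related species with annotated
genomes.  Orthologs are paired by reciprocal best hits (RBH) on translated
proteins, CDS conservation is quantified from a global nucleotide
alignment, and each pair is merged into a consensus that serves as the
mapping reference for short-read reconstruction.

Protein comparison uses local alignment with BLOSUM62; the nucleotide
consensus uses global alignment.  Disagreeing columns become IUPAC
ambiguity codes so the read mapper is not biased toward either anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GeneRecord, translate_cds

__all__ = [
    "PairwiseAlignment",
    "HomologPair",
    "ConsensusSequence",
    "align_pair",
    "alignment_identity",
    "pair_coverage",
    "reciprocal_best_hits",
    "build_consensus",
    "write_consensus",
]

# two-base IUPAC ambiguity codes
AMBIGUITY = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PairwiseAlignment:
    """A pairwise alignment as two equal-length gapped strings."""

    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    mode: str = "global"
    # 1-based inclusive footprint of the alignment on each input sequence
    a_span: tuple[int, int] = (0, 0)
    b_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped rows differ in length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" and cb == "-":
                raise ValueError("column gapped in both rows")

    def __len__(self) -> int:
        return len(self.aligned_a)


@dataclass
class HomologPair:
    """Two anchor-species genes paired as orthologs, with CDS conservation."""

    gene_id: str
    anchor1: GeneRecord
    anchor2: GeneRecord
    identity_pct: float
    coverage_pct: float
    split_homolog: bool = False
    alignment: Optional[PairwiseAlignment] = None


@dataclass
class ConsensusSequence:
    """Per-gene merge of the two anchors' CDS alignment.

    ``seq`` is over {A,C,G,T} plus IUPAC ambiguity codes at mismatch
    columns.  ``indel_mask[i]`` is True where the column was gapped in the
    non-template anchor (the template base is retained).  ``cds_interval``
    (1-based inclusive, template coordinates) marks the annotated CDS;
    mapping metrics downstream are restricted to it.
    """

    gene_id: str
    seq: str
    indel_mask: list[bool] = field(default_factory=list)
    cds_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.indel_mask:
            self.indel_mask = [False] * len(self.seq)
        if len(self.indel_mask) != len(self.seq):
            raise ValueError("indel_mask length mismatch")
        if self.cds_interval is None:
            self.cds_interval = (1, len(self.seq))
        s, e = self.cds_interval
        if not (1 <= s <= e <= len(self.seq)):
            raise ValueError("cds_interval outside consensus")

    @property
    def cds(self) -> str:
        s, e = self.cds_interval
        return self.seq[s - 1 : e]

    def __len__(self) -> int:
        return len(self.seq)


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _spans(alignment) -> tuple[tuple[int, int], tuple[int, int]]:
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return (0, 0), (0, 0)
    a_span = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    return a_span, b_span


def align_pair(
    a: GeneRecord,
    b: GeneRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -2.0,
    mode: str = "global",
) -> PairwiseAlignment:
    """Optimal pairwise alignment of two gene sequences.

    Dynamic programming via Biopython's ``PairwiseAligner``; among co-optimal
    alignments the first in the aligner's deterministic traceback order is
    returned, so output is reproducible.
    """
    if not a.seq or not b.seq:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, mode)
    result = aligner.align(a.seq, b.seq)
    best = result[0]
    # biopython's alignment[i] indexing yields the gapped rows
    row_a, row_b = best[0], best[1]
    a_span, b_span = _spans(best)
    return PairwiseAlignment(
        seq_a_id=a.gene_id,
        seq_b_id=b.gene_id,
        aligned_a=str(row_a),
        aligned_b=str(row_b),
        score=float(best.score),
        mode=mode,
        a_span=a_span,
        b_span=b_span,
    )


def alignment_identity(aln: PairwiseAlignment) -> float:
    """Percent of alignment columns where the two rows carry the same
    residue.  Gap columns count as non-identical."""
    n = len(aln)
    if n == 0:
        raise ValueError("zero-length alignment")
    same = sum(
        1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b)
        if ca == cb and ca != "-"
    )
    return 100.0 * same / n


def pair_coverage(a: GeneRecord, b: GeneRecord, aln: PairwiseAlignment) -> float:
    """Proportion of the larger sequence covered by the smaller one.

    Counted as alignment columns where both rows carry a residue, as a
    percentage of the longer input's length — symmetric in ``a`` and ``b``.
    """
    paired = sum(
        1
        for ca, cb in zip(aln.aligned_a, aln.aligned_b)
        if ca != "-" and cb != "-"
    )
    return 100.0 * paired / max(len(a.seq), len(b.seq))


def _protein_aligner(gap_open: float = -11.0, gap_extend: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _best_hits(queries: dict[str, str], targets: dict[str, str], aligner):
    """For each query protein: (best target id, score, footprints) plus the
    per-target footprint list used for split-homolog detection."""
    best: dict[str, tuple[Optional[str], float]] = {}
    # footprints[t] = list of (query id, span on t, span fraction of query)
    footprints: dict[str, list[tuple[str, tuple[int, int], float]]] = {
        t: [] for t in targets
    }
    for qid, qseq in queries.items():
        top_id, top_score = None, float("-inf")
        top_span_t = (0, 0)
        for tid, tseq in targets.items():
            alns = aligner.align(qseq, tseq)
            score = float(alns.score)
            if score > top_score:
                best_aln = alns[0]
                q_span, t_span = _spans(best_aln)
                top_id, top_score, top_span_t = tid, score, t_span
        best[qid] = (top_id, top_score)
        if top_id is not None:
            footprints[top_id].append((qid, top_span_t, 0.0))
    return best, footprints


def _tiles(spans: list[tuple[int, int]], target_len: int,
           min_fraction: float = 0.8) -> bool:
    """True if the spans are mutually (almost) non-overlapping and jointly
    cover at least ``min_fraction`` of the target."""
    spans = sorted(spans)
    covered = 0
    prev_end = 0
    for start, end in spans:
        overlap = max(0, prev_end - start + 1)
        if end - start + 1 > 0 and overlap > 0.2 * (end - start + 1):
            return False
        covered += max(0, end - max(start, prev_end + 1) + 1)
        prev_end = max(prev_end, end)
    return covered >= min_fraction * target_len


def reciprocal_best_hits(
    set_a: Sequence[GeneRecord],
    set_b: Sequence[GeneRecord],
    score_floor: float = 50.0,
    nuc_scoring: Optional[dict] = None,
) -> list[HomologPair]:
    """Pair orthologs between two anchor gene sets by reciprocal best hits.

    Proteins (translated CDS) are compared by local BLOSUM62 alignment; a
    pair is kept iff each gene is the other's best-scoring hit and the
    score clears ``score_floor``.  Genes whose best hit falls below the
    floor, or that lose the reciprocity check, are left unpaired (the
    caller can detect them by set difference).

    ``split_homolog`` is set when two or more genes of one set place their
    best local hits as non-overlapping tiles covering ≥80% of the partner
    gene — the signature of one gene annotated as several fragments in the
    other species.

    CDS identity/coverage of each retained pair come from a global
    nucleotide alignment (:func:`align_pair` defaults unless
    ``nuc_scoring`` overrides them).
    """
    if not set_a or not set_b:
        raise ValueError("both anchor gene sets must be non-empty")
    prots_a = {g.gene_id: translate_cds(g) for g in set_a}
    prots_b = {g.gene_id: translate_cds(g) for g in set_b}
    by_id_a = {g.gene_id: g for g in set_a}
    by_id_b = {g.gene_id: g for g in set_b}

    aligner = _protein_aligner()
    best_ab, foot_on_b = _best_hits(prots_a, prots_b, aligner)
    best_ba, foot_on_a = _best_hits(prots_b, prots_a, aligner)

    nuc_scoring = nuc_scoring or {}
    pairs: list[HomologPair] = []
    for aid, (bid, score) in best_ab.items():
        if bid is None or score < score_floor:
            continue
        back_id, back_score = best_ba[bid]
        if back_id != aid or back_score < score_floor:
            continue
        a, b = by_id_a[aid], by_id_b[bid]
        aln = align_pair(a, b, mode="global", **nuc_scoring)
        split = False
        hitters_on_b = [f for f in foot_on_b.get(bid, [])]
        if len(hitters_on_b) >= 2:
            split = _tiles([s for _, s, _ in hitters_on_b], len(prots_b[bid]))
        hitters_on_a = [f for f in foot_on_a.get(aid, [])]
        if not split and len(hitters_on_a) >= 2:
            split = _tiles([s for _, s, _ in hitters_on_a], len(prots_a[aid]))
        pairs.append(
            HomologPair(
                gene_id=aid,
                anchor1=a,
                anchor2=b,
                identity_pct=alignment_identity(aln),
                coverage_pct=pair_coverage(a, b, aln),
                split_homolog=split,
                alignment=aln,
            )
        )
    return pairs


def build_consensus(
    aln: PairwiseAlignment,
    template_choice: str = "longer",
    cds_interval: Optional[tuple[int, int]] = None,
) -> ConsensusSequence:
    """Merge a global CDS alignment of the two anchors into one reference.

    Per column: agreement keeps the base; mismatch becomes the two-base
    IUPAC ambiguity code; a gap in the non-template row keeps the template
    base and sets the indel mask; columns gapped in the template are
    dropped, so the consensus has the template's ungapped length.

    ``template_choice``: ``"a"``, ``"b"`` or ``"longer"`` (default — the
    anchor with the longer annotated CDS, matching the convention of
    designing on the longer annotation).  ``cds_interval`` is the CDS in
    template coordinates and is carried onto the consensus unchanged
    (consensus positions are exactly the template's ungapped positions).
    """
    if aln.mode != "global":
        raise ValueError("consensus requires a global alignment")
    len_a = sum(1 for c in aln.aligned_a if c != "-")
    len_b = sum(1 for c in aln.aligned_b if c != "-")
    if template_choice == "longer":
        template_choice = "a" if len_a >= len_b else "b"
    if template_choice not in ("a", "b"):
        raise ValueError("template_choice must be 'a', 'b' or 'longer'")
    tmpl, other = (
        (aln.aligned_a, aln.aligned_b)
        if template_choice == "a"
        else (aln.aligned_b, aln.aligned_a)
    )
    out: list[str] = []
    mask: list[bool] = []
    for ct, co in zip(tmpl, other):
        if ct == "-":
            continue  # template gapped: column dropped
        if co == "-":
            out.append(ct)
            mask.append(True)
        elif ct == co:
            out.append(ct)
            mask.append(False)
        else:
            code = AMBIGUITY.get(frozenset((ct, co)))
            if code is None:  # one side N or alike: fall back to template
                code = ct
            out.append(code)
            mask.append(False)
    return ConsensusSequence(
        gene_id=f"{aln.seq_a_id}|{aln.seq_b_id}",
        seq="".join(out),
        indel_mask=mask,
        cds_interval=cds_interval,
    )


def write_consensus(
    consensi: Iterable[ConsensusSequence], fasta_path, mask_path
) -> None:
    """Write consensus sequences as FASTA plus a BED-like TSV of the
    anchor-indel mask (1-based inclusive intervals)."""
    fasta_path, mask_path = Path(fasta_path), Path(mask_path)
    with fasta_path.open("w") as fa, mask_path.open("w") as bed:
        bed.write("gene_id\tstart\tend\tlabel\n")
        for cons in consensi:
            fa.write(f">{cons.gene_id}\n")
            for i in range(0, len(cons.seq), 70):
                fa.write(cons.seq[i : i + 70] + "\n")
            start = None
            for i, flag in enumerate(cons.indel_mask + [False]):
                if flag and start is None:
                    start = i + 1
                elif not flag and start is not None:
                    bed.write(f"{cons.gene_id}\t{start}\t{i}\tanchor_indel\n")
                    start = None
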