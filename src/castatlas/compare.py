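"""Cross-methodology comparison and atlas-level summaries.

Gathers the per-gene numbers the pipeline produces (anchor-alignment
identity/coverage, mapping identity/coverage, read depth) into an atlas
summary, classifies CDS conservation against haplotype references at the
90% pairwise-identity threshold, filters candidates by functional
category, and does the interval arithmetic for haplotype structural
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .homology import align_pair, alignment_identity
from .mapping import flag_variability
from .seqio import AnnotationRow, GeneRecord

__all__ = [
    "GeneMetricsRow",
    "AtlasSummary",
    "GenomicInterval",
    "CandidateSelection",
    "select_candidates",
    "cds_pairwise_identity",
    "call_accuracy",
    "conservation_call",
    "interval_span",
    "size_difference",
    "summarize_atlas",
]


@dataclass
class GeneMetricsRow:
    """One gene's metric row; anchor-alignment columns are ``None`` for
    genes found in a single anchor species."""

    gene_id: str
    align_identity: Optional[float] = None
    align_coverage: Optional[float] = None
    map_identity: float = 0.0
    map_coverage: float = 0.0
    depth_mean: float = 0.0
    depth_sd: float = 0.0


@dataclass
class AtlasSummary:
    n_genes: int
    means: dict[str, Optional[float]]
    mins: dict[str, Optional[float]]
    maxs: dict[str, Optional[float]]
    n_variable: int
    variable_ids: list[str]
    depth_sd_across_genes: Optional[float] = None


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("need 1 <= start <= end")


@dataclass
class CandidateSelection:
    selected: list[str]
    n_tf: int
    n_signal: int
    n_response: int


def select_candidates(rows: Sequence[AnnotationRow]) -> CandidateSelection:
    """Keep genes annotated to any of the four drought-relevant
    categories and count them the way the atlas reports them:
    transcription factors first, then signal transduction, then the
    remaining stress/stimulus-response genes."""
    selected, n_tf, n_signal, n_response = [], 0, 0, 0
    for r in rows:
        if not r.any_flag:
            continue
        selected.append(r.gene_id)
        if r.is_tf:
            n_tf += 1
        elif r.is_signal:
            n_signal += 1
        else:
            n_response += 1
    return CandidateSelection(selected, n_tf, n_signal, n_response)


def cds_pairwise_identity(seqs: Sequence[tuple[str, str]]) -> "np.ndarray":
    """Symmetric matrix of global-alignment identities (%) between CDS
    sequences given as ``(id, sequence)`` pairs; diagonal is 100."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_pair(
                GeneRecord(seqs[i][0] or "a", seqs[i][1]),
                GeneRecord(seqs[j][0] or "b", seqs[j][1]),
                mode="global",
            )
            mat[i, j] = mat[j, i] = alignment_identity(aln)
    return mat


def call_accuracy(called: str, truth: str) -> tuple[float, float]:
    """(accuracy %, called fraction %) of a reconstructed CDS vs truth.

    Accuracy is agreement over alignment columns where a base was
    actually called (N positions are abstentions, reported separately via
    the called fraction), which is the question the reconstruction is
    judged on: of the bases written, how many are right."""
    aln = align_pair(GeneRecord("called", called), GeneRecord("truth", truth),
                     mode="global")
    called_cols = agree = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca in "ACGT":
            called_cols += 1
            if ca == cb:
                agree += 1
    n_total = sum(1 for c in called if c != "-")
    frac = 100.0 * called_cols / max(1, n_total)
    if called_cols == 0:
        return 0.0, 0.0
    return 100.0 * agree / called_cols, frac


def conservation_call(identity_pct: float, threshold: float = 90.0) -> str:
    """``"conserved"`` iff pairwise identity ≥ threshold (boundary
    inclusive), else ``"divergent"``."""
    if not (0 <= identity_pct <= 100):
        raise ValueError("identity must be a percentage")
    return "conserved" if identity_pct >= threshold else "divergent"


def interval_span(iv: GenomicInterval) -> tuple[int, float]:
    """(bp, Mb to 1 decimal) of a 1-based inclusive interval."""
    bp = iv.end - iv.start + 1
    return bp, round(bp / 1_000_000, 1)


def size_difference(a_mb: float, b_mb: float) -> float:
    if a_mb < 0 or b_mb < 0:
        raise ValueError("sizes must be non-negative")
    return abs(a_mb - b_mb)


_COLUMNS = ("align_identity", "align_coverage", "map_identity",
            "map_coverage", "depth_mean")


def summarize_atlas(
    rows: Sequence[GeneMetricsRow], cutoff: float = 85.0
) -> AtlasSummary:
    """Column-wise unweighted mean/min/max over per-gene rows.

    Absent values (single-anchor genes) are excluded column-wise; the
    depth mean is the unweighted mean of per-gene depth means.  Variable
    genes are those whose mapping identity or coverage falls strictly
    below ``cutoff``.  The across-gene depth SD is reported for context
    only — it is the SD of per-gene means, not a pooled per-site SD.
    """
    if not rows:
        raise ValueError("no rows to summarize")
    means: dict[str, Optional[float]] = {}
    mins: dict[str, Optional[float]] = {}
    maxs: dict[str, Optional[float]] = {}
    for col in _COLUMNS:
        vals = [getattr(r, col) for r in rows if getattr(r, col) is not None]
        if vals:
            means[col] = float(np.mean(vals))
            mins[col] = float(min(vals))
            maxs[col] = float(max(vals))
        else:
            means[col] = mins[col] = maxs[col] = None
    variable_ids = [
        r.gene_id for r in rows
        if flag_variability(r.map_identity, r.map_coverage, cutoff)
    ]
    depths = [r.depth_mean for r in rows if r.depth_mean is not None]
    sd = float(np.std(depths)) if len(depths) > 1 else None
    return AtlasSummary(
        n_genes=len(rows),
        means=means,
        mins=mins,
        maxs=maxs,
        n_variable=len(variable_ids),
        variable_ids=variable_ids,
        depth_sd_across_genes=sd,
    )
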