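"""Primer tiling for Sanger validation and EST-SSR screening.

Primer pairs are designed to amplify each CDS in overlapping tiles that a
single Sanger read can traverse: amplicons of 300–850 bp (preferably near
750), primers of 19–23 nt, GC 40–80%, Tm 60 ± 3 °C by the GC-content
formula, successive amplicons overlapping by about 100 bp.  Candidate
primers are ranked by how conserved their window is across the aligned
species, since primers must anneal in all genotypes being screened.

Microsatellites (SSRs) are maximal perfect tandem repeats of 1–6 nt
motifs; loci whose copy number differs between homologous CDS copies are
candidate length-polymorphic markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .homology import IUPAC_BASES

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "PrimerDesignError",
    "SSRLocus",
    "gc_percent",
    "melting_temp",
    "conservation_track",
    "design_primers",
    "predicted_amplicon_size",
    "find_ssrs",
    "ssr_variability",
    "canonical_motif",
]

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

DEFAULT_SSR_MINIMA = {1: 10, 2: 10, 3: 9, 4: 12, 5: 12, 6: 12}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PrimerConstraints:
    min_len: int = 19
    max_len: int = 23
    min_gc: float = 40.0
    max_gc: float = 80.0
    tm_target: float = 60.0
    tm_tolerance: float = 3.0
    min_amplicon: int = 300
    max_amplicon: int = 850
    preferred_amplicon: int = 750
    overlap: int = 100
    overlap_tolerance: int = 30


@dataclass
class PrimerPair:
    """One amplicon's primer pair; ``rev_seq`` is the minus-strand primer
    (reverse complement of the template at its site).  Positions are
    1-based on the template; ``amplicon_len = rev_end - fwd_start + 1``."""

    pair_id: str
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    amplicon_len: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float

    def satisfies(self, c: Optional[PrimerConstraints] = None) -> bool:
        c = c or PrimerConstraints()
        for seq, tm, gc in (
            (self.fwd_seq, self.fwd_tm, self.fwd_gc),
            (self.rev_seq, self.rev_tm, self.rev_gc),
        ):
            if not (c.min_len <= len(seq) <= c.max_len):
                return False
            if not (c.min_gc <= gc <= c.max_gc):
                return False
            if abs(tm - c.tm_target) > c.tm_tolerance:
                return False
        return c.min_amplicon <= self.amplicon_len <= c.max_amplicon


class PrimerDesignError(RuntimeError):
    """No constraint-satisfying primer in a required window."""

    def __init__(self, message: str, window: tuple[int, int]):
        super().__init__(f"{message} (window {window[0]}–{window[1]})")
        self.window = window


@dataclass
class SSRLocus:
    """A maximal perfect tandem repeat.  ``motif`` is the canonical
    (lexicographically smallest) rotation; ``length = copies × |motif|``
    counts whole copies only."""

    seq_id: str
    cds_pos: int
    motif: str
    copies: int
    length: int

    def __post_init__(self) -> None:
        if self.copies * len(self.motif) != self.length:
            raise ValueError("length must equal copies × motif size")


def gc_percent(seq: str) -> float:
    """Percent G+C of a sequence (S counts as G/C; other ambiguity codes
    are excluded from the numerator, never the denominator)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = sum(1 for c in seq if c in "GCS")
    return 100.0 * gc / len(seq)


def melting_temp(seq: str) -> float:
    """GC-content melting temperature: Tm = 64.9 + 41·(nGC − 16.4)/N.

    The classic salt-adjusted GC formula for oligos; adequate for ranking
    primers inside a narrow length band, which is all it is used for here.
    """
    if len(seq) < 14:
        raise ValueError("Tm formula needs at least 14 nt")
    n_gc = sum(1 for c in seq.upper() if c in "GCS")
    return 64.9 + 41.0 * (n_gc - 16.4) / len(seq)


def conservation_track(rows: Sequence[str]) -> list[float]:
    """Per-column agreement across equal-length aligned rows: the fraction
    of sequences carrying the modal character (gaps count as their own
    character, so an indel lowers conservation)."""
    if not rows:
        raise ValueError("no rows")
    n = len(rows[0])
    if any(len(r) != n for r in rows):
        raise ValueError("rows must be equal length")
    track = []
    for i in range(n):
        col = [r[i] for r in rows]
        top = max(col.count(c) for c in set(col))
        track.append(top / len(col))
    return track


def _window_score(conservation: Optional[Sequence[float]], start0: int,
                  length: int) -> float:
    if conservation is None:
        return 1.0
    window = conservation[start0 : start0 + length]
    if not window:
        return 0.0
    return sum(window) / len(window)


def _primer_ok(seq: str, c: PrimerConstraints) -> bool:
    if any(ch not in "ACGT" for ch in seq):
        return False
    gc = gc_percent(seq)
    if not (c.min_gc <= gc <= c.max_gc):
        return False
    return abs(melting_temp(seq) - c.tm_target) <= c.tm_tolerance


def _candidates(template: str, c: PrimerConstraints, lo: int, hi: int,
                conservation, *, anchor: str):
    """Feasible primers whose start (``anchor='start'``) or end
    (``anchor='end'``) lies in 1-based [lo, hi], best conservation first."""
    out = []
    for pos in range(max(1, lo), hi + 1):
        for ln in range(c.min_len, c.max_len + 1):
            if anchor == "start":
                s0, e0 = pos - 1, pos - 1 + ln
            else:
                s0, e0 = pos - ln, pos
            if s0 < 0 or e0 > len(template):
                continue
            seq = template[s0:e0]
            if not _primer_ok(seq, c):
                continue
            out.append((-_window_score(conservation, s0, ln), s0 + 1, ln, seq))
    out.sort()
    return out


def design_primers(
    template: str,
    cds_interval: tuple[int, int],
    constraints: Optional[PrimerConstraints] = None,
    conservation: Optional[Sequence[float]] = None,
    gene_id: str = "gene",
) -> list[PrimerPair]:
    """Tile a CDS with Sanger-sized amplicons.

    A single pair is designed when the CDS fits one amplicon; otherwise
    successive amplicons overlap by ``overlap ± overlap_tolerance`` bp.
    Within each search window candidates are ranked by mean conservation
    of their footprint, ties by closeness of the amplicon to the
    preferred size.  Raises :class:`PrimerDesignError` naming the first
    window where no candidate satisfies the constraints.
    """
    c = constraints or PrimerConstraints()
    template = template.upper()
    cds_start, cds_end = cds_interval
    if not (1 <= cds_start <= cds_end <= len(template)):
        raise ValueError("cds_interval outside template")
    span = cds_end - cds_start + 1

    # number of tiles: each adds (preferred - overlap) of new coverage
    n_amp = 1
    while n_amp * c.preferred_amplicon - (n_amp - 1) * c.overlap < span + 40:
        n_amp += 1
    stride = c.preferred_amplicon - c.overlap

    pairs: list[PrimerPair] = []
    prev_rev_end: Optional[int] = None
    for i in range(n_amp):
        if i == 0:
            # forward primer in (or just upstream of) the CDS start flank
            lo = max(1, cds_start - 120)
            hi = cds_start
            window = (lo, hi)
            fwd_cands = _candidates(template, c, lo, hi, conservation,
                                    anchor="start")
        else:
            lo = prev_rev_end - c.overlap - c.overlap_tolerance + 1
            hi = prev_rev_end - c.overlap + c.overlap_tolerance + 1
            window = (lo, hi)
            fwd_cands = _candidates(template, c, lo, hi, conservation,
                                    anchor="start")
        if not fwd_cands:
            raise PrimerDesignError(
                f"{gene_id}: no forward primer for amplicon {i + 1}", window
            )

        chosen = None
        last = i == n_amp - 1
        for _, f_start, f_len, f_seq in fwd_cands[:40]:
            lo_r = f_start + c.min_amplicon - 1
            hi_r = f_start + c.max_amplicon - 1
            if last:
                lo_r = max(lo_r, cds_end)
            else:
                # leave room so the next tile can still overlap and reach on
                target = f_start + c.preferred_amplicon - 1
                lo_r = max(lo_r, target - 80)
                hi_r = min(hi_r, target + 80)
            hi_r = min(hi_r, len(template))
            rev_cands = _candidates(template, c, lo_r, hi_r, conservation,
                                    anchor="end")
            best = None
            for score_neg, r_pos, r_ln, _ in rev_cands:
                r_end = r_pos + r_ln - 1
                amp = r_end - f_start + 1
                if not (c.min_amplicon <= amp <= c.max_amplicon):
                    continue
                key = (score_neg, abs(amp - c.preferred_amplicon), r_end)
                if best is None or key < best[0]:
                    best = (key, r_pos, r_ln, r_end)
            if best is not None:
                chosen = (f_start, f_len, f_seq, best)
                break
        if chosen is None:
            raise PrimerDesignError(
                f"{gene_id}: no reverse primer for amplicon {i + 1}",
                (f_start + c.min_amplicon - 1,
                 min(f_start + c.max_amplicon - 1, len(template))),
            )
        f_start, f_len, f_seq, (_, r_pos, r_ln, r_end) = chosen
        rev_template = template[r_pos - 1 : r_end]
        rev_seq = _revcomp(rev_template)
        pair = PrimerPair(
            pair_id=f"{gene_id}_{i + 1}",
            fwd_seq=f_seq,
            rev_seq=rev_seq,
            fwd_start=f_start,
            rev_end=r_end,
            amplicon_len=r_end - f_start + 1,
            fwd_tm=melting_temp(f_seq),
            rev_tm=melting_temp(rev_seq),
            fwd_gc=gc_percent(f_seq),
            rev_gc=gc_percent(rev_seq),
        )
        assert pair.satisfies(c), "designed pair violates constraints"
        pairs.append(pair)
        prev_rev_end = r_end
    return pairs


def _iupac_match(template_char: str, base: str) -> bool:
    return base in IUPAC_BASES.get(template_char, template_char)


def _find_site(template: str, primer: str, *, last: bool = False) -> Optional[int]:
    """0-based start of a primer's exact (ambiguity-aware) template match."""
    hits = []
    for i in range(len(template) - len(primer) + 1):
        if all(_iupac_match(template[i + j], primer[j]) for j in range(len(primer))):
            hits.append(i)
            if not last:
                return i
    return hits[-1] if hits else None


def predicted_amplicon_size(pair: PrimerPair, template: str) -> int:
    """Theoretical PCR product size on a template: distance from the
    forward primer's first base to the reverse primer site's last base."""
    template = template.upper()
    fwd_at = _find_site(template, pair.fwd_seq)
    rev_site = _revcomp(pair.rev_seq)
    rev_at = _find_site(template, rev_site, last=True)
    if fwd_at is None or rev_at is None:
        raise ValueError(f"{pair.pair_id}: primer site not found on template")
    rev_end = rev_at + len(rev_site)
    size = rev_end - fwd_at
    if size <= 0:
        raise ValueError(f"{pair.pair_id}: primers in wrong orientation")
    return size


def _primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation — the cross-sequence identity
    of a repeat motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(
    seq: str,
    minima: Optional[dict[int, int]] = None,
    seq_id: str = "seq",
) -> list[SSRLocus]:
    """Maximal perfect tandem repeats of motif size 1–6.

    A locus is reported when its whole-copy length reaches the per-size
    minimum (defaults: mono/di ≥ 10 bp, tri ≥ 9 bp, tetra–hexa ≥ 12 bp).
    ``N`` breaks runs; non-primitive motifs are suppressed so an (AC)n
    run is not additionally reported as (ACAC)n.
    """
    minima = minima or DEFAULT_SSR_MINIMA
    seq = seq.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    for m in range(1, 7):
        threshold = minima.get(m)
        if threshold is None:
            continue
        i = 0
        while i + 2 * m <= n:
            motif = seq[i : i + m]
            if any(ch not in "ACGT" for ch in motif) or not _primitive(motif):
                i += 1
                continue
            # maximal left: skip starts that extend leftward
            if i > 0 and seq[i - 1] == seq[i - 1 + m] and seq[i - 1] in "ACGT":
                i += 1
                continue
            j = i + m
            while j < n and seq[j] == seq[j - m] and seq[j] in "ACGT":
                j += 1
            run = j - i
            copies = run // m
            if copies >= 2 and copies * m >= threshold:
                loci.append(
                    SSRLocus(
                        seq_id=seq_id,
                        cds_pos=i + 1,
                        motif=canonical_motif(motif),
                        copies=copies,
                        length=copies * m,
                    )
                )
                i = j - m + 1
            else:
                i += 1
    loci.sort(key=lambda l: (l.cds_pos, len(l.motif)))
    return loci


def _copies_at(seq: str, motif: str, pos0: int, slack: int = 8) -> int:
    """Longest tandem run of any rotation of ``motif`` starting within
    ``slack`` of 0-based ``pos0``."""
    m = len(motif)
    want = canonical_motif(motif)
    best = 0
    for start in range(max(0, pos0 - slack), min(len(seq), pos0 + slack + 1)):
        unit = seq[start : start + m]
        if len(unit) < m or canonical_motif(unit) != want:
            continue
        j = start + m
        while j < len(seq) and seq[j] == seq[j - m]:
            j += 1
        best = max(best, (j - start) // m)
    return best


def ssr_variability(
    seqs: Sequence[tuple[str, str]],
    minima: Optional[dict[int, int]] = None,
) -> list[dict]:
    """Compare SSR copy numbers across homologous sequences.

    ``seqs`` is a list of ``(seq_id, sequence)``.  SSR loci detected in
    any sequence are projected onto the others through a global alignment
    to the first sequence; a locus is variable iff the copy count differs
    between any two sequences (absence counts as zero copies).

    Returns one dict per locus: ``motif``, ``ref_pos`` (position on the
    first sequence), ``copies`` (per seq_id) and ``variable``.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    from .seqio import GeneRecord
    from .homology import align_pair

    ref_id, ref_seq = seqs[0]
    # position maps: other-seq 0-based pos -> ref 0-based pos (and back)
    to_ref: dict[str, dict[int, int]] = {ref_id: {i: i for i in range(len(ref_seq))}}
    from_ref: dict[str, dict[int, int]] = {ref_id: {i: i for i in range(len(ref_seq))}}
    for sid, s in seqs[1:]:
        aln = align_pair(GeneRecord("r", ref_seq), GeneRecord("q", s), mode="global")
        fwd, back = {}, {}
        pi = pj = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-" and cb != "-":
                fwd[pj] = pi
                back[pi] = pj
            if ca != "-":
                pi += 1
            if cb != "-":
                pj += 1
        to_ref[sid] = fwd
        from_ref[sid] = back

    # collect loci, keyed to ref coordinates
    groups: dict[tuple[str, int], dict] = {}
    for sid, s in seqs:
        for locus in find_ssrs(s, minima=minima, seq_id=sid):
            pos0 = locus.cds_pos - 1
            ref_pos = to_ref[sid].get(pos0)
            if ref_pos is None:  # locus inside an unaligned region
                ref_pos = min(
                    (p for p in to_ref[sid] if p >= pos0),
                    default=None,
                )
                ref_pos = to_ref[sid].get(ref_pos) if ref_pos is not None else None
            if ref_pos is None:
                continue
            key = None
            for (mot, rp) in groups:
                if mot == locus.motif and abs(rp - ref_pos) <= 8:
                    key = (mot, rp)
                    break
            if key is None:
                key = (locus.motif, ref_pos)
                groups[key] = {"motif": locus.motif, "ref_pos": ref_pos + 1,
                               "copies": {}}
            groups[key]["copies"].setdefault(sid, locus.copies)

    out = []
    for (motif, ref_pos0), info in sorted(groups.items(), key=lambda kv: kv[0][1]):
        for sid, s in seqs:
            if sid in info["copies"]:
                continue
            local = from_ref[sid].get(ref_pos0)
            if local is None:
                info["copies"][sid] = 0
            else:
                info["copies"][sid] = _copies_at(s, motif, local)
        counts = list(info["copies"].values())
        info["variable"] = max(counts) != min(counts)
        out.append(info)
    return out
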