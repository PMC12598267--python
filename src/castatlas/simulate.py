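"""Synthetic gene families with ground truth for every pipeline stage.

The generator emulates the study system: an ancestral locus (CDS plus
flanks) diverges into two anchor-species copies and a diploid target
individual; error-bearing short reads are drawn from the two target
haplotypes.  Designated genes carry structural events — a repeat-block
deletion or a larger region absent from the sequenced genotype — which
are exactly what the variability flag is meant to catch.

Mutations keep the CDS translatable: the start and stop codons are
protected, substitutions never create an in-frame stop, and CDS indels
are codon-aligned.  Every descendant is fully determined by the ancestor
plus its mutation log, which makes exact replay checks possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import GeneRecord, ShortRead

__all__ = [
    "EvolutionConfig",
    "ReadSimConfig",
    "SyntheticFamily",
    "random_locus",
    "evolve_sequence",
    "replay_log",
    "insert_structural_event",
    "generate_reads",
    "make_family",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class EvolutionConfig:
    """Per-branch mutation settings.

    ``sub_rate``: substitutions per site on one branch (two anchor
    branches of 0.01 give ≈2% pairwise divergence, the regime of closely
    related congeners).  ``indel_rate``: indel events per site; CDS indels
    are codon-aligned with length 3 × Geometric(``indel_len_p``).
    """

    sub_rate: float = 0.01
    indel_rate: float = 0.0005
    indel_len_p: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.indel_rate):
            if not (0 <= r < 0.5):
                raise ValueError("rates must lie in [0, 0.5)")


@dataclass
class ReadSimConfig:
    """Read-simulation settings: mean coverage ``depth`` over the locus,
    read length, and per-base substitution error rate."""

    depth: float = 15.0
    read_len: int = 100
    error_rate: float = 0.005
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SyntheticFamily:
    """One gene's full synthetic fixture: ancestor, the two anchor-species
    descendants, the diploid target haplotypes, the reads drawn from them,
    and the truth CDS the pipeline should reconstruct."""

    gene_id: str
    ancestor: GeneRecord
    anchor1: GeneRecord
    anchor2: GeneRecord
    target_hapA: GeneRecord
    target_hapB: GeneRecord
    mutation_log: dict[str, list[tuple]]
    reads: list[ShortRead]
    truth_cds: str
    sv_type: Optional[str] = None  # None, "repeat_deletion", "region_loss"


def random_locus(
    gene_id: str,
    rng: np.random.Generator,
    cds_codons: int = 300,
    flank: int = 150,
    species: str = "ancestor",
) -> GeneRecord:
    """A random locus: ``flank`` nt, an ORF of ``cds_codons`` codons
    (ATG … stop, no internal stop), ``flank`` nt."""
    def rand_seq(n: int) -> str:
        return "".join(rng.choice(list(_BASES), size=n))

    codons = []
    while len(codons) < cds_codons - 2:
        c = rand_seq(3)
        if c not in _STOPS:
            codons.append(c)
    cds = "ATG" + "".join(codons) + "TAA"
    left, right = rand_seq(flank), rand_seq(flank)
    seq = left + cds + right
    return GeneRecord(
        gene_id=gene_id,
        seq=seq,
        species=species,
        cds_interval=(flank + 1, flank + len(cds)),
    )


def _codon_start(pos0: int, cds_start0: int) -> int:
    """0-based start of the codon containing 0-based position ``pos0``."""
    return cds_start0 + ((pos0 - cds_start0) // 3) * 3


def evolve_sequence(
    ancestor: GeneRecord,
    cfg: EvolutionConfig,
    rng: Optional[np.random.Generator] = None,
    species: str = "derived",
) -> tuple[GeneRecord, list[tuple]]:
    """Apply i.i.d. substitutions and codon-aligned indels to a locus.

    Returns the derived record plus a mutation log of
    ``("sub", pos, "X>Y")``, ``("ins", pos, seq)`` and
    ``("del", pos, seq)`` entries with 1-based positions in ancestor
    coordinates.  :func:`replay_log` applied to the ancestor reproduces
    the derived sequence exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    seq = list(ancestor.seq)
    n = len(seq)
    cds_start, cds_end = ancestor.cds_interval
    cds_start0, cds_end0 = cds_start - 1, cds_end - 1  # 0-based inclusive
    protected = set(range(cds_start0, cds_start0 + 3)) | set(
        range(cds_end0 - 2, cds_end0 + 1)
    )
    log: list[tuple] = []

    # substitutions
    hits = np.flatnonzero(rng.random(n) < cfg.sub_rate)
    for pos0 in hits:
        pos0 = int(pos0)
        if pos0 in protected:
            continue
        old = seq[pos0]
        alts = [b for b in _BASES if b != old]
        rng.shuffle(alts)
        chosen = None
        for alt in alts:
            if cds_start0 <= pos0 <= cds_end0:
                c0 = _codon_start(pos0, cds_start0)
                codon = seq[c0 : c0 + 3]
                codon[pos0 - c0] = alt
                if "".join(codon) in _STOPS:
                    continue
            chosen = alt
            break
        if chosen is None:
            continue
        seq[pos0] = chosen
        log.append(("sub", pos0 + 1, f"{old}>{chosen}"))

    # indel events, positions in ancestor coordinates, applied right-to-left
    ev_hits = np.flatnonzero(rng.random(n) < cfg.indel_rate)
    indels: list[tuple] = []
    for pos0 in ev_hits:
        pos0 = int(pos0)
        if pos0 in protected:
            continue
        length = 3 * int(rng.geometric(cfg.indel_len_p))
        in_cds = cds_start0 <= pos0 <= cds_end0
        if in_cds:
            pos0 = _codon_start(pos0, cds_start0)
            if pos0 in protected or pos0 + length > cds_end0 - 2:
                continue
        if rng.random() < 0.5:  # insertion before pos0
            ins = _random_insert(rng, length, in_cds)
            indels.append(("ins", pos0 + 1, ins))
        else:  # deletion of [pos0, pos0+length)
            if pos0 + length > n or (protected & set(range(pos0, pos0 + length))):
                continue
            indels.append(("del", pos0 + 1, "".join(seq[pos0 : pos0 + length])))
    # drop overlapping deletions (keep leftmost) and sort for replay
    indels.sort(key=lambda e: e[1])
    pruned: list[tuple] = []
    last_del_end = -1
    for ev in indels:
        kind, pos, payload = ev
        if kind == "del":
            if pos <= last_del_end:
                continue
            last_del_end = pos + len(payload) - 1
        elif pos <= last_del_end:
            continue
        pruned.append(ev)
    log.extend(pruned)

    derived_seq, new_interval = _apply_indels(
        "".join(seq), pruned, ancestor.cds_interval
    )
    derived = GeneRecord(
        gene_id=ancestor.gene_id,
        seq=derived_seq,
        species=species,
        cds_interval=new_interval,
    )
    return derived, log


def _random_insert(rng: np.random.Generator, length: int, in_cds: bool) -> str:
    """Random insert; in-CDS inserts are stop-free codon blocks."""
    if not in_cds:
        return "".join(rng.choice(list(_BASES), size=length))
    codons = []
    while len(codons) < length // 3:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _apply_indels(
    seq: str, indels: Sequence[tuple], cds_interval: tuple[int, int]
) -> tuple[str, tuple[int, int]]:
    start, end = cds_interval
    out = seq
    for kind, pos, payload in sorted(indels, key=lambda e: -e[1]):
        pos0 = pos - 1
        if kind == "ins":
            out = out[:pos0] + payload + out[pos0:]
            if pos <= start:
                start += len(payload)
            if pos <= end:
                end += len(payload)
        elif kind == "del":
            ln = len(payload)
            out = out[:pos0] + out[pos0 + ln :]
            if pos < start:
                start -= ln
            if pos <= end:
                end -= ln
        else:
            raise ValueError(f"unknown log entry {kind!r}")
    return out, (start, end)


def replay_log(ancestor: GeneRecord, log: Sequence[tuple]) -> str:
    """Re-apply a mutation log to the ancestor; used as an exact inverse
    check on :func:`evolve_sequence` output."""
    seq = list(ancestor.seq)
    indels = []
    for kind, pos, payload in log:
        if kind == "sub":
            old, new = payload.split(">")
            if seq[pos - 1] != old:
                raise ValueError(f"log mismatch at {pos}: {seq[pos - 1]} != {old}")
            seq[pos - 1] = new
        else:
            indels.append((kind, pos, payload))
    out, _ = _apply_indels("".join(seq), indels, ancestor.cds_interval)
    return out


def insert_structural_event(
    record: GeneRecord, event: tuple
) -> tuple[GeneRecord, tuple]:
    """Apply one exact structural edit and return (record, log entry).

    Events: ``("repeat_expansion", motif, copies, pos)`` inserts
    ``motif × copies`` before 1-based ``pos``; ``("deletion", start, end)``
    removes the 1-based inclusive interval.
    """
    kind = event[0]
    if kind == "repeat_expansion":
        _, motif, copies, pos = event
        if not (1 <= pos <= len(record.seq) + 1):
            raise ValueError("insertion position outside sequence")
        payload = motif * copies
        seq, interval = _apply_indels(record.seq, [("ins", pos, payload)],
                                      record.cds_interval)
        entry = ("ins", pos, payload)
    elif kind == "deletion":
        _, start, end = event
        if not (1 <= start <= end <= len(record.seq)):
            raise ValueError("deletion interval outside sequence")
        payload = record.seq[start - 1 : end]
        seq, interval = _apply_indels(record.seq, [("del", start, payload)],
                                      record.cds_interval)
        entry = ("del", start, payload)
    else:
        raise ValueError(f"unknown structural event {kind!r}")
    return (
        GeneRecord(record.gene_id, seq, species=record.species,
                   cds_interval=interval),
        entry,
    )


def generate_reads(
    haplotypes: Sequence[GeneRecord],
    cfg: ReadSimConfig,
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "read",
) -> list[ShortRead]:
    """Draw error-bearing short reads from a diploid (unphased pool).

    Read count is Poisson with mean ``depth × mean locus length /
    read_len``; each read picks a haplotype, start and strand uniformly
    and carries i.i.d. substitution errors at ``error_rate`` per base.
    The true origin is recorded on each read.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    mean_len = sum(len(h.seq) for h in haplotypes) / len(haplotypes)
    expected = cfg.depth * mean_len / cfg.read_len
    n_reads = int(rng.poisson(expected))
    reads: list[ShortRead] = []
    for i in range(n_reads):
        hap = haplotypes[int(rng.integers(len(haplotypes)))]
        max_start = len(hap.seq) - cfg.read_len
        if max_start < 0:
            continue
        start0 = int(rng.integers(max_start + 1))
        frag = hap.seq[start0 : start0 + cfg.read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        bases = list(frag)
        err_pos = np.flatnonzero(rng.random(len(bases)) < cfg.error_rate)
        for p in err_pos:
            old = bases[p]
            alts = [b for b in _BASES if b != old]
            bases[p] = alts[int(rng.integers(3))]
        seq = "".join(bases)
        if strand == "-":
            comp = str.maketrans("ACGTN", "TGCAN")
            seq = seq.translate(comp)[::-1]
        reads.append(
            ShortRead(
                read_id=f"{id_prefix}_{i}",
                seq=seq,
                source=(hap.gene_id, start0 + 1, strand),
            )
        )
    return reads


def make_family(
    n_genes: int = 20,
    evolution: Optional[EvolutionConfig] = None,
    read_cfg: Optional[ReadSimConfig] = None,
    het_rate: float = 0.002,
    sv_spec: Optional[dict[int, str]] = None,
    seed: int = 0,
    cds_codons: int = 300,
    flank: int = 150,
) -> list[SyntheticFamily]:
    """Generate a full fixture set of ``n_genes`` synthetic families.

    Per gene the ancestor spawns anchor1, anchor2 and a target lineage
    (one evolution branch each); the target then splits into two
    haplotypes at ``het_rate`` substitutions per site (within-individual
    heterozygosity, an order of magnitude below species divergence).

    ``sv_spec`` maps gene index → structural class applied to *both*
    target haplotypes (the sequenced genotype lacks what the anchors
    carry): ``"repeat_deletion"`` plants a repeat block in the ancestral
    CDS and deletes it from the target, ``"region_loss"`` deletes a ~30%
    CDS chunk.  Default: the last two genes, one of each class.
    """
    evolution = evolution or EvolutionConfig()
    read_cfg = read_cfg or ReadSimConfig()
    rng = np.random.default_rng(seed)
    if sv_spec is None:
        sv_spec = {}
        if n_genes >= 2:
            sv_spec = {n_genes - 2: "repeat_deletion", n_genes - 1: "region_loss"}

    het_cfg = EvolutionConfig(sub_rate=het_rate, indel_rate=0.0)
    families: list[SyntheticFamily] = []
    for g in range(n_genes):
        gene_id = f"SG{g + 1}"
        ancestor = random_locus(gene_id, rng, cds_codons=cds_codons, flank=flank)
        sv_type = sv_spec.get(g)
        sv_region: Optional[tuple[int, int]] = None
        if sv_type == "repeat_deletion":
            # plant a repeat block mid-CDS in the ancestor (inherited by
            # the anchors), then delete it from the target haplotypes
            cds_start, cds_end = ancestor.cds_interval
            pos = cds_start + ((cds_end - cds_start) // 2 // 3) * 3
            motif = "ACTGGT"
            copies = 40  # 240 bp block — >15% of the CDS once inherited
            ancestor, _ = insert_structural_event(
                ancestor, ("repeat_expansion", motif, copies, pos)
            )
            sv_region = (pos, pos + len(motif) * copies - 1)

        anchor1, log1 = evolve_sequence(ancestor, evolution, rng, species="anchor1")
        anchor2, log2 = evolve_sequence(ancestor, evolution, rng, species="anchor2")
        target, log_t = evolve_sequence(ancestor, evolution, rng, species="target")

        if sv_type == "repeat_deletion":
            # region boundaries track any upstream indels on the target branch
            start, end = _project_interval(sv_region, log_t)
            target, entry = insert_structural_event(target, ("deletion", start, end))
            log_t = log_t + [entry]
        elif sv_type == "region_loss":
            cds_start, cds_end = target.cds_interval
            cds_len = cds_end - cds_start + 1
            loss = (cds_len // 9) * 3  # ~1/3 of the CDS, codon-aligned
            start = cds_start + ((cds_len // 3) // 3) * 3
            target, entry = insert_structural_event(
                target, ("deletion", start, start + loss - 1)
            )
            log_t = log_t + [entry]

        hapA, logA = evolve_sequence(target, het_cfg, rng, species="target_hapA")
        hapB, logB = evolve_sequence(target, het_cfg, rng, species="target_hapB")
        hapA = replace(hapA, gene_id=f"{gene_id}_hapA")
        hapB = replace(hapB, gene_id=f"{gene_id}_hapB")

        reads = generate_reads([hapA, hapB], read_cfg, rng,
                               id_prefix=f"{gene_id}_r")
        families.append(
            SyntheticFamily(
                gene_id=gene_id,
                ancestor=ancestor,
                anchor1=replace(anchor1, gene_id=gene_id),
                anchor2=replace(anchor2, gene_id=gene_id),
                target_hapA=hapA,
                target_hapB=hapB,
                mutation_log={
                    "anchor1": log1,
                    "anchor2": log2,
                    "target": log_t,
                    "hapA": logA,
                    "hapB": logB,
                },
                reads=reads,
                truth_cds=hapA.cds,
                sv_type=sv_type,
            )
        )
    return families


def _project_interval(interval: tuple[int, int], log: Sequence[tuple]):
    """Shift an ancestor-coordinate interval through a branch's indels."""
    start, end = interval
    for kind, pos, payload in sorted(
        (e for e in log if e[0] in ("ins", "del")), key=lambda e: e[1]
    ):
        ln = len(payload)
        if kind == "ins":
            if pos <= start:
                start += ln
                end += ln
            elif pos <= end:
                end += ln
        else:
            if pos + ln - 1 < start:
                start -= ln
                end -= ln
            elif pos <= end:
                end -= min(ln, end - pos + 1)
    return start, end


def write_family_dir(families: Sequence[SyntheticFamily], outdir) -> None:
    """Write a family set as the pipeline's on-disk input layout: FASTA
    per species, pooled FASTQ, mutation-log and truth TSVs, and an
    annotation table marking every gene as a stress-response candidate."""
    from pathlib import Path

    from .seqio import (
        AnnotationRow,
        GeneRecord,
        write_annotation_table,
        write_fasta,
        write_fastq,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([f.anchor1 for f in families], outdir / "anchor1.fasta")
    write_fasta([f.anchor2 for f in families], outdir / "anchor2.fasta")
    # haplotype reference records are annotated CDS, as a genome-derived
    # CDS database would provide them
    write_fasta(
        [GeneRecord(f.target_hapA.gene_id, f.target_hapA.cds) for f in families]
        + [GeneRecord(f.target_hapB.gene_id, f.target_hapB.cds) for f in families],
        outdir / "target_haplotypes.fasta",
    )
    all_reads = [r for f in families for r in f.reads]
    write_fastq(all_reads, outdir / "reads.fastq")
    with (outdir / "anchor_cds.tsv").open("w") as fh:
        fh.write("gene_id\tspecies\tstart\tend\n")
        for f in families:
            s1, e1 = f.anchor1.cds_interval
            s2, e2 = f.anchor2.cds_interval
            fh.write(f"{f.gene_id}\tanchor1\t{s1}\t{e1}\n")
            fh.write(f"{f.gene_id}\tanchor2\t{s2}\t{e2}\n")
    with (outdir / "truth.tsv").open("w") as fh:
        fh.write("gene_id\tsv_type\ttruth_cds\n")
        for f in families:
            fh.write(f"{f.gene_id}\t{f.sv_type or 'none'}\t{f.truth_cds}\n")
    with (outdir / "mutations.tsv").open("w") as fh:
        fh.write("gene_id\tbranch\tkind\tposition\tpayload\n")
        for f in families:
            for branch, log in f.mutation_log.items():
                for kind, pos, payload in log:
                    fh.write(f"{f.gene_id}\t{branch}\t{kind}\t{pos}\t{payload}\n")
    rows = [
        AnnotationRow(gene_id=f.gene_id, description="synthetic stress-response gene",
                      is_response=True, is_stress=True)
        for f in families
    ]
    write_annotation_table(rows, outdir / "annotations.tsv")
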