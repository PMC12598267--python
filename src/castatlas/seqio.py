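"""Sequence and table I/O.

Every other module consumes the types defined here.  All coordinates on
I/O surfaces are 1-based inclusive; sequences are normalised to uppercase
DNA over ``{A, C, G, T, N}`` (RNA ``U`` becomes ``T``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "ShortRead",
    "AnnotationRow",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "translate_cds",
    "read_annotation_table",
    "write_annotation_table",
]

_DNA_ALPHABET = set("ACGTN")


def _normalize_seq(raw: str, *, where: str = "sequence") -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"{where}: unexpected characters {sorted(bad)!r}")
    return seq


@dataclass
class GeneRecord:
    """A single gene: its (DNA) sequence plus the CDS interval within it.

    ``cds_interval`` is 1-based inclusive; by default it spans the whole
    sequence, which is the common case here where inputs are annotated CDS
    FASTA records rather than genomic loci.
    """

    gene_id: str
    seq: str
    species: str = ""
    cds_interval: Optional[Tuple[int, int]] = None
    strand: str = "+"

    def __post_init__(self) -> None:
        self.seq = _normalize_seq(self.seq, where=f"gene {self.gene_id}")
        if not self.seq:
            raise ValueError(f"gene {self.gene_id}: empty sequence")
        if self.cds_interval is None:
            self.cds_interval = (1, len(self.seq))
        start, end = self.cds_interval
        if not (1 <= start <= end <= len(self.seq)):
            raise ValueError(
                f"gene {self.gene_id}: CDS interval {self.cds_interval} "
                f"outside sequence of length {len(self.seq)}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def cds(self) -> str:
        """The CDS substring (respecting strand)."""
        start, end = self.cds_interval
        sub = self.seq[start - 1 : end]
        if self.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ShortRead:
    """One sequencing read.  ``source`` records the simulated ground-truth
    origin ``(gene_id, 1-based position on the haplotype, strand)`` when
    known; reads from real FASTQ files leave it ``None``."""

    read_id: str
    seq: str
    qual: Optional[str] = None
    source: Optional[Tuple[str, int, str]] = None

    def __post_init__(self) -> None:
        self.seq = _normalize_seq(self.seq, where=f"read {self.read_id}")
        if not self.seq:
            raise ValueError(f"read {self.read_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AnnotationRow:
    """One gene's functional-category flags (stress / stimulus response,
    signal transduction, transcription factor)."""

    gene_id: str
    description: str = ""
    is_response: bool = False
    is_stress: bool = False
    is_signal: bool = False
    is_tf: bool = False

    @property
    def any_flag(self) -> bool:
        return self.is_response or self.is_stress or self.is_signal or self.is_tf


def read_fasta(path) -> list[GeneRecord]:
    """Read a FASTA file into :class:`GeneRecord` objects, order preserved.

    Sequences are uppercased and U→T normalised.  Duplicate record ids are
    an error; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(GeneRecord(gene_id=rec.id, seq=str(rec.seq)))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[GeneRecord], path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[ShortRead]:
    """Read 4-line-per-record FASTQ.  Qualities are parsed and kept on the
    record but the downstream mapper ignores them (base calling is purely
    count-based).  A truncated trailing record is an error naming the
    record index."""
    path = Path(path)
    reads: list[ShortRead] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) % 4 != 0:
        raise ValueError(
            f"{path}: truncated FASTQ — record {len(lines) // 4 + 1} is incomplete"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        idx = i // 4 + 1
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed FASTQ record {idx}")
        if len(qual) != len(seq):
            raise ValueError(f"{path}: record {idx}: quality/sequence length mismatch")
        reads.append(ShortRead(read_id=header[1:].split()[0], seq=seq, qual=qual))
    return reads


def write_fastq(reads: Iterable[ShortRead], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rd in reads:
            qual = rd.qual if rd.qual is not None else "I" * len(rd.seq)
            fh.write(f"@{rd.read_id}\n{rd.seq}\n+\n{qual}\n")


def translate_cds(record: GeneRecord) -> str:
    """Translate a gene's CDS with the standard code.

    The terminal stop (if present) is stripped.  An internal stop codon or
    a CDS length not divisible by 3 is an error: both indicate a broken
    annotation that would poison downstream protein comparison.
    """
    cds = record.cds
    if "N" in cds:
        raise ValueError(f"gene {record.gene_id}: CDS contains N, cannot translate")
    if len(cds) % 3 != 0:
        raise ValueError(
            f"gene {record.gene_id}: CDS length {len(cds)} not a multiple of 3"
        )
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        pos = protein.index("*")
        raise ValueError(
            f"gene {record.gene_id}: internal stop codon at codon {pos + 1}"
        )
    return protein


def read_annotation_table(path) -> list[AnnotationRow]:
    """Read a TSV of per-gene category flags.

    Expected columns: ``gene_id``, ``description``, ``response``, ``stress``,
    ``signal``, ``tf`` — the last four as 0/1.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "response", "stress", "signal", "tf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            AnnotationRow(
                gene_id=r["gene_id"],
                description=str(r.get("description", "")),
                is_response=bool(int(r["response"])),
                is_stress=bool(int(r["stress"])),
                is_signal=bool(int(r["signal"])),
                is_tf=bool(int(r["tf"])),
            )
        )
    return rows


def write_annotation_table(rows: Iterable[AnnotationRow], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "description": r.description,
                "response": int(r.is_response),
                "stress": int(r.is_stress),
                "signal": int(r.is_signal),
                "tf": int(r.is_tf),
            }
            for r in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)
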