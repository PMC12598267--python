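"""Published *Castanea sativa* drought-atlas tables, shipped as package data.

These are the per-gene values reported for the 26 drought-tolerance
candidate genes: functional-category annotations, anchor-alignment and
short-read mapping metrics, CDS identity against the two haplotypes of
the 'Marrone di Chiusa Pesio' reference assembly, chromosome-5
structural-variant coordinates, and the EST-SSR loci found in the
reconstructed CDS set.  They let the report-level statistics be
recomputed without access to the underlying sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import GeneMetricsRow, GenomicInterval
from .seqio import AnnotationRow

__all__ = [
    "load_candidate_annotations",
    "load_gene_metrics",
    "load_haplotype_identities",
    "load_chr5_features",
    "load_ssr_loci",
    "CHR5_HAP1_MB",
    "CHR5_HAP2_MB",
]

# assembled chromosome-5 sizes of the two reference haplotypes (Mb)
CHR5_HAP1_MB = 81.89
CHR5_HAP2_MB = 79.79


def _data_path(name: str):
    return resources.files("castatlas").joinpath("data", name)


def load_candidate_annotations() -> list[AnnotationRow]:
    """The 26 candidate genes with their category flags."""
    from .seqio import read_annotation_table

    with resources.as_file(_data_path("castanea_candidate_annotations.tsv")) as p:
        return read_annotation_table(p)


def load_gene_metrics() -> list[GeneMetricsRow]:
    """Per-gene anchor-alignment and short-read mapping metrics."""
    with resources.as_file(_data_path("castanea_gene_metrics.tsv")) as p:
        df = pd.read_csv(p, sep="\t", na_values=["NA"])
    rows = []
    for _, r in df.iterrows():
        rows.append(
            GeneMetricsRow(
                gene_id=r["gene_id"],
                align_identity=None if pd.isna(r["align_identity"]) else float(r["align_identity"]),
                align_coverage=None if pd.isna(r["align_coverage"]) else float(r["align_coverage"]),
                map_identity=float(r["map_identity"]),
                map_coverage=float(r["map_coverage"]),
                depth_mean=float(r["depth_mean"]),
                depth_sd=float(r["depth_sd"]),
            )
        )
    return rows


def load_haplotype_identities() -> pd.DataFrame:
    """Pairwise CDS identity of each candidate against the reference
    haplotypes (NA where the comparison was not possible)."""
    with resources.as_file(_data_path("castanea_haplotype_identities.tsv")) as p:
        return pd.read_csv(p, sep="\t", na_values=["NA"])


def load_chr5_features() -> dict[str, list[GenomicInterval]]:
    """Chromosome-5 structural features (1-based inclusive intervals),
    keyed by feature name; multi-haplotype features list hap1 first."""
    with resources.as_file(_data_path("castanea_chr5_features.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    out: dict[str, list[GenomicInterval]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["feature"], []).append(
            GenomicInterval(chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]))
        )
    return out


def load_ssr_loci() -> pd.DataFrame:
    """EST-SSR loci with cross-sequence variability in the CDS set."""
    with resources.as_file(_data_path("castanea_ssr_loci.tsv")) as p:
        return pd.read_csv(p, sep="\t")
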