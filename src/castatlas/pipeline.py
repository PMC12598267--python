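"""End-to-end atlas workflow.

Runs the whole reconstruction chain on file inputs: candidate filtering →
anchor ortholog pairing → consensus building → short-read reconstruction
→ primer tiling → conservation calls against haplotype references → SSR
screening → atlas summary.  Per-gene failures (no ortholog, infeasible
primer window) are recorded and skipped, never fatal: a gene without an
anchor partner is itself a finding.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import compare, homology, mapping, markers, seqio

logger = logging.getLogger("castatlas")

__all__ = ["PipelineConfig", "AtlasBundle", "run_atlas", "load_config"]


@dataclass
class PipelineConfig:
    anchor1_fasta: Path
    anchor2_fasta: Path
    reads_fastq: Path
    annotation_tsv: Path
    outdir: Path
    haplotype_fasta: Optional[Path] = None
    anchor_cds_tsv: Optional[Path] = None
    min_depth: int = 2
    min_agreement: float = 0.65
    variability_cutoff: float = 85.0
    conservation_threshold: float = 90.0
    k: int = 15
    min_map_identity: float = 0.8
    rbh_score_floor: float = 50.0
    design_primer_pairs: bool = True
    seed: int = 0

    def thresholds(self) -> mapping.CallThresholds:
        return mapping.CallThresholds(
            min_depth=self.min_depth,
            min_agreement=self.min_agreement,
            variability_cutoff=self.variability_cutoff,
        )


@dataclass
class AtlasBundle:
    summary: compare.AtlasSummary
    metrics_rows: list[compare.GeneMetricsRow]
    reconstructions: dict[str, mapping.ReconstructionResult]
    pairs: list[homology.HomologPair]
    unpaired: list[str]
    primers: dict[str, list[markers.PrimerPair]]
    conservation_calls: dict[str, str]
    ssr_reports: dict[str, list[dict]]
    failures: dict[str, str]


def load_config(path) -> PipelineConfig:
    """Load a YAML key/value config into a :class:`PipelineConfig`."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("anchor1_fasta", "anchor2_fasta", "reads_fastq",
                "annotation_tsv", "outdir", "haplotype_fasta", "anchor_cds_tsv"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    return PipelineConfig(**raw)


def _read_anchor_cds(path) -> dict[tuple[str, str], tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r["gene_id"], r["species"]): (int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    }


def run_atlas(cfg: PipelineConfig) -> AtlasBundle:
    """Execute the full workflow and write the atlas bundle to disk."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotation = seqio.read_annotation_table(cfg.annotation_tsv)
    selection = compare.select_candidates(annotation)
    selected = set(selection.selected)
    logger.info("selected %d candidates (%d tf, %d signal, %d response)",
                len(selected), selection.n_tf, selection.n_signal,
                selection.n_response)

    anchor1 = [g for g in seqio.read_fasta(cfg.anchor1_fasta)
               if g.gene_id in selected]
    anchor2 = [g for g in seqio.read_fasta(cfg.anchor2_fasta)
               if g.gene_id in selected]
    cds_map = _read_anchor_cds(cfg.anchor_cds_tsv) if cfg.anchor_cds_tsv else {}
    anchor1 = [
        dataclasses.replace(g, species="anchor1",
                            cds_interval=cds_map.get((g.gene_id, "anchor1")))
        for g in anchor1
    ]
    anchor2 = [
        dataclasses.replace(g, species="anchor2",
                            cds_interval=cds_map.get((g.gene_id, "anchor2")))
        for g in anchor2
    ]
    reads = seqio.read_fastq(cfg.reads_fastq)

    haplotypes: dict[str, list[seqio.GeneRecord]] = {}
    if cfg.haplotype_fasta:
        for rec in seqio.read_fasta(cfg.haplotype_fasta):
            base = rec.gene_id.rsplit("_hap", 1)[0]
            haplotypes.setdefault(base, []).append(rec)

    if not anchor1 or not anchor2:
        empty = compare.AtlasSummary(0, {}, {}, {}, 0, [])
        return AtlasBundle(empty, [], {}, [], [], {}, {}, {}, {})

    pairs = homology.reciprocal_best_hits(anchor1, anchor2,
                                          score_floor=cfg.rbh_score_floor)
    paired_ids = {p.gene_id for p in pairs}
    unpaired = sorted(
        ({g.gene_id for g in anchor1} | {g.gene_id for g in anchor2}) - paired_ids
    )
    for gid in unpaired:
        logger.warning("gene %s: no reciprocal anchor ortholog", gid)

    thresholds = cfg.thresholds()
    reconstructions: dict[str, mapping.ReconstructionResult] = {}
    metrics_rows: list[compare.GeneMetricsRow] = []
    primers: dict[str, list[markers.PrimerPair]] = {}
    cons_calls: dict[str, str] = {}
    ssr_reports: dict[str, list[dict]] = {}
    failures: dict[str, str] = {}

    for pair in pairs:
        gid = pair.gene_id
        try:
            a, b = pair.anchor1, pair.anchor2
            template = a if len(a.cds) >= len(b.cds) else b
            choice = "a" if template is a else "b"
            consensus = homology.build_consensus(
                pair.alignment, template_choice=choice,
                cds_interval=template.cds_interval,
            )
            consensus.gene_id = gid
            recon = mapping.reconstruct_cds(
                consensus, reads, thresholds=thresholds, k=cfg.k,
                min_identity=cfg.min_map_identity,
            )
            reconstructions[gid] = recon
            metrics_rows.append(
                compare.GeneMetricsRow(
                    gene_id=gid,
                    align_identity=pair.identity_pct,
                    align_coverage=pair.coverage_pct,
                    map_identity=recon.mapping_identity_pct,
                    map_coverage=recon.mapping_coverage_pct,
                    depth_mean=recon.mean_depth,
                    depth_sd=recon.sd_depth,
                )
            )

            if cfg.design_primer_pairs:
                rows = _conservation_rows(pair, consensus, recon)
                track = markers.conservation_track(rows)
                try:
                    primers[gid] = markers.design_primers(
                        consensus.seq, consensus.cds_interval,
                        conservation=track, gene_id=gid,
                    )
                except markers.PrimerDesignError as exc:
                    failures[gid] = f"primer design: {exc}"

            called_cds = recon.called_cds
            ssr_inputs = [("anchor1", a.cds), ("anchor2", b.cds)]
            if called_cds.strip("N"):
                ssr_inputs.append(("target", called_cds))
            ssr_reports[gid] = markers.ssr_variability(ssr_inputs)

            if gid in haplotypes and called_cds.strip("N"):
                idents = []
                for hap in haplotypes[gid]:
                    mat = compare.cds_pairwise_identity(
                        [("target", called_cds), (hap.gene_id, hap.cds)]
                    )
                    idents.append(mat[0, 1])
                cons_calls[gid] = compare.conservation_call(
                    max(idents), cfg.conservation_threshold
                )
        except Exception as exc:  # isolate per-gene failures
            logger.exception("gene %s failed", gid)
            failures[gid] = str(exc)

    summary = compare.summarize_atlas(metrics_rows, cutoff=cfg.variability_cutoff)
    _write_outputs(cfg, outdir, selection, pairs, unpaired, reconstructions,
                   metrics_rows, primers, cons_calls, ssr_reports, summary,
                   failures, t0)
    return AtlasBundle(summary, metrics_rows, reconstructions, pairs, unpaired,
                       primers, cons_calls, ssr_reports, failures)


def _conservation_rows(pair, consensus, recon) -> list[str]:
    """Three equal-length rows on consensus coordinates: each anchor's
    base (gap where the anchor lacked the column) and the called target."""
    aln = pair.alignment
    a_is_template = len(pair.anchor1.cds) >= len(pair.anchor2.cds)
    tmpl_row, other_row = (
        (aln.aligned_a, aln.aligned_b) if a_is_template
        else (aln.aligned_b, aln.aligned_a)
    )
    row_t, row_o = [], []
    for ct, co in zip(tmpl_row, other_row):
        if ct == "-":
            continue
        row_t.append(ct)
        row_o.append(co)
    return ["".join(row_t), "".join(row_o), recon.called_seq]


def _write_outputs(cfg, outdir, selection, pairs, unpaired, reconstructions,
                   metrics_rows, primers, cons_calls, ssr_reports, summary,
                   failures, t0) -> None:
    seqio.write_fasta(
        [seqio.GeneRecord(gid, r.called_seq.replace("N", "N"))
         for gid, r in reconstructions.items() if set(r.called_seq) != {"N"}],
        outdir / "reconstructed.fasta",
    )
    pd.DataFrame(
        [dataclasses.asdict(r) for r in metrics_rows]
    ).to_csv(outdir / "gene_metrics.tsv", sep="\t", index=False, na_rep="NA")
    primer_rows = [
        {
            "pair_id": p.pair_id, "fwd": p.fwd_seq, "rev": p.rev_seq,
            "fwd_start": p.fwd_start, "rev_end": p.rev_end,
            "amplicon_len": p.amplicon_len,
            "fwd_tm": round(p.fwd_tm, 2), "rev_tm": round(p.rev_tm, 2),
            "fwd_gc": round(p.fwd_gc, 1), "rev_gc": round(p.rev_gc, 1),
        }
        for plist in primers.values() for p in plist
    ]
    pd.DataFrame(primer_rows).to_csv(outdir / "primers.tsv", sep="\t", index=False)
    ssr_rows = [
        {"gene_id": gid, "motif": rep["motif"], "pos": rep["ref_pos"],
         "variable": rep["variable"],
         "copies": ";".join(f"{k}={v}" for k, v in rep["copies"].items())}
        for gid, reps in ssr_reports.items() for rep in reps
    ]
    pd.DataFrame(ssr_rows).to_csv(outdir / "ssr_loci.tsv", sep="\t", index=False)
    manifest = {
        "n_selected": len(selection.selected),
        "n_tf": selection.n_tf,
        "n_signal": selection.n_signal,
        "n_response": selection.n_response,
        "n_paired": len(pairs),
        "unpaired": unpaired,
        "split_homologs": [p.gene_id for p in pairs if p.split_homolog],
        "n_variable": summary.n_variable,
        "variable_ids": summary.variable_ids,
        "conservation_calls": cons_calls,
        "failures": failures,
        "seed": cfg.seed,
        "thresholds": {
            "min_depth": cfg.min_depth,
            "min_agreement": cfg.min_agreement,
            "variability_cutoff": cfg.variability_cutoff,
            "conservation_threshold": cfg.conservation_threshold,
        },
        "runtime_s": round(time.time() - t0, 2),
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    with (outdir / "summary.txt").open("w") as fh:
        fh.write(f"n_genes\t{summary.n_genes}\n")
        for col, val in summary.means.items():
            if val is not None:
                fh.write(f"mean_{col}\t{val:.2f}\n")
        fh.write(f"n_variable\t{summary.n_variable}\n")
        fh.write(f"variable_ids\t{','.join(summary.variable_ids)}\n")
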