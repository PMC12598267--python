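"""Recompute the published atlas's report-level statistics.

The package ships the per-gene tables of the 26 *Castanea sativa*
drought-tolerance candidates (annotation categories, anchor-alignment
and mapping metrics, haplotype identities, chromosome-5 structural
variants).  This example reproduces the headline numbers from those
rows.
"""

from castatlas import compare, datasets

sel = compare.select_candidates(datasets.load_candidate_annotations())
print(f"candidates: {len(sel.selected)} "
      f"({sel.n_tf} transcription factor, {sel.n_signal} signal transduction, "
      f"{sel.n_response} stress/stimulus response)")

s = compare.summarize_atlas(datasets.load_gene_metrics())
print(f"anchor CDS alignment: mean identity {s.means['align_identity']:.1f}%, "
      f"mean coverage {s.means['align_coverage']:.1f}%")
print(f"short-read mapping:   mean identity {s.means['map_identity']:.0f}%, "
      f"mean coverage {s.means['map_coverage']:.0f}%, "
      f"mean depth {s.means['depth_mean']:.1f}")
print(f"variability-flagged genes (<85% identity or coverage): "
      f"{', '.join(sorted(s.variable_ids))}")

df = datasets.load_haplotype_identities()
divergent = df[df["pairwise_identity"] < 90]
print("divergent vs haplotype references (<90% identity): "
      + ", ".join(f"{r.gene_id} ({r.pairwise_identity:.1f}%)"
                  for r in divergent.itertuples()))

deletion = datasets.load_chr5_features()["hap1_exclusive_deletion"][0]
bp, mb = compare.interval_span(deletion)
diff = compare.size_difference(datasets.CHR5_HAP1_MB, datasets.CHR5_HAP2_MB)
print(f"chr5 haplotype-1-only region: {bp:,} bp (~{mb} Mb); "
      f"chr5 haplotype size difference: {diff:.2f} Mb")
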