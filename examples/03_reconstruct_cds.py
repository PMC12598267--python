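"""Reconstruct a target-species CDS from short reads and judge it.

Reads are mapped onto the anchor consensus; each site is called by a
count-based rule (>= 2 informative reads and a >= 65% majority, else N).
Mapping identity/coverage below 85% flags a gene as substantially
variable — here demonstrated on a structural-variant gene whose target
genotype lacks a repeat block the anchors carry.
"""

from castatlas import compare, homology, mapping, simulate

families = simulate.make_family(n_genes=6, seed=11)

print("gene    sv_type            map_id%  map_cov%  depth  variable  accuracy%")
for fam in families:
    aln = homology.align_pair(fam.anchor1, fam.anchor2)
    tmpl = fam.anchor1 if len(fam.anchor1.cds) >= len(fam.anchor2.cds) else fam.anchor2
    cons = homology.build_consensus(
        aln, "a" if tmpl is fam.anchor1 else "b", cds_interval=tmpl.cds_interval
    )
    res = mapping.reconstruct_cds(cons, fam.reads)
    acc, frac = compare.call_accuracy(res.called_cds, fam.truth_cds)
    print(
        f"{fam.gene_id:<8}{str(fam.sv_type):<19}{res.mapping_identity_pct:>7.1f}"
        f"{res.mapping_coverage_pct:>10.1f}{res.mean_depth:>7.1f}"
        f"  {str(res.variable):<8}{acc:>9.2f}"
    )

print(
    "\nNon-SV genes: ~100% accuracy at full coverage, not flagged."
    "\nSV genes: coverage drops below 85% over the missing region -> flagged,"
    "\nmirroring how haplotype-specific deletions reveal themselves in mapping."
)
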