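"""Screen coding sequences for microsatellites and length polymorphism.

Maximal perfect tandem repeats (motifs of 1–6 nt) are detected in each
CDS; loci whose copy number differs between homologous sequences are
candidate EST-SSR markers — transferable, easily scored length
polymorphisms inside expressed genes.
"""

from castatlas import markers, simulate
from castatlas.seqio import GeneRecord

# plant a trinucleotide repeat and expand it in one lineage
import numpy as np

rng = np.random.default_rng(3)
bg = "".join(rng.choice(list("ACGT"), size=400))
wild_type = bg[:120] + "GAT" * 6 + bg[120:]
rec = GeneRecord("wt", wild_type)
expanded, _ = simulate.insert_structural_event(
    rec, ("repeat_expansion", "GAT", 4, 121)
)

for seq_id, seq in (("wild_type", wild_type), ("expanded", expanded.seq)):
    loci = markers.find_ssrs(seq, seq_id=seq_id)
    for l in loci:
        print(f"{seq_id}: ({l.motif})x{l.copies} at CDS position {l.cds_pos}")

report = markers.ssr_variability(
    [("wild_type", wild_type), ("expanded", expanded.seq)]
)
for r in report:
    status = "VARIABLE" if r["variable"] else "monomorphic"
    print(f"\n({r['motif']})n at ~{r['ref_pos']}: {r['copies']}  -> {status}")
# A copy-number difference between homologous CDS copies is exactly what
# makes the locus usable as a genetic marker on an agarose gel.
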