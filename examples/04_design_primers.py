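"""Tile a CDS with Sanger-sized amplicons.

Primer pairs obey the screening constraints (19–23 nt, GC 40–80%,
Tm 60±3 °C by the GC formula, amplicons 300–850 bp near 750) and
successive amplicons overlap by ~100 bp so Sanger reads can be stitched.
Candidates are ranked by conservation of their annealing window across
the aligned species.
"""

import numpy as np

from castatlas import markers

rng = np.random.default_rng(5)
template = "".join(rng.choice(list("ACGT"), size=1800))
cds = (151, 1641)  # a 1491 bp CDS with 150 bp flanks

pairs = markers.design_primers(template, cds, gene_id="demo")

print("pair      fwd@   rev_end  amplicon  fwd_Tm  rev_Tm  fwd_GC%  rev_GC%")
for p in pairs:
    print(
        f"{p.pair_id:<10}{p.fwd_start:<7}{p.rev_end:<9}{p.amplicon_len:<10}"
        f"{p.fwd_tm:<8.2f}{p.rev_tm:<8.2f}{p.fwd_gc:<9.1f}{p.rev_gc:.1f}"
    )
for prev, nxt in zip(pairs, pairs[1:]):
    print(f"overlap {prev.pair_id} -> {nxt.pair_id}: "
          f"{prev.rev_end - nxt.fwd_start + 1} bp")

# The theoretical product size is the screening readout: an allele with a
# 150 bp insertion between the primer sites shifts the band by exactly 150.
p = pairs[0]
mid = (p.fwd_start + p.rev_end) // 2
mutant = template[:mid] + "".join(rng.choice(list("ACGT"), size=150)) + template[mid:]
print(
    f"\npredicted product {p.pair_id}: "
    f"{markers.predicted_amplicon_size(p, template)} bp on the reference, "
    f"{markers.predicted_amplicon_size(p, mutant)} bp on a 150 bp-insertion allele"
)
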