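import numpy as np
import pytest

from castatlas import homology, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_families():
    """Six synthetic families (incl. one repeat-deletion and one
    region-loss gene), shared across tests that only read them."""
    return simulate.make_family(n_genes=6, seed=42)


@pytest.fixture(scope="session")
def family_consensus():
    """Per-gene anchor consensus for the shared family set."""
    fams = simulate.make_family(n_genes=6, seed=42)
    out = {}
    for f in fams:
        aln = homology.align_pair(f.anchor1, f.anchor2)
        tmpl = f.anchor1 if len(f.anchor1.cds) >= len(f.anchor2.cds) else f.anchor2
        cons = homology.build_consensus(
            aln,
            "a" if tmpl is f.anchor1 else "b",
            cds_interval=tmpl.cds_interval,
        )
        cons.gene_id = f.gene_id
        out[f.gene_id] = (f, cons)
    return out
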