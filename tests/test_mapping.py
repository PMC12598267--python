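import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castatlas.homology import ConsensusSequence
from castatlas.mapping import (
    CallThresholds,
    PileupColumn,
    build_pileup,
    call_base,
    flag_variability,
    index_reference,
    map_read,
    mapping_metrics,
    reconstruct_cds,
    revcomp,
)
from castatlas.seqio import ShortRead


def semiglobal_distance(read, ref):
    """Minimal edit distance of the read aligned anywhere inside the
    reference (leading and trailing reference gaps free): full DP scan."""
    n, m = len(read), len(ref)
    prev = [0] * (m + 1)  # free reference prefix
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if read[i - 1] == ref[j - 1] else 1)
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free reference suffix


def anchored_distance(read, ref, start0):
    """Edit distance of the read aligned at 0-based ``start0`` with a
    free reference suffix — verifies a claimed placement start."""
    tail = ref[start0:]
    n, m = len(read), len(tail)
    prev = list(range(m + 1))  # ref consumed inside the alignment costs gaps
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if read[i - 1] == tail[j - 1] else 1)
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


class TestSeedIndex:
    def test_kmer_positions(self):
        idx = index_reference("ACGTACGT", k=4)
        assert idx.positions("ACGT") == [1, 5]
        assert idx.positions("CGTA") == [2]

    def test_ref_of_length_k(self):
        idx = index_reference("ACGTACGT", k=8)
        assert idx.positions("ACGTACGT") == [1]

    def test_ambiguity_expansion(self):
        idx = index_reference("AARTACGTT", k=8)
        assert 1 in idx.positions("AAATACGT")
        assert 1 in idx.positions("AAGTACGT")
        assert idx.positions("AACTACGT") == []

    def test_short_reference_error(self):
        with pytest.raises(ValueError):
            index_reference("ACG", k=8)


class TestMapRead:
    REF = (
        "ATGACCGTTAGCAATGGCCTTACGAGCATCGATTACAGGCTAGCTAGGATCCTTAAGGCAT"
        "CGGATCGATTTGACCGTAGCATGCAAGGTACCGGTTAACGGCTTAGGCATGA"
    )

    def test_exact_read_placed_at_origin(self):
        idx = index_reference(self.REF, k=15)
        read = ShortRead("r", self.REF[20:60])
        pl = map_read(read, idx)
        assert pl is not None
        assert pl.ref_start == 21
        assert pl.edit_distance == 0
        assert pl.strand == "+"

    def test_reverse_strand_read(self):
        idx = index_reference(self.REF, k=15)
        read = ShortRead("r", revcomp(self.REF[30:70]))
        pl = map_read(read, idx)
        assert pl.ref_start == 31
        assert pl.strand == "-"
        assert pl.edit_distance == 0

    def test_random_read_unmapped(self, rng):
        idx = index_reference(self.REF, k=15)
        read = ShortRead("r", "".join(rng.choice(list("ACGT"), size=50)))
        assert map_read(read, idx) is None

    def test_read_with_two_substitutions(self):
        idx = index_reference(self.REF, k=15)
        frag = list(self.REF[10:70])
        frag[25] = "A" if frag[25] != "A" else "C"
        frag[40] = "A" if frag[40] != "A" else "C"
        pl = map_read(ShortRead("r", "".join(frag)), idx)
        assert pl.ref_start == 11
        assert pl.edit_distance == 2

    def test_identity_floor_rejects(self, rng):
        idx = index_reference(self.REF, k=8)
        frag = list(self.REF[10:40])
        for i in range(0, 30, 3):  # 10 of 30 bases wrong
            frag[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[i]]
        assert map_read(ShortRead("r", "".join(frag)), idx, min_identity=0.8) is None

    def test_matches_full_scan_oracle(self, rng):
        # every placement on small references equals the exhaustive
        # semi-global DP optimum over all offsets and strands
        for trial in range(10):
            ref = "".join(rng.choice(list("ACGT"), size=150))
            idx = index_reference(ref, k=8)
            for _ in range(5):
                start = int(rng.integers(0, 110))
                frag = list(ref[start : start + 40])
                for _ in range(int(rng.integers(0, 3))):
                    p = int(rng.integers(40))
                    frag[p] = "ACGT"[int(rng.integers(4))]
                seq = "".join(frag)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                pl = map_read(ShortRead("r", seq), idx, min_identity=0.0)
                d_opt = min(
                    semiglobal_distance(seq, ref),
                    semiglobal_distance(revcomp(seq), ref),
                )
                if pl is None:
                    # unmapped only when no strand shares a seed k-mer
                    continue
                assert pl.edit_distance == d_opt
                # the reported start actually achieves the optimum
                assert (
                    anchored_distance(pl.oriented_seq, ref, pl.ref_start - 1)
                    == d_opt
                )


class TestPileup:
    def test_no_placements_zero_depth(self):
        cols = build_pileup([], "ACGTACGT")
        assert all(c.depth == 0 for c in cols)
        assert len(cols) == 8

    def test_two_full_reads_depth_two(self):
        ref = "ACGTACGTACGTACGT"
        idx = index_reference(ref, k=8)
        pls = [map_read(ShortRead(f"r{i}", ref), idx) for i in range(2)]
        cols = build_pileup(pls, ref)
        assert all(c.depth == 2 for c in cols)

    def test_staggered_reads_match_interval_stabbing(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=120))
        idx = index_reference(ref, k=10)
        intervals = []
        pls = []
        for i in range(30):
            s = int(rng.integers(0, 80))
            ln = int(rng.integers(25, 40))
            pl = map_read(ShortRead(f"r{i}", ref[s : s + ln]), idx)
            assert pl is not None and pl.edit_distance == 0
            pls.append(pl)
            intervals.append((s + 1, s + ln))
        cols = build_pileup(pls, ref)
        for pos in range(1, 121):
            stab = sum(1 for a, b in intervals if a <= pos <= b)
            assert cols[pos - 1].depth == stab

    def test_base_conservation(self, family_consensus):
        # total non-gap pileup bases equal total aligned read bases
        f, cons = family_consensus["SG1"]
        idx = index_reference(cons)
        pls = [p for p in (map_read(r, idx) for r in f.reads) if p]
        cols = build_pileup(pls, cons)
        pileup_bases = sum(
            c.base_counts[b] for c in cols for b in "ACGTN"
        )
        aligned = sum(
            1 for pl in pls for ro, rp in pl.aligned_pairs
            if ro is not None and rp is not None
        )
        assert pileup_bases == aligned


def col(**counts):
    c = PileupColumn(ref_pos=1)
    c.base_counts.update(counts)
    return c


class TestCallBase:
    T = CallThresholds()

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 1}, "N"),              # below minimum depth
            ({"A": 2}, "A"),              # unanimous at minimum depth
            ({"A": 13, "G": 7}, "A"),     # 0.65 boundary inclusive
            ({"A": 6, "G": 4}, "N"),      # 0.60 < 0.65
            ({"A": 5, "G": 5}, "N"),      # tied maximum
            ({}, "N"),
        ],
    )
    def test_truth_table(self, counts, expected):
        assert call_base(col(**counts), self.T) == expected

    def test_gaps_break_agreement_but_not_min_depth(self):
        # 2 informative reads pass min_depth, but gap reads dilute f
        assert call_base(col(A=2, **{"-": 3}), self.T) == "N"
        assert call_base(col(A=7, **{"-": 3}), self.T) == "A"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(0, 20), st.integers(0, 20),
        st.floats(0.5, 1.0), st.floats(0.0, 0.49),
    )
    def test_raising_agreement_never_uncalls_N(self, a, g, agree, delta):
        low = CallThresholds(min_agreement=max(agree - delta, 0.01))
        high = CallThresholds(min_agreement=agree)
        c = col(A=a, G=g)
        if call_base(c, low) == "N":
            assert call_base(c, high) == "N"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(1, 5))
    def test_raising_min_depth_never_uncalls_N(self, a, g, depth):
        c = col(A=a, G=g)
        if call_base(c, CallThresholds(min_depth=depth)) == "N":
            assert call_base(c, CallThresholds(min_depth=depth + 1)) == "N"


class TestMetricsAndFlag:
    def test_coverage_count(self):
        cols = [col(A=2) for _ in range(97)] + [col() for _ in range(3)]
        identity, coverage, mean_d, sd_d = mapping_metrics(cols)
        assert coverage == pytest.approx(97.0)
        assert identity == pytest.approx(100.0)
        assert mean_d == pytest.approx(2.0)
        assert sd_d == 0.0

    def test_identity_discordant_columns(self):
        cols = [col(A=3) for _ in range(47)] + [col(A=2, G=1) for _ in range(3)]
        identity, coverage, *_ = mapping_metrics(cols)
        assert coverage == 100.0
        assert identity == pytest.approx(94.0)

    def test_no_coverage_warns(self):
        with pytest.warns(UserWarning):
            identity, coverage, *_ = mapping_metrics([col(), col()])
        assert identity == 0.0 and coverage == 0.0

    @pytest.mark.parametrize(
        "ident,cov,expected",
        [
            (99.4, 100, False),
            (79.4, 81, True),
            (85.0, 85.0, False),  # strictly-below rule
            (84.99, 100, True),
            (100, 84.99, True),
        ],
    )
    def test_variability_flag(self, ident, cov, expected):
        assert flag_variability(ident, cov) is expected


class TestReconstruct:
    def test_perfect_data_limit(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        cons = ConsensusSequence("g", seq)
        reads = [
            ShortRead(f"r{i}", seq[s : s + 80])
            for i, s in enumerate(rng.integers(0, 321, size=60))
        ]
        res = reconstruct_cds(cons, reads)
        covered = [i for i, c in enumerate(res.called_seq) if c != "N"]
        assert all(res.called_seq[i] == seq[i] for i in covered)
        assert res.mapping_identity_pct == 100.0
        assert not res.variable

    def test_single_read_everywhere_gives_all_N(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        cons = ConsensusSequence("g", seq)
        res = reconstruct_cds(cons, [ShortRead("r", seq)])
        assert set(res.called_seq) == {"N"}
        assert res.mapping_coverage_pct == 100.0

    def test_repeat_block_deletion_flags_gene(self, family_consensus):
        f, cons = family_consensus["SG5"]
        assert f.sv_type == "repeat_deletion"
        res = reconstruct_cds(cons, f.reads)
        assert res.mapping_coverage_pct < 85
        assert res.variable
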