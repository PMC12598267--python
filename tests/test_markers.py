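import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castatlas.markers import (
    DEFAULT_SSR_MINIMA,
    PrimerConstraints,
    PrimerDesignError,
    canonical_motif,
    conservation_track,
    design_primers,
    find_ssrs,
    gc_percent,
    melting_temp,
    predicted_amplicon_size,
    ssr_variability,
)

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(_COMP)[::-1]


def ssr_bruteforce(seq, minima=DEFAULT_SSR_MINIMA):
    """Exhaustive scan over every start and motif size: left-maximal
    perfect tandem runs with primitive motifs."""
    found = []
    n = len(seq)
    for m in range(1, 7):
        for i in range(n - 2 * m + 1):
            motif = seq[i : i + m]
            if any(c not in "ACGT" for c in motif):
                continue
            if any(m % d == 0 and motif == motif[:d] * (m // d)
                   for d in range(1, m)):
                continue
            if i > 0 and seq[i - 1] in "ACGT" and seq[i - 1] == seq[i - 1 + m]:
                continue  # extends left: not maximal
            j = i + m
            while j < n and seq[j] in "ACGT" and seq[j] == seq[j - m]:
                j += 1
            copies = (j - i) // m
            if copies >= 2 and copies * m >= minima[m]:
                found.append((i + 1, canonical_motif(motif), copies))
    return sorted(found)


class TestGCAndTm:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("GGGG", 100.0)])
    def test_gc_examples(self, seq, expected):
        assert gc_percent(seq) == expected

    def test_gc_direct_count(self):
        seq = "G" * 9 + "A" * 12  # 21-mer, 9 G/C
        assert gc_percent(seq) == pytest.approx(100 * 9 / 21)

    def test_tm_formula(self):
        seq = "GC" * 5 + "AT" * 5  # 20-mer, 10 G/C
        assert melting_temp(seq) == pytest.approx(64.9 + 41 * (10 - 16.4) / 20)
        assert melting_temp(seq) == pytest.approx(51.78)

    def test_tm_crossing_point_by_algebra(self):
        # solving Tm = 60 for nGC at length 20 gives 14.0098...; 14 G/C
        # lands just below 60 and 15 just above, bracketing the target
        n = 20
        n_gc_star = 16.4 + (60 - 64.9) * n / 41
        low = "G" * 14 + "A" * 6
        high = "G" * 15 + "A" * 5
        assert 14 < n_gc_star < 15
        assert melting_temp(low) < 60 < melting_temp(high)

    def test_tm_depends_only_on_length_and_gc(self):
        assert melting_temp("GCGCATATATATATGCGCAT") == melting_temp(
            "ATGCATGCATGCATGCATAT"
        )

    def test_tm_too_short(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACGTACGTA")


class TestConservationTrack:
    def test_column_scores(self):
        track = conservation_track(["ACA", "ACC", "ACA"])
        assert track == [1.0, 1.0, pytest.approx(2 / 3)]

    def test_gap_lowers_score(self):
        assert conservation_track(["A-", "AA", "AA"])[1] == pytest.approx(2 / 3)

    def test_window_mean_is_definitional(self):
        track = conservation_track(["AAAA", "AAAT", "AATT"])
        assert np.mean(track[1:3]) == pytest.approx((1.0 + 2 / 3) / 2)


def _balanced_template(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDesignPrimers:
    def test_single_amplicon_short_cds(self, rng):
        template = _balanced_template(rng, 720)
        pairs = design_primers(template, (151, 570), gene_id="g")  # 420 bp CDS
        assert len(pairs) == 1
        p = pairs[0]
        assert 300 <= p.amplicon_len <= 850
        assert p.fwd_start <= 151 and p.rev_end >= 570  # covers the CDS
        assert p.satisfies()

    def test_long_cds_tiles_with_overlaps(self, rng):
        template = _balanced_template(rng, 1800)
        pairs = design_primers(template, (151, 1641), gene_id="g")  # 1491 bp CDS
        assert len(pairs) >= 2
        for prev, nxt in zip(pairs, pairs[1:]):
            overlap = prev.rev_end - nxt.fwd_start + 1
            assert 70 <= overlap <= 130
        # tiling completeness: union of amplicons covers the CDS
        covered = set()
        for p in pairs:
            covered.update(range(p.fwd_start, p.rev_end + 1))
        assert set(range(151, 1642)) <= covered

    def test_every_pair_satisfies_all_constraints(self, rng):
        c = PrimerConstraints()
        for trial in range(5):
            template = _balanced_template(rng, 1400)
            try:
                pairs = design_primers(template, (151, 1250), gene_id=f"t{trial}")
            except PrimerDesignError:
                continue
            for p in pairs:
                assert c.min_len <= len(p.fwd_seq) <= c.max_len
                assert c.min_len <= len(p.rev_seq) <= c.max_len
                assert c.min_gc <= p.fwd_gc <= c.max_gc
                assert c.min_gc <= p.rev_gc <= c.max_gc
                assert abs(p.fwd_tm - 60) <= 3 and abs(p.rev_tm - 60) <= 3
                assert 300 <= p.amplicon_len <= 850

    def test_homopolymer_template_fails_structured(self):
        with pytest.raises(PrimerDesignError):
            design_primers("A" * 900, (151, 750), gene_id="polyA")

    def test_conservation_steers_primer_choice(self, rng):
        template = _balanced_template(rng, 720)
        flat = design_primers(template, (151, 570), gene_id="g")
        # degrade conservation exactly where the flat design put its
        # forward primer; the design should move off that window
        track = [1.0] * len(template)
        p = flat[0]
        for i in range(p.fwd_start - 1, p.fwd_start - 1 + len(p.fwd_seq)):
            track[i] = 0.0
        steered = design_primers(template, (151, 570), conservation=track,
                                 gene_id="g")
        assert steered[0].fwd_start != p.fwd_start


class TestAmpliconSize:
    def test_convention(self, rng):
        template = _balanced_template(rng, 900)
        pairs = design_primers(template, (151, 570), gene_id="g")
        p = pairs[0]
        assert predicted_amplicon_size(p, template) == p.rev_end - p.fwd_start + 1

    def test_adjacent_primers(self):
        fwd = "GCGCATATGCGCATATGCGC"
        rev_site = "ATATGCGCATGCGCATGCAT"
        template = fwd + rev_site
        from castatlas.markers import PrimerPair

        pair = PrimerPair("p", fwd, rc(rev_site), 1, 40, 40,
                          melting_temp(fwd), melting_temp(rc(rev_site)),
                          gc_percent(fwd), gc_percent(rc(rev_site)))
        assert predicted_amplicon_size(pair, template) == 40

    def test_insertion_grows_product_by_its_length(self, rng):
        template = _balanced_template(rng, 900)
        pairs = design_primers(template, (151, 570), gene_id="g")
        p = pairs[0]
        base = predicted_amplicon_size(p, template)
        mid = (p.fwd_start + p.rev_end) // 2
        insert = _balanced_template(rng, 150)
        mutant = template[:mid] + insert + template[mid:]
        assert predicted_amplicon_size(p, mutant) == base + 150


class TestFindSSRs:
    def test_dinucleotide_run(self):
        loci = find_ssrs("ACACACACAC")
        assert len(loci) == 1
        assert (loci[0].cds_pos, loci[0].motif, loci[0].copies) == (1, "AC", 5)

    def test_below_threshold_not_reported(self):
        assert find_ssrs("A" * 9) == []
        assert len(find_ssrs("A" * 10)) == 1

    def test_n_breaks_runs(self):
        assert find_ssrs("AAAAAN" + "AAAAA") == []

    def test_nested_reports_suppressed(self):
        loci = find_ssrs("AC" * 8)
        assert [l.motif for l in loci] == ["AC"]  # no (ACAC)n duplicate

    def test_matches_bruteforce_on_random_2kb(self, rng):
        # seed repeats into a random background so there is signal
        parts = []
        for _ in range(8):
            parts.append("".join(rng.choice(list("ACGT"), size=200)))
            m = int(rng.integers(1, 7))
            motif = "".join(rng.choice(list("ACGT"), size=m))
            parts.append(motif * int(rng.integers(4, 12)))
        seq = "".join(parts)[:2000]
        got = sorted((l.cds_pos, l.motif, l.copies) for l in find_ssrs(seq))
        assert got == ssr_bruteforce(seq)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=120),
           st.sampled_from(["A", "AC", "ACT"]), st.integers(4, 12))
    def test_reverse_complement_invariance(self, background, motif, copies):
        seq = background + motif * copies + background[::-1]
        fwd = {(l.motif, l.copies, l.length) for l in find_ssrs(seq)}
        rev = {(l.motif, l.copies, l.length) for l in find_ssrs(rc(seq))}
        # same loci up to motif complementation; coordinates mirror
        assert {(canonical_motif(rc(m)), c, ln) for m, c, ln in fwd} == rev


class TestSSRVariability:
    def test_copy_number_difference_detected(self):
        x = "GGTCCA" + "AT" * 6 + "GGACCGTTA"
        y = "GGTCCA" + "AT" * 8 + "GGACCGTTA"
        rep = ssr_variability([("x", x), ("y", y)])
        assert len(rep) == 1
        assert rep[0]["variable"]
        assert rep[0]["copies"] == {"x": 6, "y": 8}

    def test_identical_copy_numbers_not_variable(self):
        x = "GGTCCA" + "AT" * 6 + "GGACCGTTA"
        rep = ssr_variability([("x", x), ("y", x)])
        assert rep and not rep[0]["variable"]

    def test_simulated_expansion_flags_exactly_one_locus(self, rng):
        from castatlas.seqio import GeneRecord
        from castatlas.simulate import insert_structural_event

        bg = "".join(rng.choice(list("ACGT"), size=300))
        base = bg[:100] + "GAT" * 5 + bg[100:200] + "CAA" * 5 + bg[200:]
        rec = GeneRecord("wt", base)
        mut, _ = insert_structural_event(
            rec, ("repeat_expansion", "GAT", 3, 101)
        )
        rep = ssr_variability([("wt", base), ("m1", mut.seq), ("m2", base)])
        variable = [r for r in rep if r["variable"]]
        assert len(variable) == 1
        assert variable[0]["motif"] == canonical_motif("GAT")
        assert variable[0]["copies"] == {"wt": 5, "m1": 8, "m2": 5}
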