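"""Segmentation: context scanning, seed building, merge rule, bins,
autocorrelation and summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epirate as ep
from epirate.segmentation import Region


def _sites(seq, context):
    return [(s.pos, s.strand) for s in ep.scan_cytosines({"c": seq}, context)]


class TestScanCytosines:
    @pytest.mark.parametrize(
        "seq,context,expected",
        [
            ("ACGTA", "CG", [(1, "+"), (2, "-")]),
            ("AAAAA", "CG", []),
            ("AAAAA", "CHG", []),
            ("AAAAA", "CHH", []),
            ("CCGG", "CG", [(1, "+"), (2, "-")]),
            ("CCGG", "CHG", [(0, "+"), (3, "-")]),
            ("CCGG", "CHH", []),
            ("CAGTA", "CHG", [(0, "+"), (2, "-")]),
            ("CTTAA", "CHH", [(0, "+")]),
            ("NCGT", "CG", [(1, "+"), (2, "-")]),
        ],
    )
    def test_hand_enumerated_sites(self, seq, context, expected):
        assert _sites(seq, context) == expected

    def test_n_bases_never_match(self):
        assert _sites("CNG", "CHG") == []
        assert _sites("CNN", "CHH") == []

    def test_trailing_cytosines_with_undefined_context_skipped(self):
        # C at the last position cannot be classified on the forward strand
        assert _sites("AAC", "CG") == []
        # CA at the end: could be CHG or CHH, context undefined
        assert _sites("AACA", "CHH") == []

    def test_empty_sequence_set_raises(self):
        with pytest.raises(ValueError):
            ep.scan_cytosines({}, "CG")

    def test_unknown_context_raises(self):
        with pytest.raises(ValueError):
            ep.scan_cytosines({"c": "ACGT"}, "CpG")


class TestBuildSeeds:
    def test_cg_dyad(self):
        sites = ep.scan_cytosines({"c": "ACGTA"}, "CG")
        seeds = ep.build_seeds(sites, "CG")
        assert [(s.start, s.end, s.n_c) for s in seeds] == [(1, 3, 2)]

    def test_chg_triad(self):
        sites = ep.scan_cytosines({"c": "CAGTA"}, "CHG")
        seeds = ep.build_seeds(sites, "CHG")
        assert [(s.start, s.end) for s in seeds] == [(0, 3)]

    def test_chh_single_cytosine_seeds(self):
        sites = [
            ep.CytosineSite("c", 5, "+", "CHH"),
            ep.CytosineSite("c", 9, "-", "CHH"),
        ]
        seeds = ep.build_seeds(sites, "CHH")
        assert [(s.start, s.end) for s in seeds] == [(5, 6), (9, 10)]

    def test_missing_partner_raises(self):
        with pytest.raises(ValueError, match="partner"):
            ep.build_seeds([ep.CytosineSite("c", 1, "+", "CG")], "CG")


def _dyad(a):
    return Region("c", a, a + 2, "CG", [a, a + 1])


class TestMergeRegions:
    def test_two_dyads_within_reach_merge(self):
        merged = ep.merge_regions([_dyad(1), _dyad(7)])
        assert [(r.start, r.end, r.n_c) for r in merged] == [(1, 9, 4)]

    def test_gap_beyond_cap_stays_separate(self):
        merged = ep.merge_regions([_dyad(0), _dyad(200)])
        assert len(merged) == 2

    def test_span_cap_blocks_chain_merge(self):
        # left-to-right chaining at gap 88 absorbs the first three dyads;
        # adding the fourth would exceed the 185 bp cap
        merged = ep.merge_regions([_dyad(0), _dyad(90), _dyad(180), _dyad(270)])
        assert [(r.start, r.end) for r in merged] == [(0, 182), (270, 272)]

    def test_unsorted_seeds_raise(self):
        with pytest.raises(ValueError):
            ep.merge_regions([_dyad(10), _dyad(0)])

    def test_every_site_covered_once(self, small_genome):
        sequences, _, _ = small_genome
        for context in ("CG", "CHG", "CHH"):
            sites = ep.scan_cytosines(sequences, context)
            regions = ep.merge_regions(ep.build_seeds(sites, context), context=context)
            covered = sorted(p for r in regions for p in r.sites)
            assert covered == sorted(s.pos for s in sites)
            assert all(r.span <= 185 for r in regions)

    def test_idempotent_at_fixpoint(self, small_genome):
        sequences, _, _ = small_genome
        regions = ep.segment(sequences, "CG")
        again = ep.merge_regions(regions, context="CG")
        assert [(r.start, r.end) for r in again] == [
            (r.start, r.end) for r in regions
        ]


def brute_force_merge(seeds, max_span=185):
    """Oracle: repeatedly merge the globally closest admissible pair
    (smallest gap, leftmost on ties, merged span within the cap)."""
    clusters = [Region(r.chrom, r.start, r.end, r.context, list(r.sites)) for r in seeds]
    while True:
        best = None
        for i in range(len(clusters) - 1):
            gap = clusters[i + 1].start - clusters[i].end
            span = clusters[i + 1].end - clusters[i].start
            if gap > max_span or span > max_span:
                continue
            if best is None or gap < clusters[best + 1].start - clusters[best].end:
                best = i
        if best is None:
            return clusters
        a, b = clusters[best], clusters[best + 1]
        clusters[best : best + 2] = [
            Region(a.chrom, a.start, b.end, a.context, a.sites + b.sites)
        ]


class TestMergeOracle:
    def test_matches_bruteforce_on_random_genomes(self):
        rng = np.random.default_rng(42)
        contexts = ("CG", "CHG", "CHH")
        for trial in range(40):
            n = int(rng.integers(200, 2000))
            seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3]))
            context = contexts[trial % 3]
            seeds = ep.build_seeds(ep.scan_cytosines({"c": seq}, context), context)
            got = ep.merge_regions(seeds, context=context)
            want = brute_force_merge(seeds)
            assert [(r.start, r.end, sorted(r.sites)) for r in got] == [
                (r.start, r.end, sorted(r.sites)) for r in want
            ]


class TestBinGenome:
    def test_partial_final_bin_kept(self):
        bins = ep.bin_genome({"c": 250}, 100)
        assert [(b.start, b.end) for b in bins] == [(0, 100), (100, 200), (200, 250)]

    def test_sites_assigned_by_position(self):
        sites = [
            ep.CytosineSite("c", p, s, "CG")
            for p, s in [(1, "+"), (2, "-"), (150, "+"), (151, "-")]
        ]
        bins = ep.bin_genome({"c": 250}, 100, sites, "CG")
        assert [b.n_c for b in bins] == [2, 2, 0]

    def test_bins_tile_chromosome(self):
        bins = ep.bin_genome({"a": 530, "b": 100}, 100)
        for chrom, length in (("a", 530), ("b", 100)):
            spans = sorted((b.start, b.end) for b in bins if b.chrom == chrom)
            assert spans[0][0] == 0 and spans[-1][1] == length
            assert all(s2 == e1 for (_, e1), (s2, _) in zip(spans, spans[1:]))

    def test_zero_width_raises(self):
        with pytest.raises(ValueError):
            ep.bin_genome({"c": 100}, 0)


class TestAutocorrelation:
    def test_constant_levels_are_undefined(self):
        pos = np.arange(0, 40, 2)
        prof = ep.autocorrelation(pos, np.full(pos.size, 0.8), d_max=10)
        assert not prof.defined().any()

    def test_alternating_levels(self):
        pos = np.array([0, 3, 6, 9])
        lev = np.array([1.0, 0.0, 1.0, 0.0])
        prof = ep.autocorrelation(pos, lev, d_max=8)
        assert prof.r[2] == pytest.approx(-1.0)  # distance 3
        assert prof.r[5] == pytest.approx(1.0)  # distance 6

    def test_absent_distance_flagged(self):
        prof = ep.autocorrelation(np.array([0, 10]), np.array([0.2, 0.9]), d_max=5)
        assert prof.n_pairs.sum() == 0
        assert not prof.defined().any()

    def test_invalid_dmax_raises(self):
        with pytest.raises(ValueError):
            ep.autocorrelation(np.array([0]), np.array([0.5]), d_max=0)

    def test_pairs_do_not_cross_chromosomes(self):
        pos = np.array([0, 5, 0, 5])
        chroms = np.array([0, 0, 1, 1])
        lev = np.array([1.0, 0.0, 1.0, 0.0])
        prof = ep.autocorrelation(pos, lev, d_max=6, chroms=chroms)
        assert prof.n_pairs[4] == 2  # distance 5, one pair per chromosome


class TestRegionSummary:
    def test_median_and_fraction(self):
        regions = [
            Region("c", 0, 10, "CG", list(range(k)))
            for k in (2, 2, 8, 10)
        ]
        s = ep.region_summary(regions)
        assert s["median_n_c"] == 5.0
        assert s["frac_le2_c"] == 0.5
        assert s["max_n_c"] == 10

    def test_density(self):
        s = ep.region_summary([Region("c", 0, 10, "CG", [0, 3, 6, 9])])
        assert s["median_density"] == pytest.approx(0.4)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ep.region_summary([])


@given(st.lists(st.integers(0, 5000), min_size=1, max_size=60, unique=True))
def test_merge_covers_all_chh_sites(positions):
    """Completeness: every scanned cytosine lands in exactly one region."""
    sites = [ep.CytosineSite("c", p, "+", "CHH") for p in sorted(positions)]
    regions = ep.merge_regions(ep.build_seeds(sites, "CHH"), context="CHH")
    covered = sorted(p for r in regions for p in r.sites)
    assert covered == sorted(positions)
    assert all(r.span <= 185 for r in regions)
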