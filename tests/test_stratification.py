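"""Annotation labels, shape classes, chromosome zones and stratified fits."""

import numpy as np
import pandas as pd
import pytest

import epirate as ep
from epirate.segmentation import Region
from epirate.stratification import stratified_rates


def _region(start, end, chrom="c", context="CG", n_c=None):
    sites = list(range(start, start + (n_c or 2)))
    return Region(chrom, start, end, context, sites)


def _features(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "name"])


class TestAssignFeatures:
    def test_half_overlap_labels(self):
        labels = ep.assign_features(
            [_region(100, 200)], _features(("c", 150, 300, "gene", "g1"))
        )
        assert labels.iloc[0]["gene"]
        assert not labels.iloc[0]["intergenic"]

    def test_below_threshold_is_intergenic(self):
        labels = ep.assign_features(
            [_region(100, 200)], _features(("c", 161, 300, "gene", "g1"))
        )
        assert not labels.iloc[0]["gene"]
        assert labels.iloc[0]["intergenic"]

    def test_multiple_labels_allowed(self):
        labels = ep.assign_features(
            [_region(100, 200)],
            _features(("c", 100, 145, "gene", "g1"), ("c", 140, 300, "TE", "t1")),
        )
        assert labels.iloc[0]["gene"] and labels.iloc[0]["TE"]

    def test_disjoint_chromosomes_raise(self):
        with pytest.raises(ValueError, match="chromosome"):
            ep.assign_features(
                [_region(0, 10, chrom="chrX")], _features(("c", 0, 5, "gene", "g"))
            )


class TestMakePromoters:
    def test_forward_strand_upstream(self):
        genes = pd.DataFrame(
            [("c", 5000, 7000, "gene", "g1", "+")],
            columns=["chrom", "start", "end", "feature", "name", "strand"],
        )
        prom = ep.make_promoters(genes)
        assert (prom.iloc[0]["start"], prom.iloc[0]["end"]) == (3500, 5000)

    def test_reverse_strand_upstream(self):
        genes = pd.DataFrame(
            [("c", 5000, 7000, "gene", "g1", "-")],
            columns=["chrom", "start", "end", "feature", "name", "strand"],
        )
        prom = ep.make_promoters(genes)
        assert (prom.iloc[0]["start"], prom.iloc[0]["end"]) == (7000, 8500)

    def test_clamped_at_chromosome_start(self):
        genes = pd.DataFrame(
            [("c", 400, 900, "gene", "g1", "+")],
            columns=["chrom", "start", "end", "feature", "name", "strand"],
        )
        prom = ep.make_promoters(genes)
        assert (prom.iloc[0]["start"], prom.iloc[0]["end"]) == (0, 400)


class TestSplitGbm:
    def _genes(self):
        return pd.DataFrame(
            [("c", 0, 100, "gene", "g1", "+"), ("c", 200, 300, "gene", "g2", "+")],
            columns=["chrom", "start", "end", "feature", "name", "strand"],
        )

    def test_gbm_listed_gene(self):
        regions = [_region(10, 60)]
        labels = ep.assign_features(regions, self._genes())
        out = ep.split_gbM(regions, labels, self._genes(), {"g1"})
        assert out.iloc[0]["gbM_gene"]
        assert not out.iloc[0]["non_gbM_gene"]

    def test_empty_list_makes_all_non_gbm(self):
        regions = [_region(10, 60), _region(210, 260)]
        labels = ep.assign_features(regions, self._genes())
        out = ep.split_gbM(regions, labels, self._genes(), set())
        assert (~out["gbM_gene"]).all()
        assert out["non_gbM_gene"].all()

    def test_unknown_gbm_id_warns(self):
        regions = [_region(10, 60)]
        labels = ep.assign_features(regions, self._genes())
        with pytest.warns(UserWarning, match="absent"):
            ep.split_gbM(regions, labels, self._genes(), {"ghost"})

    def test_region_spanning_both_kinds_gets_both(self):
        genes = pd.DataFrame(
            [("c", 0, 100, "gene", "g1", "+"), ("c", 100, 200, "gene", "g2", "+")],
            columns=["chrom", "start", "end", "feature", "name", "strand"],
        )
        regions = [_region(60, 140)]
        labels = ep.assign_features(regions, genes)
        out = ep.split_gbM(regions, labels, genes, {"g1"})
        assert out.iloc[0]["gbM_gene"] and out.iloc[0]["non_gbM_gene"]


class TestClassifyShape:
    def test_duplet(self):
        out = ep.classify_shape([_region(1, 3, n_c=2)])
        assert out.iloc[0]["size_class"] == "duplet"
        assert out.iloc[0]["density_class"] == "NA"

    def test_dense_long_multiplet(self):
        r = Region("c", 0, 150, "CG", list(range(20)))
        out = ep.classify_shape([r])
        assert out.iloc[0]["size_class"] == "multiplet_long"
        assert out.iloc[0]["density_class"] == "dense"

    def test_span_equal_to_median_goes_short(self):
        r = Region("c", 0, 104, "CG", list(range(4)))
        out = ep.classify_shape([r])
        assert out.iloc[0]["size_class"] == "multiplet_short"

    def test_non_cg_raises(self):
        with pytest.raises(ValueError):
            ep.classify_shape([Region("c", 0, 10, "CHH", [0, 1, 2])])


class TestAssignZone:
    def _partition(self):
        return pd.DataFrame(
            [
                ("c", 0, 1000, "arm"),
                ("c", 1000, 2000, "pericentromere"),
                ("c", 2000, 3000, "centromere"),
            ],
            columns=["chrom", "start", "end", "zone"],
        )

    def test_midpoint_rule(self):
        zones = ep.assign_zone([_region(100, 200)], self._partition())
        assert zones.iloc[0] == "arm"

    def test_straddling_region_follows_midpoint(self):
        zones = ep.assign_zone([_region(950, 1150)], self._partition())
        assert zones.iloc[0] == "pericentromere"

    def test_missing_chromosome_raises(self):
        with pytest.raises(ValueError, match="missing"):
            ep.assign_zone([_region(0, 10, chrom="chr9")], self._partition())

    def test_each_region_gets_exactly_one_zone(self, small_genome):
        sequences, _, partition = small_genome
        regions = ep.segment(sequences, "CG")
        zones = ep.assign_zone(regions, partition)
        assert len(zones) == len(regions)
        assert zones.isin(["arm", "pericentromere", "centromere"]).all()


def test_region_label_proportions_match_single_cytosines():
    """Feature proportions computed over regions track the proportions over
    individual cytosines when features are placed uniformly with respect to
    cytosine density (no planted motif enrichment)."""
    sequences, annotation, _ = ep.simulate_genome(
        length=60_000, seed=11, cg_enrichment=1.0
    )
    regions = ep.segment(sequences, "CG")
    labels = ep.assign_features(regions, annotation)
    sites = ep.scan_cytosines(sequences, "CG")
    site_labels = {t: 0 for t in ("gene", "TE")}
    spans = {
        t: [(r.start, r.end) for r in annotation.itertuples(index=False) if r.feature == t]
        for t in ("gene", "TE")
    }
    for s in sites:
        for t, ivs in spans.items():
            if any(a <= s.pos < b for a, b in ivs):
                site_labels[t] += 1
    for t in ("gene", "TE"):
        frac_regions = labels[t].mean()
        frac_sites = site_labels[t] / len(sites)
        assert abs(frac_regions - frac_sites) < 0.05


class TestStratifiedRates:
    STATUS = np.array(["U", "I", "M"])

    def _calls(self, pedigree, n, alpha, beta, seed):
        states = ep.evolve_methylomes(pedigree, n, alpha, beta, seed=seed)
        return pd.DataFrame(
            {s: self.STATUS[states[s]] for s in pedigree.sequenced_samples},
            index=[f"r{i}" for i in range(n)],
        )

    def test_stratum_equal_to_whole_set_reproduces_fit(self):
        ped = ep.build_pedigree("MA1_2")
        status = self._calls(ped, 4000, 3e-4, 9e-4, seed=7)
        retained = pd.Series(True, index=status.index)
        out = stratified_rates(
            {"all": status.index, "sub": status.index},
            status, retained, ped, restarts=5, kinds=("ABneutral",),
        )
        assert out["all"].fits["ABneutral"].alpha == pytest.approx(
            out["sub"].fits["ABneutral"].alpha
        )

    def test_planted_rate_difference_recovered(self):
        """Regions simulated with 5x rates in one stratum fit higher rates
        than the baseline stratum."""
        ped = ep.build_pedigree("MA1_2")
        hi = self._calls(ped, 4000, 5 * 1.2e-4, 5 * 4.6e-4, seed=21)
        lo = self._calls(ped, 4000, 1.2e-4, 4.6e-4, seed=22)
        lo.index = [f"lo{i}" for i in range(len(lo))]
        status = pd.concat([hi, lo])
        retained = pd.Series(True, index=status.index)
        out = stratified_rates(
            {"gene": hi.index, "intergenic": lo.index},
            status, retained, ped, restarts=5, kinds=("ABneutral",),
        )
        assert (
            out["gene"].fits["ABneutral"].alpha
            > out["intergenic"].fits["ABneutral"].alpha
        )
        assert (
            out["gene"].fits["ABneutral"].beta
            > out["intergenic"].fits["ABneutral"].beta
        )

    def test_empty_stratum_skipped_with_warning(self):
        ped = ep.build_pedigree("MA1_2")
        status = self._calls(ped, 500, 3e-4, 9e-4, seed=3)
        retained = pd.Series(True, index=status.index)
        with pytest.warns(UserWarning, match="empty"):
            out = stratified_rates(
                {"ghost": pd.Index(["nope"])}, status, retained, ped,
                kinds=("ABneutral",),
            )
        assert out["ghost"].fits is None

    def test_small_stratum_flagged_unstable(self):
        ped = ep.build_pedigree("MA1_2")
        status = self._calls(ped, 2000, 1e-3, 3e-3, seed=4)
        retained = pd.Series(True, index=status.index)
        with pytest.warns(UserWarning, match="noisy"):
            out = stratified_rates(
                {"tiny": status.index[:30]}, status, retained, ped,
                min_regions=50, restarts=4, kinds=("ABneutral",),
            )
        assert not out["tiny"].stable
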