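import numpy as np
import pytest

from linksom.io_formats import GeneAnnotation, GenomicInterval
from linksom.linker import (LinkerMapping, build_domains,
                            build_linked_metaclusters, differential_lms,
                            link_regions)
from linksom.map_analysis import TraitEnrichment
from linksom.metacluster import Metaclustering
from linksom.som_core import UnitAssignment


def gene(gid, tss, chrom="chr1", strand="+"):
    return GeneAnnotation(gid, chrom, tss, strand)


class TestBuildDomains:
    def test_single_gene_gets_cutoff_both_sides(self):
        (d,) = build_domains([gene("g", 100_000)])
        assert (d.interval.start, d.interval.end) == (50_000, 150_000)

    def test_neighbors_split_at_midpoint(self):
        d1, d2 = build_domains([gene("a", 100_000), gene("b", 140_000)])
        assert (d1.interval.start, d1.interval.end) == (50_000, 120_000)
        assert (d2.interval.start, d2.interval.end) == (120_000, 190_000)

    def test_left_edge_clipped_at_zero(self):
        (d,) = build_domains([gene("g", 10_000)])
        assert d.interval.start == 0

    def test_strand_symmetric(self):
        (dp,) = build_domains([gene("g", 100_000, strand="+")])
        (dm,) = build_domains([gene("g", 100_000, strand="-")])
        assert dp.interval == dm.interval

    def test_disjoint_and_bounded(self):
        rng = np.random.default_rng(1)
        tsss = np.sort(rng.choice(2_000_000, size=30, replace=False))
        domains = build_domains([gene(f"g{i}", int(t))
                                 for i, t in enumerate(tsss)])
        ivs = sorted((d.interval.start, d.interval.end) for d in domains)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        assert all(d.interval.end - d.interval.start <= 100_000
                   for d in domains)


class TestLinkRegions:
    @pytest.fixture
    def domains(self):
        return build_domains([gene("geneA", 100_000), gene("geneB", 140_000)])

    def test_region_inside_one_domain(self, domains):
        m = link_regions([GenomicInterval("chr1", 60_000, 60_200, "r")], domains)
        assert m["r"] == "geneA"

    def test_straddle_equidistant_breaks_lexicographically(self, domains):
        # midpoint 120000 is 20 kb from both TSSs
        m = link_regions([GenomicInterval("chr1", 119_990, 120_010, "r")],
                         domains)
        assert m["r"] == "geneA"

    def test_straddle_goes_to_nearer_tss(self, domains):
        m = link_regions([GenomicInterval("chr1", 119_000, 121_000, "r")],
                         domains)
        # midpoint 120000 equidistant again; shift the region toward geneB
        m2 = link_regions([GenomicInterval("chr1", 119_900, 122_000, "r2")],
                          domains)
        assert m2["r2"] == "geneB"

    def test_unannotated_chromosome_unmapped(self, domains, caplog):
        m = link_regions([GenomicInterval("chr9", 0, 100, "r")], domains)
        assert m.get("r") is None

    def test_region_outside_all_domains_unmapped(self, domains):
        m = link_regions([GenomicInterval("chr1", 500_000, 500_100, "r")],
                         domains)
        assert len(m) == 0

    def test_one_bp_overlap_counts(self, domains):
        # domain of geneA is [50000, 120000): region starting at 119999 overlaps
        m = link_regions([GenomicInterval("chr1", 49_900, 50_001, "r")], domains)
        assert m["r"] == "geneA"


def _mock_mc(k, n_units=None):
    n = n_units or k
    labels = np.arange(n) % k
    # relabel so ids are contiguous 0..k-1 (they are, given n >= k)
    return Metaclustering(k=k, centroids=np.zeros((k, 2)), labels=labels,
                          rows=1, cols=n)


def _assignment(ids, units, cols):
    return UnitAssignment(ids, np.array(units), 1, cols)


class TestLinkedMetaclusters:
    def test_empty_mapping_gives_empty_cells(self):
        lms = build_linked_metaclusters(
            LinkerMapping({}), _mock_mc(3), _assignment(["r1"], [0], 3),
            _mock_mc(2), _assignment(["g1"], [0], 2))
        assert lms.n_cells == 6
        assert lms.n_linked_pairs() == 0

    def test_paper_scale_cell_count(self):
        lms = build_linked_metaclusters(
            LinkerMapping({}), _mock_mc(107), _assignment(["r"], [0], 107),
            _mock_mc(39), _assignment(["g"], [0], 39))
        assert lms.n_cells == 4173

    def test_toy_contents_match_hand_tabulation(self):
        # regions r1,r2 in atac mc 0; r3 in mc 1; genes g1 in rna mc 0, g2 in 1
        mapping = LinkerMapping({"r1": "g1", "r2": "g2", "r3": "g1"})
        atac_mc = _mock_mc(2, 2)
        rna_mc = _mock_mc(2, 2)
        a_assign = _assignment(["r1", "r2", "r3"], [0, 0, 1], 2)
        r_assign = _assignment(["g1", "g2"], [0, 1], 2)
        lms = build_linked_metaclusters(mapping, atac_mc, a_assign,
                                        rna_mc, r_assign)
        assert sorted(lms.cells[(0, 0)]) == [("r1", "g1")]
        assert sorted(lms.cells[(0, 1)]) == [("r2", "g2")]
        assert sorted(lms.cells[(1, 0)]) == [("r3", "g1")]
        assert lms.cells[(1, 1)] == []

    def test_missing_feature_dropped(self):
        mapping = LinkerMapping({"r1": "g1", "rX": "g1"})
        lms = build_linked_metaclusters(
            mapping, _mock_mc(2, 2), _assignment(["r1"], [0], 2),
            _mock_mc(2, 2), _assignment(["g1"], [0], 2))
        assert lms.n_linked_pairs() == 1

    def test_pair_sum_equals_linked_regions(self):
        mapping = LinkerMapping({f"r{i}": f"g{i % 3}" for i in range(9)})
        a_assign = _assignment([f"r{i}" for i in range(9)],
                               [i % 4 for i in range(9)], 4)
        r_assign = _assignment(["g0", "g1", "g2"], [0, 1, 2], 3)
        lms = build_linked_metaclusters(mapping, _mock_mc(4, 4), a_assign,
                                        _mock_mc(3, 3), r_assign)
        assert lms.n_linked_pairs() == 9
        regions = [r for pairs in lms.cells.values() for r, _ in pairs]
        assert len(regions) == len(set(regions))  # h is a function


def _enr(mc, level, p, enriched):
    return TraitEnrichment(mc, level, 1.0, 0.0, 0.5, p, enriched)


class TestDifferentialLms:
    def _lms(self):
        mapping = LinkerMapping({f"r{i}": f"g{i}" for i in range(6)})
        a_assign = _assignment([f"r{i}" for i in range(6)],
                               [i % 3 for i in range(6)], 3)
        r_assign = _assignment([f"g{i}" for i in range(6)],
                               [i % 2 for i in range(6)], 2)
        return build_linked_metaclusters(mapping, _mock_mc(3, 3), a_assign,
                                         _mock_mc(2, 2), r_assign)

    def test_no_enrichment_gives_empty(self):
        lms = self._lms()
        assert differential_lms(lms, [_enr(0, "a", 0.5, False)],
                                [_enr(0, "a", 0.5, False)]) == []

    def test_upper_bound_product_of_enriched(self):
        lms = self._lms()
        atac = [_enr(i, "a", 1e-6, True) for i in (0, 1)]
        rna = [_enr(j, "a", 1e-6, True) for j in (0, 1)]
        diff = differential_lms(lms, atac, rna, min_regions=0)
        assert len(diff) <= 4
        assert all(i in (0, 1) and j in (0, 1) for i, j in diff)

    def test_min_regions_floor(self):
        lms = self._lms()
        atac = [_enr(i, "a", 1e-6, True) for i in range(3)]
        rna = [_enr(j, "a", 1e-6, True) for j in range(2)]
        diff = differential_lms(lms, atac, rna, min_regions=1)
        assert set(diff) == {(i, j) for (i, j), pairs in lms.cells.items()
                             if pairs}
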