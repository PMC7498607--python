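import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import DissimilarityMatrix
from skbio.tree import nj as skbio_nj

from oracle_utils import random_additive_tree
from ssrmine.diversity import (
    bipartitions,
    bootstrap_nj,
    gst,
    locus_stats,
    nei_distance,
    nj_tree,
    pic_from_freqs,
    shared_allele_distance,
)
from ssrmine.io_core import GenotypeTable
from ssrmine.simulate import make_genotypes


def _table(calls_by_ind, loci):
    inds = list(calls_by_ind)
    calls = {}
    for ind, row in calls_by_ind.items():
        for locus, call in zip(loci, row):
            calls[(ind, locus)] = call
    return GenotypeTable(inds, loci, calls)


class TestLocusStats:
    def test_botstein_hand_values_at_half_half(self):
        gt = _table({"i1": [(100, 100)], "i2": [(106, 106)]}, ["L1"])
        s = locus_stats(gt, "L1")
        assert s.he == pytest.approx(0.5)
        assert s.pic == pytest.approx(0.375)  # 1 - 0.5 - 2(0.25)(0.25)

    def test_monomorphic_locus(self):
        gt = _table({"i1": [(100, 100)], "i2": [(100, 100)]}, ["L1"])
        s = locus_stats(gt, "L1")
        assert (s.he, s.ho, s.pic) == (0.0, 0.0, 0.0)
        assert s.f is None

    def test_all_heterozygous_f_is_minus_one(self):
        gt = _table({f"i{k}": [(100, 106)] for k in range(6)}, ["L1"])
        s = locus_stats(gt, "L1")
        assert s.ho == 1.0 and s.f == pytest.approx(-1.0)

    def test_missing_calls_excluded_not_dropped_silently(self):
        gt = _table({"i1": [(100, 106)], "i2": [None]}, ["L1"])
        s = locus_stats(gt, "L1")
        assert s.ho == 1.0

    def test_all_missing_rejected(self):
        gt = _table({"i1": [None]}, ["L1"])
        with pytest.raises(ValueError):
            locus_stats(gt, "L1")


class TestNeiDistance:
    def test_identical_groups_distance_zero(self):
        gt = _table(
            {"a1": [(100, 106)], "a2": [(100, 106)], "b1": [(100, 106)], "b2": [(100, 106)]},
            ["L1"],
        )
        assert nei_distance(gt, ["a1", "a2"], ["b1", "b2"]) == pytest.approx(0.0)

    def test_disjoint_allele_sets_infinite(self):
        gt = _table({"a1": [(100, 100)], "b1": [(200, 200)]}, ["L1"])
        assert math.isinf(nei_distance(gt, ["a1"], ["b1"]))

    def test_hand_computed_two_locus_fixture(self):
        # group x: L1 p(100)=0.75, p(104)=0.25; L2 fixed 200
        # group y: L1 p(100)=0.25, p(104)=0.75; L2 fixed 200
        gt = _table(
            {
                "x1": [(100, 100), (200, 200)],
                "x2": [(100, 104), (200, 200)],
                "y1": [(104, 104), (200, 200)],
                "y2": [(100, 104), (200, 200)],
            },
            ["L1", "L2"],
        )
        jx = ((0.75**2 + 0.25**2) + 1.0) / 2
        jy = jx
        jxy = ((0.75 * 0.25 + 0.25 * 0.75) + 1.0) / 2
        expected = -math.log(jxy / math.sqrt(jx * jy))
        assert nei_distance(gt, ["x1", "x2"], ["y1", "y2"]) == pytest.approx(expected)


class TestGst:
    def test_identical_groups_zero(self):
        gt = _table(
            {"a1": [(100, 106)], "a2": [(100, 100)], "b1": [(100, 106)], "b2": [(100, 100)]},
            ["L1"],
        )
        assert gst(gt, {"A": ["a1", "a2"], "B": ["b1", "b2"]}) == pytest.approx(0.0)

    def test_fixed_different_alleles_full_differentiation(self):
        # H_S = 0, H_T = 0.5 from pooled mean frequencies => G_ST = 1
        gt = _table({"a1": [(100, 100)], "b1": [(106, 106)]}, ["L1"])
        assert gst(gt, {"A": ["a1"], "B": ["b1"]}) == pytest.approx(1.0)

    def test_recovers_generating_differentiation_under_drift(self):
        freqs = {
            "A": {"L1": {100: 0.9, 106: 0.1}, "L2": {100: 0.8, 106: 0.2}},
            "B": {"L1": {100: 0.2, 106: 0.8}, "L2": {100: 0.35, 106: 0.65}},
        }
        gt, groups = make_genotypes(freqs, {"A": 300, "B": 300}, seed=5)
        # expectation from the generating frequencies
        hs = ht = 0.0
        for locus in ("L1", "L2"):
            pa = [freqs["A"][locus][a] for a in (100, 106)]
            pb = [freqs["B"][locus][a] for a in (100, 106)]
            hs += ((1 - sum(p * p for p in pa)) + (1 - sum(p * p for p in pb))) / 2
            pooled = [(x + y) / 2 for x, y in zip(pa, pb)]
            ht += 1 - sum(p * p for p in pooled)
        expected = (ht - hs) / ht
        assert gst(gt, groups) == pytest.approx(expected, abs=0.05)


class TestNjTree:
    def test_three_taxon_branch_lengths(self):
        dm = DistanceMatrix(
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("ABC")
        )
        tree = nj_tree(dm)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_asymmetric_matrix_rejected(self):
        m = DissimilarityMatrix(np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], float), list("ABC"))
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(m)

    def test_topology_agrees_with_skbio_reference(self, rng):
        labels, mat, _ = random_additive_tree(8, rng)
        dm = DistanceMatrix(np.array(mat), ids=labels)
        assert bipartitions(nj_tree(dm)) == bipartitions(skbio_nj(dm))

    def test_recovers_additive_distances_exactly(self, rng):
        labels, mat, biparts = random_additive_tree(7, rng)
        tree = nj_tree(DistanceMatrix(np.array(mat), ids=labels))
        got = tree.tip_tip_distances()
        order = [list(got.ids).index(l) for l in labels]
        reordered = got.data[np.ix_(order, order)]
        assert np.allclose(reordered, np.array(mat), atol=1e-9)
        assert bipartitions(tree) == biparts


class TestBootstrapNj:
    def _two_pop_table(self):
        freqs = {
            "p1": {f"L{i}": {100: 0.95, 130: 0.05} for i in range(8)},
            "p2": {f"L{i}": {130: 0.95, 160: 0.05} for i in range(8)},
        }
        return make_genotypes(freqs, {"p1": 6, "p2": 6}, seed=11)

    def test_single_locus_supports_all_100(self):
        gt = _table(
            {
                "i1": [(100, 100)],
                "i2": [(100, 102)],
                "i3": [(104, 106)],
                "i4": [(104, 104)],
            },
            ["L1"],
        )
        gt2 = GenotypeTable(gt.individuals, ["L1", "L1b"], {
            **gt.calls, **{(i, "L1b"): gt.calls[(i, "L1")] for i in gt.individuals}
        })
        tree = bootstrap_nj(gt2, reps=25, seed=3)
        supports = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert supports and all(s == 100 for s in supports)

    def test_seeded_reproducibility(self):
        gt, _ = self._two_pop_table()
        t1 = bootstrap_nj(gt, reps=30, seed=9)
        t2 = bootstrap_nj(gt, reps=30, seed=9)
        assert str(t1) == str(t2)

    def test_reps_below_one_rejected(self):
        gt, _ = self._two_pop_table()
        with pytest.raises(ValueError):
            bootstrap_nj(gt, reps=0, seed=1)


def test_shared_allele_distance_bounds():
    gt = _table(
        {"i1": [(100, 106)], "i2": [(100, 106)], "i3": [(200, 202)]},
        ["L1"],
    )
    dm = shared_allele_distance(gt)
    assert dm["i1", "i2"] == 0.0
    assert dm["i1", "i3"] == 1.0


def test_pic_from_freqs_hand_value():
    assert pic_from_freqs([0.5, 0.5]) == pytest.approx(0.375)
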