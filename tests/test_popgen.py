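"""Bruvo distances, clone collapsing, clustering and neighbor joining."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssu1_checkup.popgen import (
    DistanceMatrix,
    LocusDef,
    MicrosatTable,
    bruvo_locus_distance,
    bruvo_matrix,
    cluster_kmeans_bic,
    collapse_clones,
    filter_by_locus_coverage,
    heterozygosity_profile,
    nj_tree,
)
from ssu1_checkup.simulate import SimConfig, gen_microsat_population

DI = LocusDef("d", 2)
TRI = LocusDef("t", 3)


def bruvo_oracle(a, b, motif_len):
    """Brute-force minimal matching over all allele permutations."""
    def d(x, y):
        return 1.0 - 2.0 ** (-round(abs(x - y) / motif_len))

    best = None
    for perm in itertools.permutations(range(len(b))):
        mean = sum(d(a[i], b[j]) for i, j in enumerate(perm)) / len(a)
        best = mean if best is None else min(best, mean)
    return best


def make_table(genotypes, loci=None):
    """genotypes: dict strain -> list of (a1, a2) or None per locus."""
    strains = list(genotypes)
    n_loci = len(next(iter(genotypes.values())))
    loci = loci or [LocusDef(f"L{j}", 2) for j in range(n_loci)]
    arr = np.full((len(strains), n_loci, 2), np.nan)
    for i, s in enumerate(strains):
        for j, pair in enumerate(genotypes[s]):
            if pair is not None:
                arr[i, j] = pair
    return MicrosatTable(strains, loci, arr)


class TestLocusCoverageFilter:
    def test_threshold_is_inclusive(self):
        full = [(100.0, 102.0)] * 15
        geno = {
            "keep15": full,
            "keep12": full[:12] + [None] * 3,
            "drop11": full[:11] + [None] * 4,
        }
        t = filter_by_locus_coverage(make_table(geno), min_loci=12)
        assert t.strains == ["keep15", "keep12"]

    def test_all_missing_gives_empty_table(self):
        t = make_table({"a": [None] * 15, "b": [None] * 15})
        assert len(filter_by_locus_coverage(t)) == 0

    def test_min_loci_beyond_panel_rejected(self):
        t = make_table({"a": [(100.0, 100.0)] * 3})
        with pytest.raises(ValueError):
            filter_by_locus_coverage(t, min_loci=4)


class TestBruvoLocusDistance:
    def test_identity_is_zero(self):
        assert bruvo_locus_distance((180, 186), (180, 186), TRI) == 0.0

    def test_single_step_half(self):
        mono = LocusDef("m", 1)
        # haploid-style: alleles one repeat step apart give 1 - 2^-1 = 0.5
        assert bruvo_locus_distance((10, 10), (11, 11), mono) == pytest.approx(0.5)
        # (10,10) vs (10,12) in repeat units: min matching mean(0, 1-2^-2)
        assert bruvo_locus_distance((10, 10), (10, 12), mono) == pytest.approx(0.375)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            motif = int(rng.integers(1, 5))
            a = tuple(motif * rng.integers(10, 40, size=2))
            b = tuple(motif * rng.integers(10, 40, size=2))
            locus = LocusDef("x", motif)
            assert bruvo_locus_distance(a, b, locus) == pytest.approx(
                bruvo_oracle(a, b, motif)
            )

    @given(
        a=st.tuples(st.integers(5, 60), st.integers(5, 60)),
        b=st.tuples(st.integers(5, 60), st.integers(5, 60)),
        motif=st.integers(1, 4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_bounded_zero_iff_identical(self, a, b, motif):
        locus = LocusDef("x", motif)
        av = tuple(motif * x for x in a)
        bv = tuple(motif * x for x in b)
        d_ab = bruvo_locus_distance(av, bv, locus)
        assert d_ab == bruvo_locus_distance(bv, av, locus)
        assert 0.0 <= d_ab < 1.0
        assert (d_ab == 0.0) == (sorted(av) == sorted(bv))

    def test_zero_motif_rejected(self):
        with pytest.raises(ValueError):
            LocusDef("x", 0)


class TestBruvoMatrix:
    def test_identical_strains_distance_zero(self):
        t = make_table({"a": [(100, 104)] * 15, "b": [(100, 104)] * 15})
        assert bruvo_matrix(t).d("a", "b") == 0.0

    def test_one_locus_one_step_among_fifteen(self):
        g = [(100.0, 100.0)] * 15
        # both alleles shifted one repeat step at one locus: 0.5 / 15
        g2 = list(g)
        g2[0] = (102.0, 102.0)
        t = make_table({"a": g, "b": g2})
        assert bruvo_matrix(t).d("a", "b") == pytest.approx(0.5 / 15)
        # one allele shifted: minimal matching averages (0 + 0.5) / 2
        g3 = list(g)
        g3[0] = (100.0, 102.0)
        t2 = make_table({"a": g, "b": g3})
        assert bruvo_matrix(t2).d("a", "b") == pytest.approx(0.25 / 15)

    def test_pairwise_complete_locus_averaging(self):
        # second locus missing in b: average over the shared locus only
        t = make_table({"a": [(10, 10), (20, 20)], "b": [(12, 12), None]})
        assert bruvo_matrix(t).d("a", "b") == pytest.approx(0.5)

    def test_no_shared_loci_flagged(self):
        t = make_table({"a": [(10, 10), None], "b": [None, (20, 20)]})
        m = bruvo_matrix(t)
        assert np.isnan(m.d("a", "b"))
        assert m.missing_pairs == [("a", "b")]

    def test_matches_per_pair_recomputation(self):
        t, _ = gen_microsat_population(SimConfig(seed=3, n_lineages=2, clone_size=3))
        m = bruvo_matrix(t)
        for i, a in enumerate(t.strains):
            for j, b in enumerate(t.strains):
                if i >= j:
                    continue
                per_locus = [
                    bruvo_oracle(tuple(t.alleles[i, jj]), tuple(t.alleles[j, jj]), t.loci[jj].motif_len)
                    for jj in range(len(t.loci))
                ]
                assert m.d(a, b) == pytest.approx(np.mean(per_locus))


class TestCollapseClones:
    def dm(self, ids, pairs):
        n = len(ids)
        vals = np.zeros((n, n))
        for (a, b), d in pairs.items():
            i, j = ids.index(a), ids.index(b)
            vals[i, j] = vals[j, i] = d
        return DistanceMatrix(ids, vals)

    def test_identical_strains_collapse_to_one(self):
        m = self.dm(["a", "b", "c"], {("a", "b"): 0.0, ("a", "c"): 0.0, ("b", "c"): 0.0})
        cs = collapse_clones(m)
        assert cs.representatives == ["a"]
        assert cs.clones_removed == ["b", "c"]

    def test_cutoff_is_strict(self):
        m = self.dm(["a", "b"], {("a", "b"): 0.16})
        assert len(collapse_clones(m, 0.15).components) == 2
        m2 = self.dm(["a", "b"], {("a", "b"): 0.15})
        assert len(collapse_clones(m2, 0.15).components) == 2  # d < threshold only
        m3 = self.dm(["a", "b"], {("a", "b"): 0.14})
        assert len(collapse_clones(m3, 0.15).components) == 1

    def test_single_linkage_chain(self):
        m = self.dm(
            ["a", "b", "c"],
            {("a", "b"): 0.1, ("b", "c"): 0.1, ("a", "c"): 0.2},
        )
        cs = collapse_clones(m, 0.15)
        assert cs.components == [["a", "b", "c"]]

    def test_output_partitions_strains(self):
        t, _ = gen_microsat_population(SimConfig(seed=9))
        cs = collapse_clones(bruvo_matrix(t))
        flat = sorted(s for c in cs.components for s in c)
        assert flat == sorted(t.strains)
        for rep, comp in zip(cs.representatives, cs.components):
            assert rep in comp


class TestHeterozygosity:
    def test_counts_and_diploid_flag(self):
        t = make_table(
            {
                "hom": [(10, 10), (20, 20), (30, 30)],
                "het2": [(10, 12), (20, 22), (30, 30)],
                "miss": [(10, 12), None, None],
            }
        )
        prof = {p["strain"]: p for p in heterozygosity_profile(t)}
        assert prof["hom"]["het_loci"] == 0 and not prof["hom"]["inferred_diploid"]
        assert prof["het2"]["het_loci"] == 2 and prof["het2"]["inferred_diploid"]
        assert prof["miss"]["het_loci"] == 1 and not prof["miss"]["inferred_diploid"]


class TestClusterKmeansBic:
    def test_two_separated_lineages_recovered(self):
        cfg = SimConfig(seed=2, n_lineages=2, clone_size=10, vntr_rate=0.4, loh_rate=0.05)
        t, truth = gen_microsat_population(cfg)
        res = cluster_kmeans_bic(t, k_max=5, seed=2)
        assert res.best_k == 2
        # purity up to relabeling
        by_group = {}
        for s, g in res.assignment.items():
            by_group.setdefault(g, set()).add(truth.lineage[s])
        assert all(len(v) == 1 for v in by_group.values())

    def test_identical_strains_give_k1(self):
        t = make_table({f"s{i}": [(10, 10), (20, 20)] for i in range(5)})
        res = cluster_kmeans_bic(t, k_max=3, seed=0)
        assert res.best_k == 1
        assert set(res.assignment.values()) == {0}

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=4, n_lineages=3, clone_size=5, vntr_rate=0.3)
        t, _ = gen_microsat_population(cfg)
        r1 = cluster_kmeans_bic(t, k_max=4, seed=7)
        r2 = cluster_kmeans_bic(t, k_max=4, seed=7)
        assert r1.assignment == r2.assignment
        assert r1.bic == r2.bic

    def test_wss_non_increasing_in_k(self):
        cfg = SimConfig(seed=4, n_lineages=3, clone_size=5, vntr_rate=0.3)
        t, _ = gen_microsat_population(cfg)
        res = cluster_kmeans_bic(t, k_max=5, seed=1)
        wss = [res.wss[k] for k in sorted(res.wss)]
        assert all(b <= a + 1e-9 for a, b in zip(wss, wss[1:]))

    def test_k_max_beyond_n_rejected(self):
        t = make_table({"a": [(10, 10)], "b": [(12, 12)]})
        with pytest.raises(ValueError):
            cluster_kmeans_bic(t, k_max=3, seed=0)


class TestNeighborJoining:
    def test_additive_tree_distances_recovered(self):
        # tip-tip distances from the tree ((A:1,B:2):1,C:3,D:4)
        ids = ["A", "B", "C", "D"]
        vals = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        from skbio import TreeNode
        import io as _io

        newick = nj_tree(DistanceMatrix(ids, vals))
        tree = TreeNode.read(_io.StringIO(newick))
        dm = tree.tip_tip_distances(list("ABCD"))
        assert np.allclose(dm.data, vals)

    def test_three_taxa_star(self):
        ids = ["a", "b", "c"]
        vals = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        newick = nj_tree(DistanceMatrix(ids, vals))
        assert all(x in newick for x in ids)

    def test_order_invariant_topology(self):
        t, _ = gen_microsat_population(SimConfig(seed=6, n_lineages=3, clone_size=2, vntr_rate=0.3))
        m = bruvo_matrix(t)
        from skbio import TreeNode
        import io as _io

        t1 = TreeNode.read(_io.StringIO(nj_tree(m)))
        perm = list(reversed(range(len(m.ids))))
        m2 = DistanceMatrix([m.ids[i] for i in perm], m.values[np.ix_(perm, perm)])
        t2 = TreeNode.read(_io.StringIO(nj_tree(m2)))
        assert t1.compare_rfd(t2) == 0.0

    def test_missing_distance_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], vals))
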