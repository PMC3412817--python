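import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import braycurtis as scipy_bc, jaccard as scipy_jac

from conftest import random_binary_tree
from vrbench.community_comparison import (
    bray_curtis,
    dataset_pca,
    jaccard_distance,
    nj_tree,
    otu_cluster,
    sample_distance_matrix,
    sample_feature_counts,
    unifrac,
    unifrac_matrix,
)


def naive_average_linkage(dist, ids, cutoff):
    """Brute-force agglomerative average-linkage clustering oracle."""
    clusters = [{i} for i in range(len(ids))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i][j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        if best[0] > cutoff:
            break
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return {frozenset(ids[i] for i in c) for c in clusters}


class TestOTUCluster:
    def test_below_cutoff_merges(self):
        d = np.array([[0, 0.02], [0.02, 0]])
        assert otu_cluster(d, ["a", "b"]).n_otus == 1

    def test_above_cutoff_separates(self):
        d = np.array([[0, 0.05], [0.05, 0]])
        assert otu_cluster(d, ["a", "b"]).n_otus == 2

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            x = rng.random((n, 3)) * 0.05
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0)
            ids = [f"s{i}" for i in range(n)]
            part = otu_cluster(d, ids, cutoff=0.03)
            assert part.as_sets() == naive_average_linkage(d, ids, 0.03)

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            otu_cluster(d, ["a", "b"])


class TestAbundanceMetrics:
    def test_identical_vectors(self):
        u = np.array([2.0, 1.0, 3.0])
        assert bray_curtis(u, u) == 0.0
        assert jaccard_distance(u, u) == 0.0

    def test_disjoint_supports(self):
        u, v = np.array([1.0, 0.0]), np.array([0.0, 4.0])
        assert bray_curtis(u, v) == 1.0
        assert jaccard_distance(u, v) == 1.0

    def test_hand_arithmetic(self):
        u, v = np.array([2.0, 0.0, 1.0]), np.array([1.0, 1.0, 0.0])
        assert bray_curtis(u, v) == pytest.approx(0.6)
        assert jaccard_distance(u, v) == pytest.approx(1 - 1 / 3)

    def test_all_zero_is_undefined(self):
        z = np.zeros(3)
        assert math.isnan(bray_curtis(z, z))
        assert math.isnan(jaccard_distance(z, z))

    def test_agrees_with_scipy(self, rng):
        for _ in range(20):
            u = rng.integers(0, 10, size=6).astype(float)
            v = rng.integers(0, 10, size=6).astype(float)
            if (u + v).sum() == 0:
                continue
            assert bray_curtis(u, v) == pytest.approx(scipy_bc(u, v))
            assert jaccard_distance(u, v) == pytest.approx(
                scipy_jac(u > 0, v > 0)
            )


def _tip_distances(tree):
    names = sorted(t.name for t in tree.tips())
    out = {}
    for a, b in itertools.combinations(names, 2):
        out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(ab)=0.3, d(ac)=0.5, d(bc)=0.6 -> a=0.1, b=0.2, c=0.4
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(d, ["a", "b", "c"])
        td = _tip_distances(tree)
        assert td[("a", "b")] == pytest.approx(0.3, abs=1e-9)
        assert td[("a", "c")] == pytest.approx(0.5, abs=1e-9)
        assert td[("b", "c")] == pytest.approx(0.6, abs=1e-9)

    def test_additive_four_taxon_recovery(self, rng):
        # build a known quartet ((a,b),(c,d)) with explicit branch lengths
        la, lb, lc, ld, lm = 0.1, 0.2, 0.15, 0.25, 0.3
        names = ["a", "b", "c", "d"]
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = la + lb
        d[0, 2] = d[2, 0] = la + lm + lc
        d[0, 3] = d[3, 0] = la + lm + ld
        d[1, 2] = d[2, 1] = lb + lm + lc
        d[1, 3] = d[3, 1] = lb + lm + ld
        d[2, 3] = d[3, 2] = lc + ld
        tree = nj_tree(d, names)
        td = _tip_distances(tree)
        for (i, j) in itertools.combinations(range(4), 2):
            pair = tuple(sorted((names[i], names[j])))
            assert td[pair] == pytest.approx(d[i, j], abs=1e-9)

    def test_equidistant_matrix_gives_equal_pendants(self):
        d = np.full((4, 4), 0.4)
        np.fill_diagonal(d, 0)
        tree = nj_tree(d, list("abcd"))
        pend = [t.length for t in tree.tips()]
        assert all(p == pytest.approx(0.2, abs=1e-9) for p in pend)
        td = _tip_distances(tree)
        assert all(v == pytest.approx(0.4, abs=1e-9) for v in td.values())

    def test_two_taxa_trivial_tree(self):
        tree = nj_tree(np.array([[0, 0.2], [0.2, 0]]), ["a", "b"])
        assert {t.name for t in tree.tips()} == {"a", "b"}


def brute_force_unifrac(tree, counts_a, counts_b, weighted):
    """Independent branch-enumeration oracle."""
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    num = denom = 0.0
    for node in tree.traverse(include_self=False):
        b = node.length or 0.0
        leaves = {t.name for t in node.tips()} or {node.name}
        ca = sum(counts_a.get(l, 0) for l in leaves)
        cb = sum(counts_b.get(l, 0) for l in leaves)
        if weighted:
            pa, pb = ca / tot_a, cb / tot_b
            num += b * abs(pa - pb)
            denom += b * (pa + pb)
        else:
            if (ca > 0) != (cb > 0):
                num += b
            if ca > 0 or cb > 0:
                denom += b
    return num / denom if denom > 0 else math.nan


class TestUniFrac:
    def test_identical_samples_are_zero(self, rng):
        tree = random_binary_tree(6, rng)
        counts = {t.name: int(rng.integers(1, 20)) for t in tree.tips()}
        assert unifrac(tree, counts, counts, weighted=False) == 0.0
        assert unifrac(tree, counts, counts, weighted=True) == 0.0

    def test_disjoint_root_clades_give_unweighted_one(self):
        tree = skbio.TreeNode.read(["((a:0.1,b:0.2):0.3,(c:0.2,d:0.1):0.4);"])
        sa = {"a": 5, "b": 3}
        sb = {"c": 2, "d": 9}
        assert unifrac(tree, sa, sb, weighted=False) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            tree = random_binary_tree(n, rng)
            leaves = [t.name for t in tree.tips()]
            ca = {l: int(rng.integers(0, 15)) for l in leaves}
            cb = {l: int(rng.integers(0, 15)) for l in leaves}
            if sum(ca.values()) == 0 or sum(cb.values()) == 0:
                continue
            for weighted in (False, True):
                mine = unifrac(tree, ca, cb, weighted=weighted)
                oracle = brute_force_unifrac(tree, ca, cb, weighted)
                assert mine == pytest.approx(oracle, abs=1e-12)

    def test_empty_sample_is_undefined(self, rng):
        tree = random_binary_tree(4, rng)
        leaves = [t.name for t in tree.tips()]
        full = {l: 1 for l in leaves}
        assert math.isnan(unifrac(tree, full, {}, weighted=False))


class TestSampleFeatures:
    def test_counts_aggregate_by_feature(self):
        samples = {"s1": {"a": 3, "b": 2}, "s2": {"b": 1, "c": 4}}
        feats = sample_feature_counts(samples, {"a": "X", "b": "X", "c": "Y"})
        assert feats.loc["s1", "X"] == 5 and feats.loc["s2", "Y"] == 4

    def test_distance_matrix_metrics(self):
        df = pd.DataFrame([[2, 0, 1], [1, 1, 0]], index=["s1", "s2"],
                          columns=list("abc"))
        bc = sample_distance_matrix(df, "braycurtis")
        # computed on relative abundances
        u = np.array([2, 0, 1]) / 3
        v = np.array([1, 1, 0]) / 2
        assert bc[0, 1] == pytest.approx(bray_curtis(u, v))
        jc = sample_distance_matrix(df, "jaccard")
        assert jc[0, 1] == pytest.approx(1 - 1 / 3)


class TestDatasetPCA:
    def _random_sets(self, rng, n_datasets=4, n_samples=6):
        out = {}
        for k in range(n_datasets):
            x = rng.random((n_samples, 3))
            m = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            np.fill_diagonal(m, 0)
            out[f"D{k}"] = m
        return out

    def test_identical_datasets_identical_coordinates(self, rng):
        sets = self._random_sets(rng, 3)
        sets["D1"] = sets["D0"].copy()
        res = dataset_pca(sets)
        np.testing.assert_allclose(
            res.coordinates.loc["D0"], res.coordinates.loc["D1"], atol=1e-9
        )

    def test_small_noise_keeps_coordinates_close(self, rng):
        sets = self._random_sets(rng, 3)
        noise = rng.normal(0, 1e-4, size=sets["D0"].shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        sets["D1"] = np.abs(sets["D0"] + noise)
        res = dataset_pca(sets)
        d = np.linalg.norm(res.coordinates.loc["D0"] - res.coordinates.loc["D1"])
        assert d < 0.01

    def test_explained_variance_matches_eigen_oracle(self, rng):
        sets = self._random_sets(rng, 5)
        res = dataset_pca(sets)
        iu = np.triu_indices(6, k=1)
        X = np.stack([sets[k][iu] for k in sets])
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        eig = eig[eig > 1e-12]
        oracle = eig[0] / eig.sum()
        assert res.explained_variance_ratio[0] == pytest.approx(oracle, abs=1e-9)

    def test_fewer_than_two_datasets_rejected(self, rng):
        with pytest.raises(ValueError, match="2 datasets"):
            dataset_pca({"only": np.zeros((3, 3))})

    def test_distances_to_reference(self, rng):
        sets = self._random_sets(rng, 3)
        res = dataset_pca(sets)
        d = res.distances_to("D0")
        assert set(d.index) == {"D1", "D2"}
        assert (d >= 0).all()
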