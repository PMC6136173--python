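"""Tests of diversity, distances, ordination, permutation fits, Mantel,
UPGMA and intensity preprocessing, with scikit-bio as independent oracle
for PCoA and the Mantel statistic."""

import numpy as np
import pandas as pd
import pytest

from viromescope.ecology import (
    DistanceMatrix,
    alpha_diversity,
    autoscale,
    bray_curtis,
    euclidean_distance,
    factor_fit,
    mantel,
    pcoa,
    presence_filter,
    upgma,
    vector_fit,
)


class TestAlphaDiversity:
    def test_uniform_community_maximal_evenness(self):
        a = alpha_diversity([0.25, 0.25, 0.25, 0.25])
        assert a.richness == 4
        assert a.shannon_h == pytest.approx(np.log(4))
        assert a.pielou_j == pytest.approx(1.0)

    def test_single_taxon(self):
        a = alpha_diversity([1, 0, 0])
        assert (a.richness, a.shannon_h, a.pielou_j) == (1, 0.0, 0.0)

    def test_skewed_community_formula(self):
        a = alpha_diversity([0.5, 0.25, 0.25])
        h = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert a.shannon_h == pytest.approx(h)  # ~1.0397
        assert a.pielou_j == pytest.approx(h / np.log(3))  # ~0.9464

    def test_all_zero_row_warns(self):
        with pytest.warns(UserWarning):
            a = alpha_diversity([0.0, 0.0])
        assert (a.richness, a.shannon_h, a.pielou_j) == (0, 0.0, 0.0)

    def test_scale_invariance(self):
        a = alpha_diversity([5, 3, 2])
        b = alpha_diversity([0.5, 0.3, 0.2])
        assert a.shannon_h == pytest.approx(b.shannon_h)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(m).data[0, 1] == 0.0

    def test_disjoint_support_one(self):
        m = pd.DataFrame([[1, 0], [0, 2]], index=["a", "b"])
        assert bray_curtis(m).data[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        m = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"])
        assert bray_curtis(m).data[0, 1] == pytest.approx(4 / 12)

    def test_zero_row_pair_defined_zero_with_warning(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=["a", "b", "c"])
        with pytest.warns(UserWarning):
            d = bray_curtis(m)
        assert d.data[0, 1] == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(pd.DataFrame([[-1, 2], [1, 1]]))

    def test_common_scale_invariance_and_bounds(self, rng):
        x = rng.random((6, 10))
        d1 = bray_curtis(pd.DataFrame(x)).data
        d2 = bray_curtis(pd.DataFrame(7.3 * x)).data
        np.testing.assert_allclose(d1, d2)
        assert (d1 >= 0).all() and (d1 <= 1).all()
        np.testing.assert_allclose(d1, d1.T)


class TestPcoa:
    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_identical_points_no_axes(self):
        d = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        res = pcoa(d)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(6, 2))
        d = euclidean_distance(pd.DataFrame(pts, index=list("abcdef")))
        res = pcoa(d)
        from scipy.spatial.distance import pdist, squareform

        recon = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(recon, d.data, atol=1e-9)

    def test_collinear_points_single_axis_with_gap_ratio(self):
        pts = pd.DataFrame({"x": [0.0, 1.0, 3.0]}, index=list("abc"))
        res = pcoa(euclidean_distance(pts))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 1
        ax = res.coordinates[:, 0]
        gaps = np.diff(np.sort(ax))
        assert gaps[1] / gaps[0] == pytest.approx(2.0, abs=1e-9)

    def test_matches_scikit_bio_oracle(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.random((8, 12))
        dm = bray_curtis(pd.DataFrame(x, index=[f"s{i}" for i in range(8)]))
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, ids=dm.ids), method="eigh"
        )
        k = ours.n_axes
        ref = theirs.samples.to_numpy()[:, :k]
        for ax in range(k):
            a, b = ours.coordinates[:, ax], ref[:, ax]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


class TestFactorFit:
    def _ordination(self, coords):
        ids = [f"s{i}" for i in range(len(coords))]
        from viromescope.ecology import OrdinationResult

        c = np.asarray(coords, dtype=float)
        return OrdinationResult(ids, c, np.ones(c.shape[1]), np.ones(c.shape[1]))

    def test_perfect_axis_split_minimal_p(self, rng):
        # 20 vs 10 perfect separation: no label permutation can match the
        # observed r^2, so p attains its add-one lower bound
        coords = np.column_stack(
            [np.r_[np.zeros(20), np.ones(10) * 10], rng.normal(size=30)]
        )
        labels = ["a"] * 20 + ["b"] * 10
        res = factor_fit(self._ordination(coords), labels, n_perm=999, rng_seed=1)
        assert res.effect > 0.95
        assert res.p_raw == pytest.approx(1 / 1000)

    def test_identical_centroids_r2_near_zero(self, rng):
        base = rng.normal(size=(10, 2))
        coords = np.vstack([base, base])  # two groups, identical point clouds
        labels = ["a"] * 10 + ["b"] * 10
        res = factor_fit(self._ordination(coords), labels, n_perm=99, rng_seed=2)
        assert res.effect < 0.05

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            factor_fit(self._ordination(rng.normal(size=(6, 2))), ["a"] * 6, n_perm=9)

    def test_p_lower_bound_and_seed_determinism(self, rng):
        coords = rng.normal(size=(12, 2))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = factor_fit(self._ordination(coords), labels, n_perm=199, rng_seed=5)
        r2 = factor_fit(self._ordination(coords), labels, n_perm=199, rng_seed=5)
        assert r1.p_raw == r2.p_raw >= 1 / 200


class TestVectorFit:
    def _ordination(self, coords):
        from viromescope.ecology import OrdinationResult

        c = np.asarray(coords, dtype=float)
        return OrdinationResult([f"s{i}" for i in range(len(c))], c, np.ones(c.shape[1]), np.ones(c.shape[1]))

    def test_axis_variable_r2_one(self, rng):
        coords = rng.normal(size=(15, 2))
        res = vector_fit(self._ordination(coords), coords[:, 0], n_perm=99, rng_seed=1)
        assert res.effect == pytest.approx(1.0)
        assert abs(res.direction[0]) == pytest.approx(1.0, abs=1e-9)
        assert res.direction[1] == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_variable_direction(self, rng):
        coords = rng.normal(size=(30, 2))
        coords = (coords - coords.mean(0)) @ np.linalg.cholesky(
            np.linalg.inv(np.cov(coords.T))
        ).T  # whiten so both axes contribute equally
        y = coords[:, 0] + coords[:, 1]
        res = vector_fit(self._ordination(coords), y, n_perm=99, rng_seed=2)
        assert np.abs(res.direction) == pytest.approx([np.sqrt(0.5), np.sqrt(0.5)], abs=1e-6)

    def test_constant_variable_rejected(self, rng):
        with pytest.raises(ValueError):
            vector_fit(self._ordination(rng.normal(size=(8, 2))), np.ones(8), n_perm=9)


class TestMantel:
    def _dm(self, pts, ids=None):
        ids = ids or [f"s{i}" for i in range(len(pts))]
        return euclidean_distance(pd.DataFrame(pts, index=ids))

    def test_self_correlation_one(self, rng):
        d = self._dm(rng.normal(size=(8, 3)))
        res = mantel(d, d, n_perm=99, rng_seed=1)
        assert res.effect == pytest.approx(1.0)

    def test_monotone_transform_rank_invariance(self, rng):
        d = self._dm(rng.normal(size=(8, 3)))
        d2 = DistanceMatrix(d.ids, np.sqrt(d.data) + d.data**2)
        res = mantel(d, d2, n_perm=99, rng_seed=1)
        assert res.effect == pytest.approx(1.0)

    def test_mismatched_ids_rejected(self, rng):
        d1 = self._dm(rng.normal(size=(5, 2)))
        d2 = self._dm(rng.normal(size=(5, 2)), ids=list("vwxyz"))
        with pytest.raises(ValueError):
            mantel(d1, d2)

    def test_statistic_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        d1 = self._dm(rng.normal(size=(10, 3)))
        d2 = self._dm(rng.normal(size=(10, 3)))
        ours = mantel(d1, d2, n_perm=99, rng_seed=3)
        r, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.data, ids=d1.ids),
            skbio.DistanceMatrix(d2.data, ids=d2.ids),
            method="spearman", permutations=0,
        )
        assert ours.effect == pytest.approx(r)


class TestUpgma:
    def test_two_leaves_half_distance(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 4.0], [4.0, 0]]))
        assert upgma(d) == "(A:2,B:2);"

    def test_closest_pair_joins_first(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]]),
        )
        nwk = upgma(d)
        assert nwk == "((A:0.5,B:0.5):4.5,C:5);"

    def test_input_order_invariance(self):
        ids = ["A", "B", "C", "D"]
        m = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0.0]]
        )
        d1 = DistanceMatrix(ids, m)
        perm = [2, 0, 3, 1]
        d2 = DistanceMatrix([ids[i] for i in perm], m[np.ix_(perm, perm)])
        assert upgma(d1) == upgma(d2)

    def test_heights_match_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage

        pts = rng.random((6, 4))
        d = euclidean_distance(pd.DataFrame(pts, index=list("abcdef")))
        pytest.importorskip("skbio")
        z = linkage(d.condensed(), method="average")
        nwk = upgma(d)
        # ultrametric tree: every leaf-to-root path equals the root height
        root_height = z[-1, 2] / 2
        depths = _leaf_depths(nwk)
        for leaf, depth in depths.items():
            assert depth == pytest.approx(root_height, rel=1e-9)


def _leaf_depths(newick: str) -> dict:
    """Leaf -> distance from root, via scikit-bio's newick parser."""
    import io

    import skbio

    tree = skbio.TreeNode.read(io.StringIO(newick))
    return {tip.name: tree.distance(tip) for tip in tree.tips()}


class TestAutoscaleAndFilter:
    def test_three_point_feature(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(autoscale(m)["f"], [-1, 0, 1])

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        once = autoscale(m)
        twice = autoscale(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_output_column_means_zero(self, rng):
        m = pd.DataFrame(rng.random((10, 5)))
        np.testing.assert_allclose(autoscale(m).mean(axis=0), 0.0, atol=1e-12)

    def test_constant_feature_dropped_with_warning(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = autoscale(m)
        assert list(out.columns) == ["f"]

    def test_presence_filter_inclusive_boundary(self):
        n = 30
        m = pd.DataFrame({
            "keep": [1.0] * 15 + [0.0] * 15,   # 15/30 detected: retained
            "drop": [1.0] * 14 + [0.0] * 16,   # 14/30: removed
        })
        out = presence_filter(m, min_fraction=0.5)
        assert list(out.columns) == ["keep"]

    def test_zero_threshold_identity(self, rng):
        m = pd.DataFrame(rng.random((6, 4)))
        assert presence_filter(m, min_fraction=0.0).shape == m.shape
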