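"""DBSCAN, radius of gyration, nearest-neighbor distances and hotspot
enrichment, checked against brute-force references."""

import numpy as np
import pytest

from synprime.nanocluster import (NOISE, dbscan, distance_to_cluster_centers,
                                  hotspot_enrichment, nnd, radius_of_gyration)


def brute_force_dbscan(points, eps, min_pts):
    """O(N^2) reference implementation of the published algorithm with
    the same deterministic border-point rule."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, NOISE)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if core[k] and labels[k] == NOISE:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    for i in range(n):
        if core[i]:
            continue
        ids = sorted(labels[j] for j in neighbors[i]
                     if core[j] and labels[j] != NOISE)
        labels[i] = ids[0] if ids else NOISE
    return labels


def canonical(labels):
    """Relabel clusters by order of first appearance."""
    mapping, out = {}, []
    for v in labels:
        if v == NOISE:
            out.append(NOISE)
            continue
        if v not in mapping:
            mapping[v] = len(mapping)
        out.append(mapping[v])
    return np.asarray(out)


class TestDbscan:
    def test_single_dense_ball(self, rng):
        pts = rng.uniform(-5, 5, size=(10, 3))
        res = dbscan(pts, eps=50.0, min_pts=5)
        assert res.n_clusters == 1
        assert res.n_noise == 0

    def test_isolated_points_are_noise(self):
        pts = np.diag([100.0, 200.0, 300.0])
        res = dbscan(pts, eps=50.0, min_pts=2)
        assert res.n_clusters == 0
        assert res.n_noise == 3

    def test_empty_input(self):
        res = dbscan(np.empty((0, 3)))
        assert res.n_clusters == 0 and res.labels.size == 0

    @pytest.mark.parametrize("eps,min_pts", [(30.0, 3), (50.0, 5),
                                             (80.0, 8), (120.0, 4)])
    def test_matches_brute_force_reference(self, rng, eps, min_pts):
        pts = rng.uniform(0, 500, size=(200, 3))
        ours = canonical(dbscan(pts, eps=eps, min_pts=min_pts).labels)
        ref = canonical(brute_force_dbscan(pts, eps, min_pts))
        np.testing.assert_array_equal(ours, ref)

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 300, size=(150, 3))
        perm = rng.permutation(150)
        a = canonical(dbscan(pts, eps=60, min_pts=4).labels)
        b = canonical(dbscan(pts[perm], eps=60, min_pts=4).labels)
        # compare as partitions: identical grouping of the same points
        groups_a = {}
        groups_b = {}
        for i in range(150):
            groups_a.setdefault(a[i], set()).add(i)
            groups_b.setdefault(b[i], set()).add(int(perm[i]))
        assert set(map(frozenset, groups_a.values())) == \
            set(map(frozenset, groups_b.values()))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            dbscan(np.zeros((3, 3)), eps=0.0)
        with pytest.raises(ValueError):
            dbscan(np.zeros((3, 3)), min_pts=0)


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_half_separation(self):
        pts = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(pts) == pytest.approx(1.0)

    def test_unit_square_corners(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(0.5))

    def test_rigid_motion_invariance_and_dilation(self, rng):
        pts = rng.normal(size=(60, 3))
        base = radius_of_gyration(pts)
        # rotation about z + translation
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = pts @ R.T + np.array([5.0, -3.0, 11.0])
        assert radius_of_gyration(moved) == pytest.approx(base, rel=1e-9)
        assert radius_of_gyration(3.5 * pts) == pytest.approx(3.5 * base,
                                                              rel=1e-9)


class TestDistances:
    def test_nearest_of_two(self):
        d = nnd(np.array([[0.0, 0, 0]]), np.array([[3.0, 0, 0], [10.0, 0, 0]]))
        np.testing.assert_allclose(d.distances, [3.0])

    def test_identical_sets_give_zeros(self, rng):
        pts = rng.uniform(0, 100, (20, 3))
        np.testing.assert_allclose(nnd(pts, pts.copy()).distances, 0.0)

    def test_matches_brute_force(self, rng):
        a = rng.uniform(0, 1000, (500, 3))
        b = rng.uniform(0, 1000, (500, 3))
        ours = nnd(a, b).distances
        ref = np.min(np.linalg.norm(a[:, None] - b[None], axis=2), axis=1)
        np.testing.assert_allclose(ours, ref, atol=1e-9)
        assert np.all(ours <= ref + 1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            nnd(np.empty((0, 3)), np.zeros((2, 3)))

    def test_distance_to_single_center(self):
        d = distance_to_cluster_centers(np.array([[100.0, 0, 0]]),
                                        np.array([[0.0, 0, 0]]))
        np.testing.assert_allclose(d.distances, [100.0])

    def test_equidistant_tie(self):
        d = distance_to_cluster_centers(np.array([[0.0, 0, 0]]),
                                        np.array([[5.0, 0, 0], [-5.0, 0, 0]]))
        np.testing.assert_allclose(d.distances, [5.0])

    def test_ecdf_properties(self, rng):
        d = nnd(rng.uniform(0, 100, (200, 3)), rng.uniform(0, 100, (50, 3)))
        xs = np.linspace(0, 200, 30)
        cdf = d.ecdf(xs)
        assert np.all(np.diff(cdf) >= 0)
        assert d.ecdf(1e9) == 1.0
        assert d.frac_below(xs[10]) == cdf[10]


class TestHotspotEnrichment:
    def test_uniform_roi(self, rng):
        bg = rng.normal(100.0, 10.0, 5000)
        roi = np.full(400, bg.mean() + 5 * bg.std(ddof=1))
        res = hotspot_enrichment(roi, bg)
        assert res.z50 == pytest.approx(5.0)
        assert res.z90 == pytest.approx(5.0)
        assert res.enrichment == pytest.approx(1.0)

    def test_discrete_ninety_ten_split(self):
        bg = np.concatenate([np.zeros(50), np.full(50, 2.0)])  # mean 1, sd ~1
        mu, sd = bg.mean(), bg.std(ddof=1)
        roi = np.concatenate([np.full(90, mu + 1.0 * sd),
                              np.full(10, mu + 10.0 * sd)])
        res = hotspot_enrichment(roi, bg)
        assert res.z50 == pytest.approx(1.0)
        assert res.z90 == pytest.approx(10.0)
        assert res.enrichment == pytest.approx(10.0)

    def test_zero_variance_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            hotspot_enrichment(np.ones(10), np.full(10, 3.0))

    def test_nonpositive_median_flagged(self, rng):
        bg = rng.normal(100.0, 10.0, 2000)
        roi = rng.normal(100.0, 10.0, 900)   # ROI at background level
        res = hotspot_enrichment(roi, bg)
        if res.z50 <= 0:
            assert res.enrichment is None
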