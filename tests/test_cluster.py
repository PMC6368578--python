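import io

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from conftest import random_ggs
from ggsig.cluster import (
    Cladogram,
    WSSCurve,
    complete_linkage,
    elbow_suggest,
    kmeans_fit,
    kmeans_wss,
    pca_project,
    to_newick,
    type_partition_check,
)
from ggsig.distance import DeltaMatrix, distance_matrix
from ggsig.signature import GGSVector


def dmatrix(labels, values):
    return DeltaMatrix(labels=tuple(labels), n=2, values=np.asarray(values, dtype=float))


def cophenetic_of(clad):
    """Pairwise merge heights implied by a Cladogram (oracle helper)."""
    k = len(clad.leaves)
    members = {i: {i} for i in range(k)}
    coph = np.zeros((k, k))
    for idx, (a, b, h) in enumerate(clad.merges):
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = h
        members[k + idx] = members.pop(a) | members.pop(b)
    return coph


class TestCompleteLinkage:
    def test_two_leaves(self):
        m = dmatrix(["a", "b"], [[0, 0.3], [0.3, 0]])
        clad = complete_linkage(m)
        assert clad.merges == ((0, 1, 0.3),)

    def test_three_leaf_hand_agglomeration(self):
        m = dmatrix(["a", "b", "c"], [[0, 1, 5], [1, 0, 5], [5, 5, 0]])
        clad = complete_linkage(m)
        (a, b, h1), (x, y, h2) = clad.merges
        assert {a, b} == {0, 1} and h1 == 1
        assert {x, y} == {2, 3} and h2 == 5

    def test_heights_non_decreasing_on_random_metrics(self, rng):
        for _ in range(100):
            pts = rng.uniform(size=(6, 4))
            m = dmatrix([f"l{i}" for i in range(6)], squareform(pdist(pts, "cityblock")))
            heights = [h for _, _, h in complete_linkage(m).merges]
            assert all(b >= a for a, b in zip(heights, heights[1:]))

    def test_agrees_with_scipy_cophenetic(self, rng):
        """Dual route: farthest-neighbour agglomeration vs scipy 'complete'."""
        for _ in range(25):
            pts = rng.uniform(size=(8, 3))
            cond = pdist(pts, "cityblock")
            m = dmatrix([f"l{i}" for i in range(8)], squareform(cond))
            mine = cophenetic_of(complete_linkage(m))
            scipy_coph = squareform(cophenet(linkage(cond, method="complete")))
            np.testing.assert_allclose(mine, scipy_coph, rtol=1e-10)

    def test_deterministic_tie_break(self):
        # all distances tied: first merge must join the lexicographically
        # smallest label pair
        m = dmatrix(["c", "a", "b"], 0.5 * (1 - np.eye(3)))
        clad = complete_linkage(m)
        a, b, _ = clad.merges[0]
        assert {clad.leaves[a], clad.leaves[b]} == {"a", "b"}

    def test_leaf_set_and_height_bound(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(7)]
        m = distance_matrix(vs)
        clad = complete_linkage(m)
        assert clad.leaves == m.labels
        assert max(h for _, _, h in clad.merges) <= m.values.max() + 1e-12


class TestNewick:
    def test_two_leaf_ultrametric(self):
        clad = Cladogram(merges=((0, 1, 0.3),), leaves=("a", "b"))
        tree = dendropy.Tree.get(data=to_newick(clad), schema="newick")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": pytest.approx(0.15), "b": pytest.approx(0.15)}

    def test_three_leaf_worked_example(self):
        clad = Cladogram(merges=((0, 1, 1.0), (3, 2, 5.0)), leaves=("a", "b", "c"))
        nwk = to_newick(clad)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.5)
        assert lengths["b"] == pytest.approx(0.5)
        assert lengths["c"] == pytest.approx(2.5)
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.length is not None and not e.head_node.is_leaf()]
        assert internal == [pytest.approx(2.0)]

    def test_round_trip_topology(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(6)]
        clad = complete_linkage(distance_matrix(vs))
        tree = dendropy.Tree.get(data=to_newick(clad), schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(clad.leaves)
        # ultrametric: all leaves equidistant from root
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_reserved_characters_quoted(self):
        clad = Cladogram(merges=((0, 1, 0.4),), leaves=("x (1)", "y"))
        nwk = to_newick(clad)
        assert "'x (1)'" in nwk
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"x (1)", "y"}


class TestPCA:
    def test_identical_vectors_project_to_origin(self, rng):
        v = random_ggs(rng, label="a")
        vs = [v, GGSVector("b", 2, v.rho.copy()), GGSVector("c", 2, v.rho.copy())]
        res = pca_project(vs, components=2)
        np.testing.assert_allclose(res.coordinates, 0.0, atol=1e-12)

    def test_components_beyond_rank_bound_error(self, rng):
        vs = [random_ggs(rng, label=l) for l in ("a", "b", "c")]
        with pytest.raises(ValueError, match="rank"):
            pca_project(vs, components=3)  # only 2 directions from 3 points

    def test_mirror_vectors_single_axis(self):
        a = GGSVector("a", 2, np.linspace(0, 2, 10))
        b = GGSVector("b", 2, 2 - np.linspace(0, 2, 10))
        res = pca_project([a, b], components=1)
        c = res.coordinates[:, 0]
        assert c[0] == pytest.approx(-c[1])
        assert abs(c[0]) > 0

    def test_variance_conservation(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(8)]
        x = np.vstack([v.rho for v in vs])
        total = ((x - x.mean(0)) ** 2).sum() / (len(vs) - 1)
        res = pca_project(vs, components=7)
        assert res.explained_variance.sum() == pytest.approx(total)

    def test_deterministic_sign(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(5)]
        r1 = pca_project(vs, components=2)
        r2 = pca_project(list(vs), components=2)
        np.testing.assert_array_equal(r1.coordinates, r2.coordinates)


def blob_vectors(rng, centers, per=6, scale=0.02, n=2):
    vs = []
    for ci, c in enumerate(centers):
        for i in range(per):
            vs.append(GGSVector(f"c{ci}_{i}", n, c + rng.normal(0, scale, size=len(c))))
    return vs


class TestKmeansWSS:
    def test_k_equals_points_zero_wss(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(5)]
        _, wss = kmeans_fit(vs, 5, seed=0)
        assert wss == pytest.approx(0.0, abs=1e-20)

    def test_k1_closed_form(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(6)]
        x = np.vstack([v.rho for v in vs])
        expected = ((x - x.mean(0)) ** 2).sum()
        _, wss = kmeans_fit(vs, 1, seed=0)
        assert wss == pytest.approx(expected)

    def test_three_blobs_elbow_shape(self, rng):
        centers = [np.full(10, 1.0), np.full(10, 2.0), np.r_[np.full(5, 0.0), np.full(5, 3.0)]]
        vs = blob_vectors(rng, centers)
        curve = kmeans_wss(vs, 1, 6, seed=0)
        w = dict(zip(curve.ks, curve.wss))
        assert w[3] < 0.2 * w[2]
        assert abs(w[4] - w[3]) < 0.5 * (w[2] - w[3])

    def test_reproducible(self, rng):
        vs = blob_vectors(rng, [np.full(10, 0.0), np.full(10, 2.0)])
        c1 = kmeans_wss(vs, 1, 5, seed=9)
        c2 = kmeans_wss(vs, 1, 5, seed=9)
        assert c1 == c2

    def test_more_restarts_never_worse(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(12)]
        for k in (2, 3, 4):
            w_few = kmeans_fit(vs, k, restarts=2, seed=5)[1]
            w_many = kmeans_fit(vs, k, restarts=20, seed=5)[1]
            assert w_many <= w_few + 1e-12

    def test_k_max_exceeds_points_errors(self, rng):
        vs = [random_ggs(rng, label=f"v{i}") for i in range(3)]
        with pytest.raises(ValueError):
            kmeans_wss(vs, 1, 4)


class TestElbow:
    def curve(self, wss, k_min=1):
        ks = tuple(range(k_min, k_min + len(wss)))
        return WSSCurve(ks=ks, wss=tuple(float(w) for w in wss),
                        restarts=20, max_iter=50, seed=0)

    def test_hand_computed_second_difference(self):
        res = elbow_suggest(self.curve([100, 20, 18, 17]))
        assert res.k == 2 and res.clear

    def test_linear_decline_flags_no_elbow(self):
        res = elbow_suggest(self.curve([100, 80, 60, 40, 20]))
        assert res.k == 2 and not res.clear

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            elbow_suggest(self.curve([10, 5]))

    def test_three_blob_fixture(self, rng):
        centers = [np.full(10, 0.0), np.full(10, 1.5), np.r_[np.full(5, -1.5), np.full(5, 1.5)]]
        vs = blob_vectors(rng, centers, per=5)
        res = elbow_suggest(kmeans_wss(vs, 1, 8, seed=2))
        assert res.k == 3


class TestPartitionCheck:
    def make(self, within, between):
        labels = ["a1", "a2", "b1", "b2"]
        values = np.full((4, 4), between)
        values[0, 1] = values[1, 0] = within
        values[2, 3] = values[3, 2] = within
        np.fill_diagonal(values, 0.0)
        m = dmatrix(labels, values)
        return m, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_clean_separation(self):
        m, types = self.make(0.1, 0.9)
        report = type_partition_check(m, types)
        assert report.perfect
        assert report.max_same_type == pytest.approx(0.1)
        assert report.min_different_type == pytest.approx(0.9)

    def test_violation_listed(self):
        m, types = self.make(0.1, 0.9)
        values = m.values.copy()
        values[0, 1] = values[1, 0] = 0.95  # same-type pair beyond min between
        report = type_partition_check(dmatrix(m.labels, values), types)
        kinds = {(a, b): kind for a, b, _, kind in report.violations}
        assert kinds[("a1", "a2")] == "same-type-too-far"
        assert not report.perfect

    def test_single_type_errors(self):
        m, _ = self.make(0.1, 0.9)
        with pytest.raises(ValueError, match="2 types"):
            type_partition_check(m, {l: "A" for l in m.labels})

    def test_unknown_label_errors(self):
        m, types = self.make(0.1, 0.9)
        types.pop("b2")
        with pytest.raises(KeyError):
            type_partition_check(m, types)
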