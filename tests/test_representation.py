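import itertools

import numpy as np
import pytest

from netimage import (
    DiseaseAnnotation,
    GeneNetwork,
    compute_similarity,
    fuse_networks,
    leaf_order,
    represent_all,
    represent_all_baseline,
    represent_baseline,
    represent_vertex,
    select_neighborhood,
)
from netimage.representation import (
    ClassCentroids,
    LeafOrder,
    SimilarityMatrix,
    assign_center_tag,
    build_classification_matrix,
    build_sub_adjacency,
    class_centroid_distance,
    neighbor_class_value,
    NeighborhoodField,
    _window_positions,
)

from conftest import dense_network, random_network


def brute_force_similarity(weights, cap):
    """Independent oracle: explicit double loop over row pairs."""
    n = weights.shape[0]
    s = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = sum((weights[i, k] - weights[j, k]) ** 2 for k in range(n))
            s[i, j] = cap if d == 0 else 1.0 / d
    return s


class TestComputeSimilarity:
    def test_hand_evaluated_rows(self):
        # rows (0,1,0) and (1,0,0): squared difference sum = 2
        w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        net = GeneNetwork("x", ["a", "b", "c"], w)
        s = compute_similarity(net)
        assert s.values[0, 1] == pytest.approx(0.5)

    def test_hand_evaluated_quarter(self):
        # rows (0,0,2) and (0,0,0): squared difference sum = 4
        w = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        net = GeneNetwork("x", ["a", "b", "c"], w)
        s = compute_similarity(net)
        assert s.values[0, 1] == pytest.approx(0.25)

    def test_identical_rows_capped(self):
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        net = GeneNetwork("x", ["a", "b", "c"], w)
        s = compute_similarity(net, cap=99.0)
        assert s.values[0, 1] == 99.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(5):
            net = random_network(rng, 10, density=0.5)
            s = compute_similarity(net, cap=1e9)
            np.testing.assert_allclose(
                s.values, brute_force_similarity(net.weights, 1e9), rtol=1e-10
            )

    def test_sqrt_variant_is_square_root_of_distance(self, rng):
        net = random_network(rng, 6, density=0.8)
        plain = compute_similarity(net)
        rooted = compute_similarity(net, use_sqrt=True)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(
            1.0 / rooted.values[off], np.sqrt(1.0 / plain.values[off])
        )


class TestLeafOrder:
    def test_near_identical_pairs_adjacent(self, two_cluster_network):
        s = compute_similarity(two_cluster_network)
        order = leaf_order(s).order.tolist()
        pos = {v: i for i, v in enumerate(order)}
        assert abs(pos[0] - pos[1]) == 1  # genes 0,1 have near-identical rows
        assert abs(pos[2] - pos[3]) == 1

    def test_n2_is_permutation(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = compute_similarity(GeneNetwork("x", ["a", "b"], w))
        order = leaf_order(s)
        assert sorted(order.order.tolist()) == [0, 1]

    def test_inverse_permutations(self, rng):
        net = dense_network(rng, 13)
        order = leaf_order(compute_similarity(net))
        np.testing.assert_array_equal(order.position[order.order], np.arange(13))

    def test_relabeling_equivariance(self, rng):
        net = dense_network(rng, 12)
        order = leaf_order(compute_similarity(net))
        seq = [net.genes[i] for i in order.order]
        perm = rng.permutation(12)
        net_p = GeneNetwork(
            "p",
            [net.genes[i] for i in perm],
            net.weights[np.ix_(perm, perm)],
        )
        order_p = leaf_order(compute_similarity(net_p))
        seq_p = [net_p.genes[i] for i in order_p.order]
        assert seq == seq_p

    def test_deterministic(self, rng):
        net = random_network(rng, 15, density=0.4)
        s = compute_similarity(net)
        np.testing.assert_array_equal(leaf_order(s).order, leaf_order(s).order)


def window_oracle(pos, k, n):
    """Enumerate the truncated-and-extended window from its definition."""
    lo, hi = pos - k, pos + k
    if lo < 0:
        hi = min(hi - lo, n - 1)
        lo = 0
    if hi > n - 1:
        lo = max(lo - (hi - (n - 1)), 0)
        hi = n - 1
    return [p for p in range(lo, hi + 1) if p != pos]


class TestSelectNeighborhood:
    def _fabricate(self, sims):
        """Similarity of gene 0 against genes 1..len(sims) with identity order."""
        n = len(sims) + 1
        values = np.full((n, n), 0.01)
        for i, s in enumerate(sims, start=1):
            values[0, i] = values[i, 0] = s
        np.fill_diagonal(values, 1e12)
        order = LeafOrder(np.arange(n), np.arange(n))
        return SimilarityMatrix(values=values), order

    def test_top_similarity_candidates_win(self):
        sim, order = self._fabricate([0.9, 0.2, 0.5, 0.7])
        field = select_neighborhood(0, order, sim, k=4, m=3)
        assert field.members == [1, 4]  # the 0.9 and 0.7 candidates

    def test_equal_similarity_prefers_smaller_position(self):
        sim, order = self._fabricate([0.3, 0.3, 0.3, 0.3])
        field = select_neighborhood(0, order, sim, k=4, m=3)
        assert field.members == [1, 2]

    def test_boundary_window_extends_opposite_side(self):
        n, k = 10, 3
        assert window_oracle(0, k, n) == [1, 2, 3, 4, 5, 6]
        np.testing.assert_array_equal(
            _window_positions(0, k, n), np.arange(1, 7)
        )
        np.testing.assert_array_equal(
            _window_positions(n - 1, k, n), np.arange(3, 9)
        )

    def test_pool_size_is_min_2k_nminus1(self, rng):
        for n, k in [(9, 4), (12, 3), (30, 10)]:
            for pos in range(n):
                assert len(_window_positions(pos, k, n)) == min(2 * k, n - 1)

    def test_exhaustive_subset_oracle(self, rng):
        """select_neighborhood equals argmax over all (m-1)-subsets of the
        window's summed similarity to the center."""
        for _ in range(25):
            n = int(rng.integers(8, 31))
            m = int(rng.integers(3, 7))
            k = int(rng.integers(m + 1, min(11, n)))
            net = dense_network(rng, n)
            sim = compute_similarity(net)
            order = leaf_order(sim)
            center = int(rng.integers(0, n))
            field = select_neighborhood(center, order, sim, k, m)
            window = window_oracle(int(order.position[center]), k, n)
            best, best_val = None, -np.inf
            for subset in itertools.combinations(window, m - 1):
                val = sum(
                    sim.values[center, order.order[p]] for p in subset
                )
                if val > best_val:
                    best, best_val = subset, val
            assert sorted(order.order[list(best)].tolist()) == sorted(field.members)

    def test_small_pool_error(self):
        sim, order = self._fabricate([0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            select_neighborhood(0, order, sim, k=3, m=3)  # violates m < k? no: pool
        with pytest.raises(ValueError):
            select_neighborhood(0, order, sim, k=5, m=5)


class TestSubAdjacency:
    def test_read_off_parent_matrix(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.4
        w[0, 2] = w[2, 0] = 0.9
        net = GeneNetwork("x", ["a", "b", "c", "d"], w)
        field = NeighborhoodField(center=0, radius=2, members=[1, 2], m=3)
        a = build_sub_adjacency(net, field)
        np.testing.assert_allclose(
            a, [[0.0, 0.4, 0.9], [0.4, 0.0, 0.0], [0.9, 0.0, 0.0]]
        )

    def test_isolated_center_zero_row(self, rng):
        net = random_network(rng, 6, density=0.5)
        w = net.weights.copy()
        w[0, :] = w[:, 0] = 0.0
        net = GeneNetwork("x", net.genes, w)
        field = NeighborhoodField(center=0, radius=3, members=[2, 4], m=3)
        a = build_sub_adjacency(net, field)
        assert np.all(a[0] == 0) and np.all(a[:, 0] == 0)

    def test_symmetric_zero_diagonal(self, rng):
        for _ in range(5):
            net = random_network(rng, 10, density=0.6)
            members = sorted(rng.choice(np.arange(1, 10), 4, replace=False).tolist())
            field = NeighborhoodField(center=0, radius=5, members=members, m=5)
            a = build_sub_adjacency(net, field)
            np.testing.assert_allclose(a, a.T)
            assert np.all(np.diag(a) == 0)


class TestClassDistance:
    def test_same_class_zero(self, rng, small_annotation):
        net = random_network(rng, 4, density=0.9)
        assert class_centroid_distance(2, 2, net, small_annotation) == 0.0

    def test_singleton_classes_hand_value(self):
        w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        net = GeneNetwork("x", ["a", "b", "c"], w)
        ann = DiseaseAnnotation(
            tags={"a": frozenset({1}), "b": frozenset({2})},
            n_classes=2,
            target_class=1,
        )
        # centroids are rows (0,1,0) and (1,0,0): distance sqrt(2)
        assert class_centroid_distance(1, 2, net, ann) == pytest.approx(np.sqrt(2))

    def test_symmetry(self, rng, small_annotation):
        net = random_network(rng, 4, density=0.9)
        d12 = class_centroid_distance(1, 2, net, small_annotation)
        d21 = class_centroid_distance(2, 1, net, small_annotation)
        assert d12 == d21

    def test_empty_class_error(self, rng):
        net = random_network(rng, 4)
        ann = DiseaseAnnotation(
            tags={"g0": frozenset({1})}, n_classes=3, target_class=1
        )
        with pytest.raises(ValueError, match="no member"):
            ClassCentroids(net, ann)(1, 2)


class TestCenterTag:
    def test_target_in_tags_wins(self):
        ann = DiseaseAnnotation(
            tags={"g": frozenset({1, 5})}, n_classes=5, target_class=1
        )
        assert assign_center_tag("g", ann, lambda a, b: 1.0) == 1

    def test_unannotated_gets_zero(self):
        ann = DiseaseAnnotation(tags={}, n_classes=5, target_class=1)
        assert assign_center_tag("g", ann, lambda a, b: 1.0) == 0

    def test_closest_class_to_target(self):
        ann = DiseaseAnnotation(
            tags={"g": frozenset({2, 3})}, n_classes=5, target_class=1
        )
        dist = {(2, 1): 0.4, (3, 1): 0.9}
        assert assign_center_tag("g", ann, lambda a, b: dist[(a, b)]) == 2

    def test_distance_tie_prefers_smaller_code(self):
        ann = DiseaseAnnotation(
            tags={"g": frozenset({4, 3})}, n_classes=5, target_class=1
        )
        assert assign_center_tag("g", ann, lambda a, b: 1.0) == 3


class TestNeighborClassValue:
    def test_center_tag_in_neighbor_tags(self):
        ann = DiseaseAnnotation(
            tags={"n": frozenset({8, 2})}, n_classes=10, target_class=8
        )
        assert neighbor_class_value("n", 8, ann, lambda a, b: 1.0) == 2.0

    def test_unannotated_neighbor_zero(self):
        ann = DiseaseAnnotation(tags={}, n_classes=10, target_class=1)
        assert neighbor_class_value("n", 3, ann, lambda a, b: 1.0) == 0.0

    def test_closest_tag_over_four(self):
        ann = DiseaseAnnotation(
            tags={"n": frozenset({4, 6})}, n_classes=10, target_class=1
        )
        dist = {(4, 1): 0.2, (6, 1): 0.8}
        assert neighbor_class_value("n", 1, ann, lambda a, b: dist[(a, b)]) == 1.0

    def test_masked_center_falls_back_to_target(self):
        ann = DiseaseAnnotation(
            tags={"n": frozenset({4, 6})}, n_classes=10, target_class=6
        )
        dist = {(4, 6): 0.9, (6, 6): 0.0}
        # reference class is the target (6) because t_center == 0
        assert neighbor_class_value("n", 0, ann, lambda a, b: dist[(a, b)]) == 1.5


class TestClassificationMatrix:
    def test_direct_placement(self):
        field = NeighborhoodField(center=0, radius=2, members=[1, 2], m=3)
        c = build_classification_matrix(field, [2.0, 0.0])
        np.testing.assert_allclose(c, np.diag([0.0, 2.0, 0.0]))

    def test_all_unannotated_zero_matrix(self):
        field = NeighborhoodField(center=0, radius=2, members=[1, 2], m=3)
        assert np.all(build_classification_matrix(field, [0.0, 0.0]) == 0)

    def test_length_mismatch_error(self):
        field = NeighborhoodField(center=0, radius=2, members=[1, 2], m=3)
        with pytest.raises(ValueError):
            build_classification_matrix(field, [1.0])

    def test_nonzeros_only_on_diagonal(self, rng):
        m = 6
        field = NeighborhoodField(
            center=0, radius=3, members=[1, 2, 3, 4, 5], m=m
        )
        c = build_classification_matrix(field, rng.uniform(size=m - 1))
        assert np.count_nonzero(c - np.diag(np.diag(c))) == 0
        assert c[0, 0] == 0


def _random_instance(rng, n=20, n_classes=3, annotated=10):
    net = dense_network(rng, n)
    tagged = rng.choice(n, size=annotated, replace=False)
    tags = {
        net.genes[i]: frozenset(
            rng.choice(np.arange(1, n_classes + 1), size=rng.integers(1, 3), replace=False).tolist()
        )
        for i in tagged
    }
    ann = DiseaseAnnotation(tags=tags, n_classes=n_classes, target_class=1)
    return net, ann


class TestRepresentVertex:
    def test_decomposition_and_shapes(self, rng):
        net, ann = _random_instance(rng)
        ds_params = dict(k=8, m=5)
        from netimage.representation import compute_similarity, leaf_order

        sim = compute_similarity(net)
        order = leaf_order(sim)
        for center in range(net.n):
            img = represent_vertex(net, ann, order, sim, center, **ds_params)
            np.testing.assert_allclose(img.E - img.A, img.C)
            assert np.all(np.diag(img.A) == 0)
            np.testing.assert_allclose(img.A, img.A.T)
            assert img.C[0, 0] == 0
            assert np.count_nonzero(img.C - np.diag(np.diag(img.C))) == 0

    def test_no_annotation_means_e_equals_a(self, rng):
        net = dense_network(rng, 15)
        ann = DiseaseAnnotation(tags={}, n_classes=2, target_class=1)
        ds = represent_all(net, ann, k=6, m=4)
        for img in ds.images:
            assert np.all(np.diag(img) == 0)

    def test_mask_center_zeroes_tag(self, rng):
        net, ann = _random_instance(rng)
        sim = compute_similarity(net)
        order = leaf_order(sim)
        gene = next(iter(ann.tags))
        img = represent_vertex(net, ann, order, sim, gene, 8, 5, mask_center=True)
        assert img.t_center == 0

    def test_represent_all_shapes_and_determinism(self, rng):
        net, ann = _random_instance(rng, n=25)
        ds1 = represent_all(net, ann, k=10, m=6)
        ds2 = represent_all(net, ann, k=10, m=6)
        assert ds1.images.shape == (25, 6, 6)
        np.testing.assert_array_equal(ds1.images, ds2.images)
        np.testing.assert_array_equal(ds1.t_centers, ds2.t_centers)

    def test_relabeling_equivariance_full_image(self, rng):
        net, ann = _random_instance(rng, n=14)
        sim = compute_similarity(net)
        order = leaf_order(sim)
        dist = ClassCentroids(net, ann)
        perm = rng.permutation(14)
        net_p = GeneNetwork(
            "p", [net.genes[i] for i in perm], net.weights[np.ix_(perm, perm)]
        )
        sim_p = compute_similarity(net_p)
        order_p = leaf_order(sim_p)
        dist_p = ClassCentroids(net_p, ann)
        for gene in net.genes:
            e1 = represent_vertex(net, ann, order, sim, gene, 6, 4, dist=dist).E
            e2 = represent_vertex(
                net_p, ann, order_p, sim_p, gene, 6, 4, dist=dist_p
            ).E
            np.testing.assert_allclose(e1, e2)


class TestBaseline:
    def test_consecutive_successors(self, rng):
        net = dense_network(rng, 8)
        order = LeafOrder(np.arange(8), np.arange(8))
        img = represent_baseline(net, order, 0, m=3)
        assert np.all(np.diag(img.E) == 0)
        np.testing.assert_allclose(
            img.A[0, 1:], [net.weights[0, 1], net.weights[0, 2]]
        )

    def test_wraps_at_sequence_end(self, rng):
        net = dense_network(rng, 5)
        order = LeafOrder(np.arange(5), np.arange(5))
        img = represent_baseline(net, order, 4, m=3)
        np.testing.assert_allclose(
            img.A[0, 1:], [net.weights[4, 0], net.weights[4, 1]]
        )

    def test_diagonal_always_zero(self, rng):
        net, _ = _random_instance(rng, n=16)
        ds = represent_all_baseline(net, m=5)
        assert np.all(ds.images[:, np.arange(5), np.arange(5)] == 0)

    def test_matches_environment_when_selection_coincides(self, rng):
        # fabricated similarity decreasing with leaf position: the top m-1
        # window candidates for center 0 are exactly its successors 1, 2
        net = dense_network(rng, 9)
        ann = DiseaseAnnotation(tags={}, n_classes=2, target_class=1)
        order = LeafOrder(np.arange(9), np.arange(9))
        values = np.zeros((9, 9))
        for j in range(1, 9):
            values[0, j] = values[j, 0] = 1.0 / j
        values[values == 0] = 1e-3
        np.fill_diagonal(values, 1e12)
        sim = SimilarityMatrix(values=values)
        env = represent_vertex(net, ann, order, sim, 0, k=5, m=3)
        base = represent_baseline(net, order, 0, m=3)
        np.testing.assert_allclose(env.E, base.E)


class TestFusion:
    def _views(self, rng, n=12, n_views=3):
        base = dense_network(rng, n)
        views = [base]
        for v in range(1, n_views):
            w = base.weights * rng.uniform(0.8, 1.2, size=base.weights.shape)
            w = np.triu(w, 1) + np.triu(w, 1).T
            views.append(GeneNetwork(f"v{v}", base.genes, w))
        return views

    def test_identical_views_equal_single(self, rng):
        net, ann = _random_instance(rng, n=12)
        twin = GeneNetwork("twin", net.genes, net.weights)
        fused = fuse_networks([net, twin], net, ann, k=6, m=4)
        # reference alone, with min-max scaled weights (as in fusion)
        lo, hi = net.weights.min(), net.weights.max()
        scaled = GeneNetwork("s", net.genes, (net.weights - lo) / (hi - lo))
        single = fuse_networks([scaled], scaled, ann, k=6, m=4)
        np.testing.assert_allclose(fused.images, single.images, atol=1e-12)

    def test_two_view_mean_of_a_blocks(self, rng):
        views = self._views(rng, n=12, n_views=2)
        ann = DiseaseAnnotation(tags={}, n_classes=2, target_class=1)  # C = 0
        fused = fuse_networks(views, views[0], ann, k=6, m=4)
        sim = compute_similarity(views[0])
        order = leaf_order(sim)
        for i, gene in enumerate(fused.genes):
            field = select_neighborhood(views[0].index_of(gene), order, sim, 6, 4)
            blocks = []
            for v in views:
                lo, hi = v.weights.min(), v.weights.max()
                sv = GeneNetwork("s", v.genes, (v.weights - lo) / (hi - lo))
                blocks.append(build_sub_adjacency(sv, field))
            np.testing.assert_allclose(fused.images[i], np.mean(blocks, axis=0))

    def test_off_diagonal_is_mean_sub_adjacency(self, rng):
        views = self._views(rng)
        _, ann = _random_instance(rng, n=12)
        fused = fuse_networks(views, views[0], ann, k=6, m=4)
        for img in fused.images:
            off = img - np.diag(np.diag(img))
            np.testing.assert_allclose(off, off.T)

    def test_mismatched_ordering_rejected(self, rng):
        views = self._views(rng)
        _, ann = _random_instance(rng, n=12)
        other = GeneNetwork(
            "bad", list(reversed(views[1].genes)), views[1].weights
        )
        with pytest.raises(ValueError, match="ordering"):
            fuse_networks([views[0], other], views[0], ann, k=6, m=4)

    def test_reference_must_be_member(self, rng):
        views = self._views(rng)
        _, ann = _random_instance(rng, n=12)
        outsider = GeneNetwork("out", views[0].genes, views[0].weights)
        with pytest.raises(ValueError, match="reference"):
            fuse_networks(views[1:], outsider, ann, k=6, m=4)


class TestDatasetRoundTrip:
    def test_save_load(self, tmp_path, rng):
        net, ann = _random_instance(rng, n=15)
        ds = represent_all(net, ann, k=6, m=4)
        ds.save(tmp_path / "ds")
        from netimage import RepresentationDataset

        back = RepresentationDataset.load(tmp_path / "ds")
        np.testing.assert_array_equal(back.images, ds.images)
        assert back.genes == ds.genes
        assert back.params == ds.params
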