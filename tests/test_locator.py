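"""RSSI-space distances, weighted kNN position estimates, error distance."""

import dataclasses
import math

import numpy as np
import pytest

import telefall as tf
from telefall.locator import (
    DimensionError,
    LayoutError,
    LocatorConfigError,
    NodeLayout,
    NodePosition,
)
from telefall.rssi import InvalidRssiError


def random_round(layout, rng):
    return tf.RssiRound(
        wearable=rng.integers(0, 256, layout.n),
        references=rng.integers(0, 256, (layout.m, layout.n)),
        reference_ids=tuple(n.id for n in layout.reference_nodes),
        generator_ids=tuple(g.id for g in layout.rf_generators),
    )


def knn_oracle(rnd, layout, p, table, use_weighting=True):
    """Naive sort-and-recompute reference for estimate_position."""
    if use_weighting:
        w = [tf.weight_rssi(int(v), table) for v in rnd.wearable]
        mat = [[tf.weight_rssi(int(v), table) for v in row] for row in rnd.references]
    else:
        w = [float(v) for v in rnd.wearable]
        mat = [[float(v) for v in row] for row in rnd.references]
    dists = []
    for i, row in enumerate(mat):
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(w, row)))
        dists.append((d, rnd.reference_ids[i], layout.reference_nodes[i]))
    dists.sort(key=lambda t: (t[0], t[1]))
    sel = dists[:p]
    if any(d == 0 for d, _, _ in sel):
        zeros = [t for t in sel if t[0] == 0]
        weights = [(1.0 / len(zeros)) if d == 0 else 0.0 for d, _, _ in sel]
    else:
        inv = [1.0 / d**2 for d, _, _ in sel]
        weights = [v / sum(inv) for v in inv]
    x = sum(wk * node.x for wk, (_, _, node) in zip(weights, sel))
    y = sum(wk * node.y for wk, (_, _, node) in zip(weights, sel))
    return x, y


class TestRssiDistance:
    def test_identical_vectors(self):
        assert tf.rssi_distance([5, 9, 1], [5, 9, 1]) == 0.0

    def test_pythagorean(self):
        assert tf.rssi_distance([3, 0], [0, 4]) == pytest.approx(5.0)

    def test_permutation_symmetry(self):
        assert tf.rssi_distance([1, 7, 3], [2, 5, 9]) == pytest.approx(
            tf.rssi_distance([7, 3, 1], [5, 9, 2])
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            tf.rssi_distance([1, 2], [1, 2, 3])


class TestWeightRound:
    def test_all_144_maps_to_176(self, default_layout, class_table):
        rnd = tf.RssiRound(
            wearable=np.full(default_layout.n, 144),
            references=np.full((default_layout.m, default_layout.n), 144),
            reference_ids=tuple(n.id for n in default_layout.reference_nodes),
            generator_ids=tuple(g.id for g in default_layout.rf_generators),
        )
        w = tf.weight_round(rnd, class_table)
        assert np.all(w.weighted_wearable == 176.0)
        assert np.all(w.weighted_references == 176.0)
        # raw entries untouched
        assert np.all(w.wearable == 144)

    def test_matches_scalar_oracle(self, default_layout, class_table):
        rng = np.random.default_rng(3)
        rnd = random_round(default_layout, rng)
        w = tf.weight_round(rnd, class_table)
        for i in range(default_layout.m):
            for j in range(default_layout.n):
                assert w.weighted_references[i, j] == pytest.approx(
                    tf.weight_rssi(int(rnd.references[i, j]), class_table)
                )

    def test_double_weighting_rejected(self, default_layout, class_table):
        rnd = random_round(default_layout, np.random.default_rng(4))
        w = tf.weight_round(rnd, class_table)
        with pytest.raises(InvalidRssiError):
            tf.weight_round(w, class_table)

    def test_non_integer_round_rejected(self, default_layout):
        with pytest.raises(InvalidRssiError):
            tf.RssiRound(
                wearable=np.full(default_layout.n, 1.5),
                references=np.ones((default_layout.m, default_layout.n), dtype=int),
                reference_ids=tuple(n.id for n in default_layout.reference_nodes),
                generator_ids=tuple(g.id for g in default_layout.rf_generators),
            )


class TestEstimatePosition:
    def test_exact_match_with_p1_recovers_node(self, default_layout, class_table):
        rng = np.random.default_rng(7)
        rnd = random_round(default_layout, rng)
        rnd = dataclasses.replace(rnd, wearable=rnd.references[6].copy())
        w = tf.weight_round(rnd, class_table)
        est = tf.estimate_position(w, default_layout, p=1)
        node = default_layout.reference_nodes[6]
        assert (est.x, est.y) == pytest.approx((node.x, node.y))
        assert est.neighbors[0][0] == node.id

    def test_all_equal_distances_give_centroid(self, default_layout):
        rnd = tf.RssiRound(
            wearable=np.full(default_layout.n, 100),
            references=np.full((default_layout.m, default_layout.n), 110),
            reference_ids=tuple(n.id for n in default_layout.reference_nodes),
            generator_ids=tuple(g.id for g in default_layout.rf_generators),
        )
        est = tf.estimate_position(rnd, default_layout, p=default_layout.m, use_weighting=False)
        centroid = default_layout.reference_coords().mean(axis=0)
        assert (est.x, est.y) == pytest.approx(tuple(centroid))

    def test_weights_sum_to_one_and_decrease(self, default_layout, class_table):
        rng = np.random.default_rng(8)
        rnd = tf.weight_round(random_round(default_layout, rng), class_table)
        est = tf.estimate_position(rnd, default_layout, p=5)
        weights = [w for _, _, w in est.neighbors]
        dists = [d for _, d, _ in est.neighbors]
        assert sum(weights) == pytest.approx(1.0, abs=1e-9)
        assert dists == sorted(dists)
        assert weights == sorted(weights, reverse=True)

    def test_estimate_inside_neighbor_bounding_box(self, default_layout, class_table):
        rng = np.random.default_rng(9)
        for _ in range(20):
            rnd = tf.weight_round(random_round(default_layout, rng), class_table)
            p = int(rng.integers(1, 7))
            est = tf.estimate_position(rnd, default_layout, p=p)
            coords = {n.id: (n.x, n.y) for n in default_layout.reference_nodes}
            xs = [coords[nid][0] for nid, _, _ in est.neighbors]
            ys = [coords[nid][1] for nid, _, _ in est.neighbors]
            assert min(xs) - 1e-12 <= est.x <= max(xs) + 1e-12
            assert min(ys) - 1e-12 <= est.y <= max(ys) + 1e-12

    def test_matches_brute_force_oracle(self, default_layout, class_table):
        rng = np.random.default_rng(10)
        for _ in range(25):
            rnd = tf.weight_round(random_round(default_layout, rng), class_table)
            p = int(rng.integers(1, 7))
            est = tf.estimate_position(rnd, default_layout, p=p)
            ox, oy = knn_oracle(rnd, default_layout, p, class_table)
            assert est.x == pytest.approx(ox, abs=1e-12)
            assert est.y == pytest.approx(oy, abs=1e-12)

    def test_translation_equivariance(self, class_table):
        base = tf.grid_layout(8.0, 6.0, 2.0, 4)
        dx, dy = 3.0, 1.5
        shifted = NodeLayout(
            room_length=base.room_length + dx,
            room_width=base.room_width + dy,
            reference_nodes=tuple(
                NodePosition(n.id, n.x + dx, n.y + dy) for n in base.reference_nodes
            ),
            rf_generators=tuple(
                NodePosition(g.id, g.x + dx, g.y + dy) for g in base.rf_generators
            ),
            gateway=(base.gateway[0] + dx, base.gateway[1] + dy),
        )
        rng = np.random.default_rng(11)
        rnd = tf.weight_round(random_round(base, rng), class_table)
        a = tf.estimate_position(rnd, base, p=3)
        b = tf.estimate_position(rnd, shifted, p=3)
        assert (b.x, b.y) == pytest.approx((a.x + dx, a.y + dy))

    def test_multiple_zero_distances_share_weight(self, class_table):
        layout = tf.grid_layout(4.0, 4.0, 2.0, 2)
        ids = tuple(n.id for n in layout.reference_nodes)
        gids = tuple(g.id for g in layout.rf_generators)
        refs = np.full((layout.m, layout.n), 80)
        refs[0] = refs[1] = 120  # two nodes identical to the wearable
        rnd = tf.RssiRound(
            wearable=np.full(layout.n, 120), references=refs,
            reference_ids=ids, generator_ids=gids,
        )
        est = tf.estimate_position(rnd, layout, p=3, use_weighting=False)
        w = dict((nid, wk) for nid, _, wk in est.neighbors)
        assert w[ids[0]] == pytest.approx(0.5)
        assert w[ids[1]] == pytest.approx(0.5)
        third = [nid for nid, _, wk in est.neighbors if nid not in (ids[0], ids[1])][0]
        assert w[third] == 0.0

    def test_ties_broken_by_ascending_node_id(self, default_layout):
        # every node equidistant: selection must be the p lexicographically
        # smallest ids
        rnd = tf.RssiRound(
            wearable=np.full(default_layout.n, 100),
            references=np.full((default_layout.m, default_layout.n), 90),
            reference_ids=tuple(n.id for n in default_layout.reference_nodes),
            generator_ids=tuple(g.id for g in default_layout.rf_generators),
        )
        est = tf.estimate_position(rnd, default_layout, p=3, use_weighting=False)
        assert [n[0] for n in est.neighbors] == ["ref01", "ref02", "ref03"]

    def test_p_out_of_range_rejected(self, default_layout, class_table):
        rnd = tf.weight_round(
            random_round(default_layout, np.random.default_rng(0)), class_table
        )
        with pytest.raises(LocatorConfigError):
            tf.estimate_position(rnd, default_layout, p=default_layout.m + 1)
        with pytest.raises(LocatorConfigError):
            tf.estimate_position(rnd, default_layout, p=0)

    def test_weighting_requested_on_raw_round_rejected(self, default_layout):
        rnd = random_round(default_layout, np.random.default_rng(1))
        with pytest.raises(LocatorConfigError):
            tf.estimate_position(rnd, default_layout, p=4, use_weighting=True)


class TestErrorDistance:
    def test_identical_points(self):
        assert tf.error_distance((2.0, 3.0), (2.0, 3.0)) == 0.0

    def test_pythagorean(self):
        assert tf.error_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_symmetric(self):
        assert tf.error_distance((1, 2), (4, 6)) == tf.error_distance((4, 6), (1, 2))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            tf.error_distance((math.nan, 0), (0, 0))


class TestLayoutValidation:
    def test_node_outside_room_rejected(self):
        with pytest.raises(LayoutError):
            NodeLayout(
                room_length=5, room_width=5,
                reference_nodes=(NodePosition("r1", 6.0, 1.0),),
                rf_generators=(NodePosition("g1", 1.0, 1.0),),
                gateway=(2.5, 2.5),
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(LayoutError):
            NodeLayout(
                room_length=5, room_width=5,
                reference_nodes=(NodePosition("a", 1, 1), NodePosition("a", 2, 2)),
                rf_generators=(NodePosition("g1", 1.0, 1.0),),
                gateway=(2.5, 2.5),
            )


class TestSerialization:
    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_layout_round_trip(self, tmp_path, default_layout, ext):
        path = tmp_path / f"layout.{ext}"
        tf.write_layout(default_layout, path)
        assert tf.read_layout(path) == default_layout

    def test_round_csv_round_trip_bit_exact(self, tmp_path, default_layout):
        rnd = random_round(default_layout, np.random.default_rng(12))
        path = tmp_path / "round.csv"
        tf.write_round_csv(rnd, path)
        back = tf.read_round_csv(path)
        assert back.reference_ids == rnd.reference_ids
        assert back.generator_ids == rnd.generator_ids
        np.testing.assert_array_equal(back.wearable, rnd.wearable)
        np.testing.assert_array_equal(back.references, rnd.references)

    def test_estimate_json(self, tmp_path, default_layout, class_table):
        import json

        rnd = tf.weight_round(
            random_round(default_layout, np.random.default_rng(13)), class_table
        )
        est = tf.estimate_position(rnd, default_layout, p=4)
        from telefall.locator import write_estimate_json

        path = tmp_path / "estimate.json"
        write_estimate_json(est, path)
        data = json.loads(path.read_text())
        assert set(data) == {"x", "y", "p", "neighbors"}
        assert len(data["neighbors"]) == 4


class TestMaskedRounds:
    def test_dropped_entries_excluded_pairwise(self, default_layout, class_table):
        rnd = tf.simulate_round(
            default_layout, (3.0, 2.0), tf.PathLossParams(sigma_db=2.0),
            class_table, seed=5, drop_probability=0.3,
        )
        assert rnd.wearable_mask is not None
        w = tf.weight_round(rnd, class_table)
        est = tf.estimate_position(w, default_layout, p=4)
        assert np.isfinite(est.x) and np.isfinite(est.y)
        assert default_layout.contains(est.x, est.y)
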