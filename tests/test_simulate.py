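"""Matrix-level cluster expansion simulator."""

import numpy as np
import pytest

from typermat import (
    DistanceMatrix,
    SimConfig,
    add_deltas,
    block_duplicate,
    check_four_point,
    check_kalmanson,
    check_robinson,
    duplicate_leaf,
    recombine_leaf,
    replay_events,
    simulate_cluster_matrix,
)


class TestDuplicateLeaf:
    def test_row_copy(self, d3):
        out = duplicate_leaf(d3, "1", "z")
        assert out["z", "2"] == 1.0 and out["z", "3"] == 2.0 and out["z", "1"] == 0.0
        assert out.labels.index("z") == out.labels.index("1") + 1

    def test_zero_start(self):
        D = DistanceMatrix.zeros(["x", "y"])
        out = duplicate_leaf(D, "x", "z")
        assert np.all(out.values == 0.0)

    def test_divergence_after_copy(self, d3):
        out = add_deltas(duplicate_leaf(d3, "1", "z"), {"1": 1.0, "z": 1.0})
        assert out["1", "z"] == 2.0

    def test_duplicate_label_rejected(self, d3):
        with pytest.raises(ValueError):
            duplicate_leaf(d3, "1", "2")


class TestRecombineLeaf:
    def test_direct_substitution(self):
        D = DistanceMatrix.from_dict(
            ["x", "y", "u"], {("x", "y"): 2.0, ("x", "u"): 3.0, ("y", "u"): 3.0}
        )
        out = recombine_leaf(D, "x", "y", 0.5, "z")
        assert out["z", "x"] == 1.0 and out["z", "y"] == 1.0 and out["z", "u"] == 3.0
        assert out.labels == ("x", "z", "y", "u")

    def test_pure_copy_limit(self):
        D = DistanceMatrix.from_dict(
            ["x", "y", "u"], {("x", "y"): 2.0, ("x", "u"): 3.0, ("y", "u"): 3.0}
        )
        out = recombine_leaf(D, "x", "y", 1.0, "z")
        assert out["z", "x"] == 0.0 and out["z", "u"] == D["x", "u"]

    def test_child_splits_parent_distance(self):
        """d(z,x) + d(z,y) = d(x,y) for every crossover fraction."""
        D = DistanceMatrix.from_dict(
            ["x", "y", "u"], {("x", "y"): 2.0, ("x", "u"): 3.0, ("y", "u"): 3.0}
        )
        for a in (0.0, 0.25, 0.631, 1.0):
            out = recombine_leaf(D, "x", "y", a, "z")
            assert out["z", "x"] + out["z", "y"] == pytest.approx(D["x", "y"])

    def test_nonadjacent_parents_rejected_by_default(self, line4):
        with pytest.raises(ValueError):
            recombine_leaf(line4, "g1", "g3", 0.5, "z")
        out = recombine_leaf(line4, "g1", "g3", 0.5, "z", allow_nonadjacent=True)
        assert "z" in out


class TestAddDeltas:
    def test_zero_deltas_identity(self, d3):
        assert add_deltas(d3, {}).allclose(d3, 0)

    def test_explicit_values(self, d3):
        out = add_deltas(d3, {"1": 0.1, "2": 0.2, "3": 0.0})
        assert out["1", "2"] == pytest.approx(1.3)
        assert out["1", "3"] == pytest.approx(2.1)
        assert out["2", "3"] == pytest.approx(3.2)
        assert np.all(np.diag(out.values) == 0.0)

    def test_negative_delta_rejected(self, d3):
        with pytest.raises(ValueError):
            add_deltas(d3, {"1": -0.1})


class TestBlockDuplicate:
    def test_shape_and_zero_distances(self, line4):
        out = block_duplicate(line4, ["g2", "g3"], ["c2", "c3"])
        assert out.n == 6
        assert out["g2", "c2"] == 0.0 and out["g3", "c3"] == 0.0
        assert out["c2", "c3"] == line4["g2", "g3"]

    def test_single_gene_block_equals_leaf_duplication(self, line4):
        a = block_duplicate(line4, ["g2"], ["z"])
        b = duplicate_leaf(line4, "g2", "z")
        assert a.allclose(b, 0)

    def test_noncontiguous_block_rejected(self, line4):
        with pytest.raises(ValueError):
            block_duplicate(line4, ["g1", "g3"], ["a", "b"])

    def test_block_then_divergence_breaks_circular_structure(self):
        """Duplicating two genes as a unit makes the genomic order discordant
        with the gene tree, so the Kalmanson check fails in genomic order."""
        fails = 0
        for seed in range(10):
            D, _ = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="block", block_size=2, seed=seed)
            )
            fails += not check_kalmanson(D, list(D.labels)).holds
        assert fails >= 9


class TestSimulateClusterMatrix:
    def test_determinism(self):
        cfg = SimConfig(n_final=9, mode="mixed", psi=0.4, seed=11)
        D1, log1 = simulate_cluster_matrix(cfg)
        D2, log2 = simulate_cluster_matrix(cfg)
        assert D1.labels == D2.labels
        assert np.array_equal(D1.values, D2.values)
        assert len(log1.events) == len(log2.events)

    def test_replay_reproduces_matrix_exactly(self):
        for mode in ("tandem", "gehring", "mixed", "block"):
            D, log = simulate_cluster_matrix(
                SimConfig(n_final=8, mode=mode, psi=0.5, seed=5)
            )
            assert replay_events(log).allclose(D, 0)  # bit-identical

    def test_tandem_gives_tree_metric(self):
        for seed in range(5):
            D, _ = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="tandem", seed=seed)
            )
            assert check_four_point(D).holds

    def test_gehring_gives_kalmanson_in_genomic_order(self):
        for seed in range(5):
            D, _ = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="gehring", seed=seed)
            )
            assert check_kalmanson(D, list(D.labels)).holds

    def test_equal_rates_gives_robinson_in_genomic_order(self):
        for seed in range(5):
            D, _ = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="gehring", equal_rates=True, seed=seed)
            )
            assert check_robinson(D, list(D.labels)).holds

    def test_metric_at_every_size(self):
        D, log = simulate_cluster_matrix(SimConfig(n_final=10, mode="mixed", psi=0.3, seed=2))
        assert D.is_metric()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_final=2)
        with pytest.raises(ValueError):
            SimConfig(n_final=5, mode="bogus")
        with pytest.raises(ValueError):
            SimConfig(n_final=5, psi=1.5)
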