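"""Recognition of type R matrices and event-history round trips."""

import numpy as np
import pytest

from typermat import (
    DistanceMatrix,
    SimConfig,
    box_parameters,
    estimate_a,
    is_cherry,
    peel_copy,
    peel_event,
    recognize_type_r,
    simulate_cluster_matrix,
)
from typermat.recognize import PeelError, enumerate_histories


def sim_events(log):
    """Normalized (parents, child) -> a for recombinant events of a log."""
    return {
        (frozenset(e.parents), e.child): e.a
        for e in log.events
        if e.kind == "recombinant"
    }


class TestEstimateA:
    def test_worked_fixture(self, w1):
        a, spread = estimate_a(w1, "x", "y", "z")
        assert a == pytest.approx(0.3, abs=1e-12)
        assert spread <= 1e-12

    def test_pure_copy_gives_a_one(self):
        D, _ = simulate_cluster_matrix(SimConfig(n_final=6, mode="tandem", seed=1))
        # find an exact copy pair: constant row shift
        v, labs = D.values, D.labels
        found = None
        for i in range(D.n):
            for j in range(D.n):
                if i == j:
                    continue
                mask = np.ones(D.n, dtype=bool)
                mask[[i, j]] = False
                diffs = v[j, mask] - v[i, mask]
                if diffs.max() - diffs.min() < 1e-12:
                    found = (labs[i], labs[j])
        assert found is not None
        p, z = found
        other = next(w for w in labs if w not in (p, z))
        a, _ = estimate_a(D, p, other, z)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_small_matrix_rejected(self, dbox):
        with pytest.raises(ValueError):
            estimate_a(dbox, "p", "q", "r")

    def test_round_trip_last_event(self):
        """The most recent crossover is always exactly identified."""
        for seed in range(100):
            D, log = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="gehring", a_range=(0.1, 0.9), seed=seed)
            )
            last = [e for e in log.events if e.kind == "recombinant"][-1]
            a, spread = estimate_a(D, last.parents[0], last.parents[1], last.child)
            assert abs(a - last.a) <= 1e-6
            assert spread <= 1e-9


class TestPeel:
    def test_worked_fixture_full_inversion(self, w1):
        ev, reduced = peel_event(w1, "x", "y", "z", 0.3)
        assert ev.delta_z == pytest.approx(0.5, abs=1e-12)
        assert ev.f_a == pytest.approx(0.33, abs=1e-12)
        assert ev.d_xy_ancestral == pytest.approx(1.0, abs=1e-12)
        assert ev.delta_x == pytest.approx(0.1, abs=1e-12)
        assert ev.delta_y == pytest.approx(0.2, abs=1e-12)
        line = DistanceMatrix.line_metric({"u": 0, "x": 1, "y": 2, "v": 4})
        assert reduced.allclose(line, 1e-12)

    def test_boundary_a_rejected(self, w1):
        with pytest.raises(PeelError):
            peel_event(w1, "x", "y", "z", 0.0)

    def test_copy_removal_restores_matrix(self, d3):
        from typermat import add_deltas, duplicate_leaf

        grown = add_deltas(duplicate_leaf(d3, "2", "z"), {})
        ev, reduced = peel_copy(grown, "2", "z")
        assert reduced.allclose(d3, 0)
        assert ev.delta_z == pytest.approx(0.0)


class TestCherry:
    def test_adjacent_leaves_of_a_path(self, line4):
        assert is_cherry(line4, "g1", "g2")

    def test_separated_leaves_are_not(self, line4):
        assert not is_cherry(line4, "g1", "g3")

    def test_equal_arm_star(self):
        D = DistanceMatrix(
            "abcd", 2.0 * (1 - np.eye(4)), _validate=False
        )
        assert is_cherry(D, "a", "b")


class TestBoxParameters:
    def test_hand_computed_box(self, dbox):
        bp = box_parameters(dbox)
        assert bp.u == pytest.approx(2.0)
        assert bp.v == pytest.approx(1.0)
        assert all(h == pytest.approx(1.0) for h in bp.h.values())
        assert (bp.A, bp.B, bp.C) == (6.0, 8.0, 10.0)
        # diagonals of C = (p,s) and (q,r): circular order interleaves them
        i = {lab: bp.circular_order.index(lab) for lab in "pqrs"}
        assert abs(i["p"] - i["s"]) == 2 and abs(i["q"] - i["r"]) == 2

    def test_tree_quartet_degenerates(self, line4):
        bp = box_parameters(line4)
        assert bp.v == pytest.approx(0.0)
        assert bp.is_tree_like

    def test_star_collapses_to_point(self):
        D = DistanceMatrix("abcd", 2.0 * (1 - np.eye(4)), _validate=False)
        bp = box_parameters(D)
        assert bp.u == pytest.approx(0.0) and bp.v == pytest.approx(0.0)

    def test_sides_nonnegative_on_random_metrics(self):
        from .conftest import random_metric

        rng = np.random.default_rng(0)
        for _ in range(50):
            D = random_metric(4, rng)
            bp = box_parameters(D)
            assert bp.u >= -1e-12 and bp.v >= -1e-12


class TestRecognize:
    def test_any_three_point_metric_is_type_r(self, d3):
        res = recognize_type_r(d3)
        assert res.is_type_r and not res.events

    def test_tandem_histories_recovered_as_copies(self):
        for seed in range(10):
            D, _ = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="tandem", seed=seed)
            )
            res = recognize_type_r(D)
            assert res.is_type_r
            assert all(ev.kind == "copy" and ev.a in (0.0, 1.0) for ev in res.events)

    def test_crossover_histories_recognized_with_valid_events(self):
        """Recognition succeeds and returns an exactly feasible history whose
        events all lie in the set of mathematically equivalent histories."""
        for seed in range(20):
            D, log = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="gehring", a_range=(0.1, 0.9), seed=seed)
            )
            res = recognize_type_r(D)
            assert res.is_type_r
            assert len(res.events) == D.n - res.terminal_matrix.n
            hists = enumerate_histories(D)
            keys = [frozenset(ev.normalized() for ev in h) for h in hists]
            assert frozenset(ev.normalized() for ev in res.events) in keys

    def test_simulated_history_among_exact_histories(self):
        """The simulated event set (triples and crossover fractions) is always
        one of the exactly feasible histories the matrix admits."""
        for seed in range(50):
            D, log = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="gehring", a_range=(0.1, 0.9), seed=seed)
            )
            truth = sim_events(log)
            found = False
            for h in enumerate_histories(D):
                ok = len(h) == 4
                for ev in h:
                    key = (frozenset({ev.x, ev.y}), ev.z)
                    if key not in truth or abs(truth[key] - ev.a) > 1e-6:
                        ok = False
                        break
                found = found or ok
            assert found, seed

    def test_terminal_box_matches_restricted_genomic_order(self):
        """The terminal box's circular order is the genomic order restricted
        to the four terminal genes (up to rotation/reflection), and each box
        triple places a gene between its circular neighbours."""
        def circ_canon(order):
            order = list(order)
            rots = [tuple(order[i:] + order[:i]) for i in range(len(order))]
            rots += [r[::-1] for r in rots]
            return min(rots)

        for seed in range(20):
            D, log = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="gehring", a_range=(0.1, 0.9), seed=seed)
            )
            res = recognize_type_r(D)
            if res.box is None:
                continue
            term = res.terminal_matrix.labels
            restricted = [g for g in log.genomic_order if g in term]
            assert circ_canon(res.box.circular_order) == circ_canon(restricted)
            order = res.box.circular_order
            for x, y, z in res.box.equivalent_triples:
                i = order.index(z)
                assert {x, y} == {order[(i - 1) % 4], order[(i + 1) % 4]}

    def test_block_histories_rejected_in_genomic_order(self):
        rejected = 0
        for seed in range(20):
            D, _ = simulate_cluster_matrix(
                SimConfig(n_final=8, mode="block", block_size=2, seed=seed)
            )
            rejected += not recognize_type_r(D).is_type_r
        assert rejected >= 18

    def test_block_histories_are_tree_metrics_hence_type_r_when_reordered(self):
        """A block duplication is simultaneous leaf duplication: the matrix is
        additive, so order-agnostic recognition accepts it (as pure copies)."""
        D, _ = simulate_cluster_matrix(
            SimConfig(n_final=6, mode="block", block_size=2, seed=0)
        )
        res = recognize_type_r(D, use_genomic_order=False)
        assert res.is_type_r

    def test_tolerance_monotonicity(self):
        D, _ = simulate_cluster_matrix(
            SimConfig(n_final=7, mode="gehring", a_range=(0.1, 0.9), seed=3)
        )
        assert recognize_type_r(D, 1e-9).is_type_r
        assert recognize_type_r(D, 1e-6).is_type_r
        assert recognize_type_r(D, 1e-3).is_type_r

    def test_nonmetric_input_rejected(self):
        D = DistanceMatrix.from_dict(
            "abc", {("a", "b"): 1.0, ("a", "c"): 10.0, ("b", "c"): 1.0}
        )
        with pytest.raises(ValueError):
            recognize_type_r(D)
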