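import numpy as np
import pytest

from braindyn.community import MultilayerAssignment
from braindyn.dynmetrics import (AllegianceMatrix, aggregate_to_network,
                                 compare_core_periphery, core_periphery,
                                 flexibility, integration, module_allegiance,
                                 promiscuity, recruitment)


def assignment(labels):
    labels = np.asarray(labels, dtype=int)
    return MultilayerAssignment(labels=labels, Q=0.0, seed=0, gamma=1.0,
                                omega=1.0)


class TestAllegiance:
    def test_all_one_community_gives_ones(self):
        runs = [assignment(np.ones((4, 3)))] * 2
        assert np.all(module_allegiance(runs).P == 1.0)

    def test_half_coassignment_counted_by_hand(self):
        # pair (0, 1) together in 1 of 2 layers, single run
        runs = [assignment([[1, 1], [1, 2]])]
        P = module_allegiance(runs).P
        assert P[0, 1] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal_random(self, rng):
        runs = [assignment(rng.integers(1, 4, (6, 5))) for _ in range(4)]
        P = module_allegiance(runs).P
        assert np.array_equal(P, P.T)
        assert np.all(np.diag(P) == 1.0)
        assert P.min() >= 0 and P.max() <= 1

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            module_allegiance([assignment(np.ones((3, 2))),
                               assignment(np.ones((4, 2)))])


class TestRecruitmentIntegration:
    def P(self, mat):
        mat = np.asarray(mat, float)
        return AllegianceMatrix(P=mat, n_runs=1, n_layers=1)

    def test_recruitment_by_hand(self):
        # S = {0, 1}, P_01 = 0.5 -> R_0 = (1 + 0.5)/2
        P = np.eye(3)
        P[0, 1] = P[1, 0] = 0.5
        r = recruitment(self.P(P), ["a", "a", "b"])
        assert r[0] == pytest.approx(0.75)
        assert r[2] == 1.0  # alone in its system: self-term only

    def test_integration_by_hand(self):
        # N=4, S={0,1}, P_02=0.2, P_03=0.4 -> I_0 = 0.3
        P = np.eye(4)
        P[0, 2] = P[2, 0] = 0.2
        P[0, 3] = P[3, 0] = 0.4
        i = integration(self.P(P), ["a", "a", "b", "b"])
        assert i[0] == pytest.approx(0.3)

    def test_all_ones_saturates_both(self):
        P = np.ones((5, 5))
        smap = ["a", "a", "b", "b", "b"]
        assert np.allclose(recruitment(self.P(P), smap), 1.0)
        assert np.allclose(integration(self.P(P), smap), 1.0)

    def test_zero_off_system_allegiance_zero_integration(self):
        P = np.eye(4)
        P[0, 1] = P[1, 0] = 0.8
        assert np.allclose(integration(self.P(P), ["a", "a", "b", "b"])[:2], 0.0)

    def test_printed_variant_sums_within_system(self):
        P = np.eye(4)
        P[0, 1] = P[1, 0] = 0.6
        v = integration(self.P(P), ["a", "a", "b", "b"], as_printed=True)
        assert v[0] == pytest.approx((1.0 + 0.6) / 2)

    def test_single_system_integration_undefined(self):
        with pytest.raises(ValueError, match="all nodes"):
            integration(self.P(np.eye(3)), ["a", "a", "a"])

    def test_bounded_by_allegiance_range(self, rng):
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        smap = ["a", "a", "b", "b", "c", "c"]
        P = self.P(M)
        for vals in (recruitment(P, smap), integration(P, smap)):
            assert vals.min() >= M.min() - 1e-12
            assert vals.max() <= M.max() + 1e-12


class TestFlexibility:
    def test_constant_labels_zero(self):
        assert np.all(flexibility(assignment(np.ones((3, 5)))) == 0.0)

    def test_alternating_labels_maximal(self):
        labels = np.tile([1, 2, 1, 2], (2, 1))
        assert np.all(flexibility(assignment(labels)) == 1.0)

    def test_hand_counted_changes(self):
        f = flexibility(assignment([[1, 1, 2, 2, 2]]))
        assert f[0] == pytest.approx(0.25)

    def test_single_layer_undefined(self):
        with pytest.raises(ValueError):
            flexibility(assignment(np.ones((3, 1))))

    def test_relabeling_invariant(self, rng):
        labels = rng.integers(1, 4, (5, 6))
        f1 = flexibility(assignment(labels))
        f2 = flexibility(assignment(labels * 3 + 1))
        assert np.array_equal(f1, f2)


class TestPromiscuity:
    def test_boundary_identities(self):
        # node 0 stays in one community; node 2 visits all three
        labels = np.array([[1, 1, 1, 1],
                           [1, 2, 2, 1],
                           [1, 2, 3, 1]])
        psi = promiscuity(assignment(labels))
        assert psi[0] == 0.0
        assert psi[2] == 1.0

    def test_two_of_three_communities(self):
        labels = np.array([[1, 2, 1], [1, 2, 3], [3, 3, 3]])
        assert promiscuity(assignment(labels))[0] == pytest.approx(0.5)

    def test_single_community_assignment_yields_zero(self):
        assert np.all(promiscuity(assignment(np.ones((4, 3)))) == 0.0)

    def test_relabeling_invariant(self, rng):
        labels = rng.integers(1, 5, (6, 7))
        p1 = promiscuity(assignment(labels))
        p2 = promiscuity(assignment(labels + 10))
        assert np.array_equal(p1, p2)


class TestAggregation:
    def test_constant_values(self):
        out = aggregate_to_network(np.full(6, 0.7), ["a"] * 3 + ["b"] * 3)
        assert out == {"a": pytest.approx(0.7), "b": pytest.approx(0.7)}

    def test_two_node_mean(self):
        out = aggregate_to_network([0.2, 0.4, 1.0], ["s", "s", "t"])
        assert out["s"] == pytest.approx(0.3)

    def test_permutation_within_system_invariant(self, rng):
        vals = rng.random(6)
        smap = ["a", "a", "a", "b", "b", "b"]
        swapped = vals.copy()
        swapped[[0, 2]] = swapped[[2, 0]]
        assert aggregate_to_network(vals, smap) == \
            aggregate_to_network(swapped, smap)


class TestCorePeriphery:
    def test_strict_ordering(self):
        flex = np.arange(90) / 90.0
        cp = core_periphery(flex, k=10)
        assert cp.core == list(range(10))
        assert cp.periphery == list(range(80, 90))

    def test_ties_broken_by_index_with_warning(self):
        with pytest.warns(RuntimeWarning, match="ties"):
            cp = core_periphery(np.zeros(30), k=5)
        assert cp.core == [0, 1, 2, 3, 4]
        assert set(cp.core).isdisjoint(cp.periphery)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            core_periphery(np.arange(10.0), k=6)

    def test_two_group_overlap_sets(self):
        a = core_periphery(np.arange(20.0), k=3)
        b = core_periphery(np.arange(20.0)[::-1].copy(), k=3)
        out = compare_core_periphery(a, b)
        assert out["core_only_a"] == [0, 1, 2]
        assert out["core_only_b"] == [17, 18, 19]
        assert out["core_common"] == []
        assert out["periphery_common"] == []
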