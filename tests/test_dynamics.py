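import math

import networkx as nx
import numpy as np
import pytest

import spinflow as sf
from spinflow.dynamics import CapacityError, StateSpace

from .oracles import (
    oracle_boltzmann,
    oracle_joint_by_paths,
    oracle_level_weights,
    oracle_transfer_matrix,
)


class TestStateSpace:
    def test_encode_decode_roundtrip(self):
        space = StateSpace(5)
        rng = np.random.default_rng(0)
        for k in rng.integers(0, 32, size=20):
            assert space.encode(space.decode(int(k))) == int(k)
        states = rng.integers(0, 2, size=5)
        assert (space.decode(space.encode(states)) == states).all()

    def test_little_endian_convention(self):
        space = StateSpace(4)
        assert space.encode([1, 0, 0, 0]) == 1
        assert space.encode([0, 0, 0, 1]) == 8

    def test_level_members_partition_the_space(self):
        space = StateSpace(4)
        sizes = [len(space.level_members(k / 4)) for k in range(5)]
        assert sizes == [math.comb(4, k) for k in range(5)]
        assert sum(sizes) == 16

    def test_fractional_level_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            StateSpace(4).level_members(0.3)


class TestTransferOperator:
    def test_single_isolated_node_is_all_half(self):
        system = sf.SpinSystem(graph=nx.empty_graph(1), beta=3.0)
        t = sf.build_transfer_operator(system)
        assert np.allclose(t.matrix, 0.5)

    def test_infinite_temperature_entries(self):
        system = sf.SpinSystem(graph=sf.make_kite(), beta=0.0)
        t = sf.build_transfer_operator(system)
        n, size = 10, 1024
        off = t.matrix.copy()
        np.fill_diagonal(off, 0.0)
        assert np.allclose(np.sort(off, axis=1)[:, -n:], 1 / (2 * n))
        assert np.allclose(np.diag(t.matrix), 0.5)

    def test_triangle_matches_entrywise_oracle(self, triangle_system):
        t = sf.build_transfer_operator(triangle_system)
        expected = oracle_transfer_matrix(triangle_system.graph, 1.0)
        assert np.allclose(t.matrix, expected, atol=1e-14)

    def test_rows_stochastic_and_single_flip_support(self, kite_transfer):
        m = kite_transfer.matrix
        assert (m >= 0).all()
        assert np.abs(m.sum(axis=1) - 1).max() < 1e-12
        ks = np.arange(kite_transfer.space.size)
        hamming = np.bitwise_count(ks[:, None] ^ ks[None, :])
        assert (m[hamming > 1] == 0).all()

    @pytest.mark.parametrize("power", [1, 10, 100])
    def test_powers_remain_row_stochastic(self, triangle_transfer, power):
        m = np.linalg.matrix_power(triangle_transfer.matrix, power)
        assert np.abs(m.sum(axis=1) - 1).max() < 1e-10
        assert m.min() >= -1e-15

    def test_capacity_cap_enforced(self):
        system = sf.SpinSystem(graph=sf.make_kite(), beta=1.0)
        with pytest.raises(CapacityError, match="Monte Carlo"):
            sf.build_transfer_operator(system, cap=8)


class TestStationaryDistribution:
    def test_infinite_temperature_is_uniform(self):
        system = sf.SpinSystem(graph=nx.complete_graph(3), beta=0.0)
        pi = sf.stationary_distribution(sf.build_transfer_operator(system))
        assert np.allclose(pi, 1 / 8, atol=1e-12)

    def test_matches_boltzmann_enumeration(self, triangle_system, triangle_transfer):
        pi = sf.stationary_distribution(triangle_transfer)
        expected = oracle_boltzmann(triangle_system.graph, 1.0)
        assert np.abs(pi - expected).max() < 1e-12

    def test_global_flip_symmetry(self, kite_transfer, kite_pi):
        complement = (1 << 10) - 1
        assert np.abs(kite_pi - kite_pi[np.arange(1024) ^ complement]).max() < 1e-10

    def test_detailed_balance(self, kite_transfer, kite_pi):
        """Glauber dynamics is reversible w.r.t. its stationary distribution."""
        m = kite_transfer.matrix
        flow = kite_pi[:, None] * m
        assert np.abs(flow - flow.T).max() < 1e-10


class TestFreeEnergyProfile:
    def test_infinite_temperature_is_binomial(self):
        system = sf.SpinSystem(graph=nx.complete_graph(4), beta=0.0)
        t = sf.build_transfer_operator(system)
        profile = sf.free_energy_profile(sf.stationary_distribution(t), t.space)
        for k in range(5):
            expected = -math.log(math.comb(4, k) / 16)
            assert profile[k / 4] == pytest.approx(expected, abs=1e-9)
        assert min(profile, key=profile.get) == 0.5

    def test_profile_symmetric_under_global_flip(self, kite_pi, kite_transfer):
        profile = sf.free_energy_profile(kite_pi, kite_transfer.space)
        for gamma, value in profile.items():
            assert value == pytest.approx(profile[round(1 - gamma, 10)], abs=1e-9)

    def test_kite_is_bistable_with_interior_barrier(self, kite_pi, kite_transfer):
        profile = sf.free_energy_profile(kite_pi, kite_transfer.space)
        assert profile[0.5] > profile[0.0]
        assert profile[0.5] > profile[1.0]
        assert profile[0.5] == max(profile.values())

    def test_unnormalized_input_rejected(self, kite_transfer):
        with pytest.raises(ValueError, match="normalized"):
            sf.free_energy_profile(np.ones(1024), kite_transfer.space)


class TestConditionalDistribution:
    def test_ground_level_is_point_mass(self, kite_transfer, kite_pi):
        level = sf.conditional_state_distribution(kite_pi, kite_transfer.space, 0.0)
        assert level.member_states.tolist() == [0]
        assert level.conditional_dist.tolist() == [1.0]

    def test_infinite_temperature_is_uniform_within_level(self):
        system = sf.SpinSystem(graph=sf.make_kite(), beta=0.0)
        t = sf.build_transfer_operator(system)
        pi = sf.stationary_distribution(t)
        level = sf.conditional_state_distribution(pi, t.space, 0.3)
        assert len(level.member_states) == math.comb(10, 3)
        assert np.allclose(level.conditional_dist, 1 / math.comb(10, 3), atol=1e-10)

    def test_matches_boltzmann_restriction(self, kite_system, kite_transfer, kite_pi):
        level = sf.conditional_state_distribution(kite_pi, kite_transfer.space, 0.1)
        expected_full = oracle_level_weights(kite_system.graph, kite_system.beta, 0.1)
        assert len(level.member_states) == 10
        got = level.full_vector(kite_transfer.space)
        assert np.abs(got - expected_full).max() < 1e-10

    def test_infeasible_level_rejected(self, kite_transfer, kite_pi):
        with pytest.raises(ValueError, match="multiple"):
            sf.conditional_state_distribution(kite_pi, kite_transfer.space, 0.25)


class TestEvolveJoint:
    def test_lag_zero_is_deterministic_in_the_bit(self, kite_transfer, kite_pi):
        level = sf.conditional_state_distribution(kite_pi, kite_transfer.space, 0.2)
        joint = sf.evolve_joint(kite_transfer, level, 5, 0)
        bit = kite_transfer.space.states[:, 5]
        assert joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert joint[0][bit == 1].sum() == 0.0
        assert joint[1][bit == 0].sum() == 0.0

    def test_marginals_consistent_over_time(self, kite_transfer, kite_pi):
        level = sf.conditional_state_distribution(kite_pi, kite_transfer.space, 0.3)
        j0 = sf.evolve_joint(kite_transfer, level, 2, 0)
        j5 = sf.evolve_joint(kite_transfer, level, 2, 5)
        # the time-0 node marginal is preserved by propagation
        assert np.allclose(j0.sum(axis=1), j5.sum(axis=1), atol=1e-12)
        assert j5.sum() == pytest.approx(1.0, abs=1e-12)

    def test_triangle_matches_path_enumeration(self, triangle_system, triangle_transfer):
        pi = sf.stationary_distribution(triangle_transfer)
        level = sf.conditional_state_distribution(pi, triangle_transfer.space, 1 / 3)
        got = sf.evolve_joint(triangle_transfer, level, 0, 2)
        expected = oracle_joint_by_paths(triangle_system.graph, 1.0, 1 / 3, 0, 2)
        assert np.abs(got - expected).max() < 1e-12
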