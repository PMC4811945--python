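"""Energy function, exact distributions, rate theory, and run statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikecsp import NetworkSpec, NeuronParams, simulate
from spikecsp.energy import (
    EnergyModel,
    all_states,
    apply_temperature,
    boltzmann_exact,
    empirical_distribution,
    energy,
    energy_jump_histogram,
    event_rate_gibbs,
    event_rate_spiking,
    marginal_energy,
    ncc_membrane,
    rate_ratio,
    tv_distance,
    undefined_variable_stats,
)
from spikecsp.simulator import StateChange, state_at, state_change_times


def model(b, W):
    return EnergyModel(np.asarray(b, float), np.asarray(W, float))


class TestEnergy:
    def test_zero_state_has_zero_energy(self):
        m = model([1.0, -2.0], [[0, 0.5], [0.5, 0]])
        assert energy([0, 0], m) == 0.0

    def test_single_unit(self):
        assert energy([1], model([2.0], [[0.0]])) == pytest.approx(-2.0)

    def test_pairwise_term_counted_once(self):
        m = model([0, 0], [[0, 1], [1, 0]])
        assert energy([1, 1], m) == pytest.approx(-1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            energy([1, 0, 1], model([0, 0], [[0, 0], [0, 0]]))

    def test_asymmetric_weights_rejected(self):
        with pytest.raises(ValueError):
            model([0, 0], [[0, 1], [2, 0]])


class TestBoltzmannExact:
    def test_single_unit_sigmoid(self):
        for b in (-1.0, 0.0, 2.5):
            p = boltzmann_exact(model([b], [[0.0]]))
            assert p[1] == pytest.approx(1 / (1 + math.exp(-b)))

    def test_uniform_for_flat_model(self):
        p = boltzmann_exact(model([0, 0, 0], np.zeros((3, 3))))
        assert np.allclose(p, 1 / 8)

    def test_two_coupled_units(self):
        p = boltzmann_exact(model([0, 0], [[0, 1], [1, 0]]))
        assert p[3] == pytest.approx(math.e / (3 + math.e))

    def test_too_large_rejected(self):
        with pytest.raises(ValueError):
            all_states(21)


class TestTemperature:
    def test_identity_at_unit_temperature(self, small_symmetric_model):
        m = apply_temperature(small_symmetric_model, 1.0)
        assert np.allclose(m.biases, small_symmetric_model.biases)
        assert np.allclose(m.weights, small_symmetric_model.weights)

    def test_high_temperature_flattens(self, small_symmetric_model):
        p = boltzmann_exact(apply_temperature(small_symmetric_model, 1e9))
        assert np.allclose(p, 1 / len(p), atol=1e-6)

    def test_half_temperature_doubles_energy_gaps(self, small_symmetric_model):
        m2 = apply_temperature(small_symmetric_model, 0.5)
        x, y = [1, 0, 1, 0, 1, 0], [0, 1, 1, 0, 0, 1]
        gap = energy(x, small_symmetric_model) - energy(y, small_symmetric_model)
        gap2 = energy(x, m2) - energy(y, m2)
        assert gap2 == pytest.approx(2 * gap)

    def test_cooling_sharpens_the_mode(self, small_symmetric_model):
        p = boltzmann_exact(small_symmetric_model)
        pc = boltzmann_exact(apply_temperature(small_symmetric_model, 0.5))
        assert pc[np.argmax(p)] > p.max()

    def test_invalid_temperature(self, small_symmetric_model):
        with pytest.raises(ValueError):
            apply_temperature(small_symmetric_model, 0.0)


class TestNCC:
    def test_uncoupled_reduces_to_bias(self):
        m = model([0.7, -0.3], np.zeros((2, 2)))
        for x in ([0, 0], [0, 1], [1, 1]):
            assert ncc_membrane(0, x, m) == pytest.approx(0.7)

    def test_equals_conditional_log_odds(self, small_symmetric_model):
        """u_k must equal log p(x_k=1|rest) - log p(x_k=0|rest) (enumeration)."""
        m = small_symmetric_model
        p = boltzmann_exact(m)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 2, size=m.n_units)
            k = int(rng.integers(m.n_units))
            i1 = int(sum((x[j] if j != k else 1) << j for j in range(m.n_units)))
            i0 = int(sum((x[j] if j != k else 0) << j for j in range(m.n_units)))
            assert ncc_membrane(k, x, m) == pytest.approx(
                math.log(p[i1]) - math.log(p[i0])
            )

    def test_two_unit_example(self):
        m = model([0, 0], [[0, 1], [1, 0]])
        assert ncc_membrane(0, [0, 1], m) == pytest.approx(1.0)


class TestRateTheory:
    def test_spiking_rate_examples(self):
        assert event_rate_spiking(0.0, 0.010) == pytest.approx(100.0)
        assert event_rate_spiking(50.0, 0.010) == pytest.approx(200.0)  # saturation 2/tau
        assert event_rate_spiking(-50.0, 0.010) == pytest.approx(0.0, abs=1e-15)

    def test_gibbs_rate_examples(self):
        assert event_rate_gibbs(0.0, 1.0) == pytest.approx(0.5)
        assert event_rate_gibbs(5.0, 1.0) == pytest.approx(event_rate_gibbs(-5.0, 1.0))
        assert event_rate_gibbs(50.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_ratio_example(self):
        assert rate_ratio(0.0, 0.010, 1.0) == pytest.approx(200.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(u=st.floats(-30, 30), tau=st.floats(1e-3, 1.0), rho0=st.floats(0.1, 10.0))
    def test_ratio_is_exactly_the_quotient(self, u, tau, rho0):
        q = event_rate_spiking(u, tau) / event_rate_gibbs(u, rho0)
        assert abs(rate_ratio(u, tau, rho0) - q) <= 1e-12 * q

    def test_ratio_monotone_increasing(self):
        us = np.linspace(-10, 10, 101)
        vals = rate_ratio(us, 0.010, 1.0)
        assert np.all(np.diff(vals) > 0)


class TestJumpHistogram:
    def test_empty_changes(self):
        h = energy_jump_histogram([], model([1.0], [[0.0]]))
        assert h.total_transitions == 0 and h.counts.sum() == 0

    def test_single_on_change_jump_is_minus_bias(self):
        h = energy_jump_histogram(
            [StateChange(0.0, 0, True)], model([2.0], [[0.0]])
        )
        assert h.jumps[0] == pytest.approx(-2.0)

    def test_closed_trajectory_telescopes_to_zero(self, small_symmetric_model):
        rng = np.random.default_rng(5)
        n = small_symmetric_model.n_units
        x = np.zeros(n, dtype=int)
        changes = []
        for t in range(200):
            k = int(rng.integers(n))
            x[k] ^= 1
            changes.append(StateChange(float(t), k, bool(x[k])))
        for k in np.flatnonzero(x):  # return to the all-off start state
            changes.append(StateChange(1000.0 + k, int(k), False))
        h = energy_jump_histogram(changes, small_symmetric_model)
        assert float(np.sum(h.jumps)) == pytest.approx(0.0, abs=1e-9)


class TestUndefinedStats:
    def _net(self):
        net = NetworkSpec()
        ids = [net.add_neuron(NeuronParams(bias=-30.0), principal=True) for _ in range(4)]
        net.wta_groups = {"a": ids[:2], "b": ids[2:]}
        return net, ids

    def test_clamped_one_per_group_is_all_defined(self):
        net, ids = self._net()
        traj = simulate(net, t_end=0.005, seed=0, initial=[ids[0], ids[2]])
        stats = undefined_variable_stats(traj)
        assert set(stats.counts) == {0}

    def test_initial_all_off_counts_both_groups_undefined(self):
        net, _ = self._net()
        traj = simulate(net, t_end=0.005, seed=0)
        stats = undefined_variable_stats(traj)
        assert stats.counts.get(2, 0) >= 1

    def test_agrees_with_brute_force_recount(self):
        from spikecsp import Trajectory

        net, ids = self._net()
        traj = Trajectory(  # three spikes at distinct times -> 6 distinct changes
            times=np.array([0.001, 0.004, 0.012]),
            neurons=np.array([ids[0], ids[1], ids[2]]),
            t_end=0.5,
            network=net,
        )
        stats = undefined_variable_stats(traj)
        # recount by evaluating state_at just after each change
        changes = [c for c in state_change_times(traj) if not (c.time == 0.0 and c.on)]
        expected = {}
        eval_times = [0.0] + [c.time + 1e-9 for c in changes]
        for t in eval_times:
            x = state_at(traj, min(t, traj.t_end))
            k = sum(
                1
                for members in net.wta_groups.values()
                if sum(x[m] for m in members) != 1
            )
            expected[k] = expected.get(k, 0) + 1
        assert stats.counts == expected


class TestMarginalEnergy:
    def test_no_auxiliary_is_shifted_energy_table(self, small_symmetric_model):
        m = small_symmetric_model
        Em = marginal_energy(m, list(range(m.n_units)))
        X = all_states(m.n_units)
        E = np.array([energy(x, m) for x in X])
        assert np.allclose(Em, E - E.min())

    def test_uncoupled_auxiliary_changes_nothing(self):
        m = model([0.5, -0.5], [[0, 0.8], [0.8, 0]])
        W = np.zeros((3, 3))
        W[:2, :2] = m.weights
        joint = model([0.5, -0.5, 1.7], W)
        assert np.allclose(marginal_energy(joint, [0, 1]), marginal_energy(m, [0, 1]))

    def test_matches_marginalized_enumeration(self):
        rng = np.random.default_rng(8)
        W = rng.normal(scale=0.5, size=(3, 3))
        W = np.triu(W, 1)
        W = W + W.T
        joint = model(rng.normal(size=3), W)
        Em = marginal_energy(joint, [0, 1])
        p = boltzmann_exact(joint)
        pm = np.zeros(4)
        for i, x in enumerate(all_states(3)):
            pm[int(x[0]) + 2 * int(x[1])] += p[i]
        expected = -np.log(pm)
        assert np.allclose(Em, expected - expected.min())


def test_spiking_network_samples_its_boltzmann_distribution(two_neuron_net):
    """Time-weighted occupancy of a symmetric 2-neuron network matches the
    exact Boltzmann distribution (p(1,1) = e / (3 + e))."""
    traj = simulate(two_neuron_net, t_end=400.0, seed=2)
    emp = empirical_distribution(traj, [0, 1], burn_in=1.0)
    exact = boltzmann_exact(model([0, 0], [[0, 1], [1, 0]]))
    assert tv_distance(emp, exact) < 0.02
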