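"""TSP compiler, readout, oracles, and TSPLIB I/O."""

import numpy as np
import pytest

from spikecsp import Trajectory, simulate
from spikecsp import tsp
from spikecsp.simulator import StateChange


@pytest.fixture
def inst4():
    costs = np.array(
        [
            [0.0, 1.0, 2.0, 4.0],
            [1.0, 0.0, 1.5, 2.0],
            [2.0, 1.5, 0.0, 1.0],
            [4.0, 2.0, 1.0, 0.0],
        ]
    )
    return tsp.TSPInstance(costs=costs)


@pytest.fixture
def net4(inst4):
    return tsp.compile_tsp(inst4, tsp.TSPNetworkParams(N_resting=1))


def make_traj(tspnet, spikes):
    """Hand-built trajectory from (time, step, city) spikes."""
    times = np.array([t for t, _, _ in spikes])
    neurons = np.array([tspnet.modules[s][c] for _, s, c in spikes])
    return Trajectory(times=times, neurons=neurons, t_end=1.0, network=tspnet.net)


class TestNormalizeCosts:
    def test_divides_by_max(self):
        inst = tsp.TSPInstance(costs=[[0, 1, 2], [1, 0, 4], [2, 4, 0]])
        c = tsp.normalize_costs(inst)
        assert sorted(set(c[~np.eye(3, dtype=bool)])) == [0.25, 0.5, 1.0]

    def test_normalized_matrix_unchanged(self):
        m = np.array([[0, 0.5, 1.0], [0.5, 0, 0.25], [1.0, 0.25, 0]])
        assert np.allclose(tsp.normalize_costs(tsp.TSPInstance(costs=m)), m)

    def test_symmetry_preserved(self, inst4):
        c = tsp.normalize_costs(inst4)
        assert np.allclose(c, c.T)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tsp.normalize_costs(tsp.TSPInstance(costs=np.zeros((3, 3))))


class TestCompile:
    @pytest.mark.parametrize(
        "n,nr,neurons",
        [(38, 7, 1755), (39, 8, 1880), (4, 1, 25)],
    )
    def test_neuron_count(self, n, nr, neurons):
        inst = tsp.generate_planar_instance(n, seed=1)
        tn = tsp.compile_tsp(inst, tsp.TSPNetworkParams(N_resting=nr))
        assert tn.net.n_neurons == neurons == tsp.neuron_count_formula(n, nr)

    @pytest.mark.parametrize("n,nr", [(4, 1), (5, 2), (6, 0), (3, 3)])
    def test_connection_count_formula(self, n, nr):
        inst = tsp.generate_planar_instance(n, seed=2)
        tn = tsp.compile_tsp(inst, tsp.TSPNetworkParams(N_resting=nr))
        assert tn.connection_count() == tsp.connection_count_formula(n, nr)

    def test_cost_weights_follow_rescaling_rule(self, inst4, net4):
        ctil = tsp.normalize_costs(inst4)
        p = net4.params
        for n in range(net4.n_steps):
            m = (n + 1) % net4.n_steps
            for i in range(4):
                for j in range(4):
                    w = net4.net.weight(net4.modules[n][i], net4.modules[m][j])
                    if i == j:
                        assert w == 0.0  # same-city adjacent pairs unconnected
                    else:
                        assert w == pytest.approx(
                            p.w_offset + (1 - ctil[i, j]) * p.w_scale
                        )

    def test_uniqueness_weights_in_nonadjacent_modules(self, inst4):
        tn = tsp.compile_tsp(inst4, tsp.TSPNetworkParams(N_resting=2))
        # modules 0 and 2 are non-adjacent in a 6-ring; 0 and 1 adjacent
        assert tn.net.weight(tn.modules[0][2], tn.modules[2][2]) == pytest.approx(-14.7)
        assert tn.net.weight(tn.modules[0][2], tn.modules[1][2]) == 0.0

    def test_principal_weights_symmetric(self, net4):
        W = net4.net.weight_matrix(net4.net.principal_ids)
        assert np.allclose(W, W.T)

    def test_first_module_clamped(self, net4):
        p = net4.params
        assert net4.net.neurons[net4.modules[0][0]].bias == p.b_P
        assert all(net4.net.neurons[net4.modules[0][i]].bias == p.b_N for i in (1, 2, 3))
        assert all(
            net4.net.neurons[net4.modules[1][i]].bias == p.b_WTA for i in range(4)
        )

    def test_too_few_cities(self):
        with pytest.raises(ValueError):
            tsp.compile_tsp(tsp.TSPInstance(costs=np.ones((2, 2)) - np.eye(2)))


class TestReadout:
    def test_no_spikes_is_undefined_and_invalid(self, net4):
        traj = make_traj(net4, [])
        r = tsp.read_tour(traj, 0.5, net4)
        assert all(s is tsp.UNDEFINED for s in r.steps) and not r.valid

    def test_consecutive_duplicates_collapse(self, inst4):
        # 3 cities over 4 modules visiting 1,2,2,3 -> tour (1,2,3), valid
        inst3 = tsp.TSPInstance(costs=inst4.costs[:3, :3])
        tn = tsp.compile_tsp(inst3, tsp.TSPNetworkParams(N_resting=1))
        traj = make_traj(tn, [(0.01, 0, 0), (0.02, 1, 1), (0.03, 2, 1), (0.04, 3, 2)])
        r = tsp.read_tour(traj, 0.05, tn)
        assert r.valid and r.collapsed_tour == [0, 1, 2]

    def test_nonconsecutive_repeat_invalid(self, inst4):
        inst3 = tsp.TSPInstance(costs=inst4.costs[:3, :3])
        tn = tsp.compile_tsp(inst3, tsp.TSPNetworkParams(N_resting=1))
        traj = make_traj(tn, [(0.01, 0, 1), (0.02, 1, 0), (0.03, 2, 1), (0.04, 3, 2)])
        assert not tsp.read_tour(traj, 0.05, tn).valid

    def test_most_recent_outlives_psp(self, net4):
        # the spike's PSP has long expired at t=0.5; readout still sees it
        traj = make_traj(net4, [(0.01, 0, 0)])
        assert tsp.read_tour(traj, 0.5, net4).steps[0] == 0

    def test_tour_cost_all_ones(self):
        inst = tsp.TSPInstance(costs=np.ones((3, 3)) - np.eye(3))
        r = tsp.TourReadout([0, 1, 2], [0, 1, 2], True, None)
        assert tsp.tour_cost(r, inst) == pytest.approx(3.0)

    def test_reversed_symmetric_tour_same_cost(self, inst4):
        a = tsp.TourReadout([0, 1, 2, 3], [0, 1, 2, 3], True, None)
        b = tsp.TourReadout([0, 3, 2, 1], [0, 3, 2, 1], True, None)
        assert tsp.tour_cost(a, inst4) == pytest.approx(tsp.tour_cost(b, inst4))

    def test_invalid_readout_rejected(self, inst4):
        r = tsp.TourReadout([0, 1, 1, 2], [0, 1, 2], False, None)
        with pytest.raises(ValueError):
            tsp.tour_cost(r, inst4)


class TestPerformanceTrace:
    def test_held_optimum_gives_one(self, inst4, net4):
        tour, opt = tsp.brute_force_tsp(inst4)
        spikes = [(0.001 * (s + 1), s, tour[s % 4]) for s in range(5)]
        traj = make_traj(net4, spikes)
        perf = tsp.performance_trace(traj, inst4, [0.5], net4)
        assert perf[0] == pytest.approx(1.0)

    def test_never_exceeds_one(self, inst4, net4):
        traj = simulate(net4.net, t_end=2.0, seed=3)
        perf = tsp.performance_trace(traj, inst4, np.linspace(0.1, 2.0, 20), net4)
        assert np.all((perf[~np.isnan(perf)] <= 1.0 + 1e-12))


class TestStateChangesToCost:
    def test_unreachable_threshold(self, inst4, net4):
        _, opt = tsp.brute_force_tsp(inst4)
        traj = simulate(net4.net, t_end=2.0, seed=1)
        assert tsp.state_changes_to_cost(traj, net4, opt * 0.5) is None

    def test_infinite_threshold_hits_first_valid_tour(self, inst4, net4):
        traj = simulate(net4.net, t_end=2.0, seed=1)
        n_inf = tsp.state_changes_to_cost(traj, net4, np.inf)
        assert n_inf is not None and n_inf >= 1

    def test_monotone_in_threshold(self, inst4, net4):
        _, opt = tsp.brute_force_tsp(inst4)
        traj = simulate(net4.net, t_end=5.0, seed=2)
        counts = [
            tsp.state_changes_to_cost(traj, net4, th)
            for th in (opt, opt * 1.3, np.inf)
        ]
        defined = [c for c in counts if c is not None]
        assert sorted(defined, reverse=True) == defined


class TestGenerators:
    def test_planar_triangle_inequality(self):
        inst = tsp.generate_planar_instance(8, seed=5)
        c = inst.costs
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert c[i, j] <= c[i, k] + c[k, j] + 1e-12

    def test_seed_reproducibility(self):
        a = tsp.generate_planar_instance(6, seed=9)
        b = tsp.generate_planar_instance(6, seed=9)
        assert np.array_equal(a.costs, b.costs)
        c = tsp.generate_asymmetric_instance(6, seed=9)
        d = tsp.generate_asymmetric_instance(6, seed=9)
        assert np.array_equal(c.costs, d.costs)

    def test_symmetric_flag_consistency(self):
        assert tsp.generate_planar_instance(5, seed=1).symmetric
        assert not tsp.generate_asymmetric_instance(5, seed=1).symmetric


class TestOracles:
    def test_three_city_cost(self):
        c = np.array([[0, 1, 5], [2, 0, 1], [1, 4, 0]], dtype=float)
        _, cost = tsp.brute_force_tsp(tsp.TSPInstance(costs=c))
        # asymmetric: min of the two orientations 0->1->2->0 and 0->2->1->0
        assert cost == pytest.approx(min(1 + 1 + 1, 5 + 4 + 2))

    def test_all_equal_costs(self):
        inst = tsp.TSPInstance(costs=3.0 * (np.ones((5, 5)) - np.eye(5)))
        _, cost = tsp.brute_force_tsp(inst)
        assert cost == pytest.approx(15.0)

    @pytest.mark.parametrize("gen", ["planar", "asymmetric"])
    def test_brute_force_agrees_with_held_karp(self, gen):
        inst = (
            tsp.generate_planar_instance(8, seed=3)
            if gen == "planar"
            else tsp.generate_asymmetric_instance(8, seed=3)
        )
        _, bf = tsp.brute_force_tsp(inst)
        _, hk = tsp.held_karp_tsp(inst)
        assert bf == pytest.approx(hk)


class TestTSPLIB:
    def test_euc2d_rounding(self, tmp_path):
        p = tmp_path / "toy.tsp"
        p.write_text(
            "NAME: toy\nTYPE: TSP\nDIMENSION: 3\nEDGE_WEIGHT_TYPE: EUC_2D\n"
            "NODE_COORD_SECTION\n1 0 0\n2 3 4\n3 0 10\nEOF\n"
        )
        inst = tsp.read_tsplib(p)
        expected = np.array([[0, 5, 10], [5, 0, 7], [10, 7, 0]], dtype=float)
        assert np.array_equal(inst.costs, expected)  # nint(6.708) = 7

    def test_full_matrix_round_trip(self, tmp_path, inst4):
        p = tmp_path / "m.tsp"
        tsp.write_tsplib(inst4, p)
        back = tsp.read_tsplib(p)
        assert np.allclose(back.costs, inst4.costs)

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "bad.tsp"
        p.write_text("NAME toy without colon\nDIMENSION: 3\n")
        with pytest.raises(ValueError, match="malformed"):
            tsp.read_tsplib(p)

    def test_unsupported_dialect_named(self, tmp_path):
        p = tmp_path / "geo.tsp"
        p.write_text(
            "NAME: g\nDIMENSION: 3\nEDGE_WEIGHT_TYPE: GEO\n"
            "NODE_COORD_SECTION\n1 0 0\n2 1 1\n3 2 2\nEOF\n"
        )
        with pytest.raises(ValueError, match="GEO"):
            tsp.read_tsplib(p)


def test_low_cost_tours_have_lower_principal_energy():
    """Over clamped valid 5-city tour states, the Boltzmann energy of the
    principal network decreases as total (1 - normalized cost) weight
    increases, i.e. it is anti-monotone with tour cost."""
    from itertools import permutations

    from spikecsp.energy import energy
    from spikecsp.gibbs import spiking_model_to_gibbs

    inst = tsp.generate_planar_instance(5, seed=11)
    tn = tsp.compile_tsp(inst, tsp.TSPNetworkParams(N_resting=0, clamp_first=False))
    model, ids = spiking_model_to_gibbs(tn.net, mode="principal")
    index = {nid: i for i, nid in enumerate(ids)}
    rows = []
    for perm in permutations(range(1, 5)):
        tour = (0,) + perm
        x = np.zeros(model.n_units)
        for step, city in enumerate(tour):
            x[index[tn.modules[step][city]]] = 1.0
        cost = sum(inst.costs[tour[i], tour[(i + 1) % 5]] for i in range(5))
        rows.append((cost, energy(x, model)))
    rows.sort()
    costs = np.array([r[0] for r in rows])
    energies = np.array([r[1] for r in rows])
    # strictly increasing energy with cost (equal costs share equal energy)
    for i in range(len(rows) - 1):
        if costs[i + 1] > costs[i] + 1e-12:
            assert energies[i + 1] > energies[i]
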