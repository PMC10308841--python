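"""Path energy, temperature schedule, Metropolis steps and the annealer,
checked against enumeration and dynamic-programming oracles."""

import math

import numpy as np
import pytest

import pathmorph as pm
from pathmorph import fixtures as fx
from pathmorph.annealing import EdgeCosts


def _single_atom_ensemble(positions):
    """Toy ensemble with one-atom 'frames' at given positions.

    ``positions[w][m]`` is the x-coordinate of model m in window w; neighbour
    RMSD is then just |x1 - x2|, so energies are hand-computable.
    """
    atoms = [pm.AtomRecord(1, "CA", "C", "BEA", 1)]
    windows = []
    for col in positions:
        windows.append([pm.StructureFrame(atoms, np.array([[x, 0.0, 0.0]]))
                        for x in col])
    n_models = max(len(c) for c in windows)
    pinned = len(windows[0]) == 1 and len(windows[-1]) == 1
    return pm.ModelEnsemble(windows, n_models, pinned_endpoints=pinned)


class TestPathEnergy:
    def test_rms_of_constant_neighbor_rmsd(self):
        ens = _single_atom_ensemble([[0.0], [2.0], [4.0], [6.0]])
        assert np.isclose(pm.path_energy(ens, [0, 0, 0, 0]), 2.0)

    def test_identical_frames_zero_energy(self):
        ens = _single_atom_ensemble([[1.0], [1.0, 1.0], [1.0, 1.0], [1.0]])
        assert pm.path_energy(ens, [0, 1, 0, 0]) == 0.0

    def test_matches_hand_computation_on_toy_ensemble(self):
        # 4 windows, pinned ends, 2 models in each interior window
        pos = [[0.0], [1.0, 3.0], [2.0, 5.0], [6.0]]
        ens = _single_atom_ensemble(pos)
        for i in range(2):
            for j in range(2):
                p = [0, i, j, 0]
                d = [abs(pos[1][i] - 0.0), abs(pos[2][j] - pos[1][i]),
                     abs(6.0 - pos[2][j])]
                expected = math.sqrt(sum(x * x for x in d) / 3.0)
                assert np.isclose(pm.path_energy(ens, p), expected)

    def test_invalid_path_rejected(self):
        ens = _single_atom_ensemble([[0.0], [1.0, 2.0], [3.0]])
        with pytest.raises(IndexError):
            pm.path_energy(ens, [0, 5, 0])

    def test_rigid_translation_invariance(self, rng):
        ens = fx.make_random_ensemble(5, 3, jitter=1.0, seed=8)
        shift = np.array([7.0, -3.0, 2.0])
        shifted = pm.ModelEnsemble(
            [[m.with_coords(m.coords + shift) for m in w] for w in ens.windows],
            ens.n_models, ens.pinned_endpoints)
        for _ in range(5):
            p = [0] + list(rng.integers(0, 3, size=3)) + [0]
            assert np.isclose(pm.path_energy(ens, p),
                              pm.path_energy(shifted, p), atol=1e-10)


class TestTemperatureSchedule:
    def test_initial_temperature_is_t0(self):
        sched = pm.AnnealSchedule()
        assert pm.temperature(sched, 0) == 50.0

    def test_final_temperature_is_t_end(self):
        sched = pm.AnnealSchedule()
        assert np.isclose(pm.temperature(sched, sched.s_max), 0.1)

    def test_strictly_decreasing(self):
        sched = pm.AnnealSchedule(T0=50.0, s_max=500, T_end=0.1)
        temps = [pm.temperature(sched, s) for s in range(0, 501, 25)]
        assert all(a > b for a, b in zip(temps, temps[1:]))

    def test_out_of_range_step_rejected(self):
        with pytest.raises(ValueError):
            pm.temperature(pm.AnnealSchedule(), -1)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            pm.AnnealSchedule(T0=0.1, T_end=50.0)
        with pytest.raises(ValueError):
            pm.AnnealSchedule(form="linear")


class TestMcStep:
    def test_downhill_always_accepted(self, rng):
        # start from the worst path of a planted ensemble: proposals toward
        # the planted model are downhill and must always be accepted
        ens = _single_atom_ensemble([[0.0], [0.5, 50.0], [1.0]])
        state = pm.PathState([0, 1, 0])
        for _ in range(50):
            out = pm.mc_step(ens, state, T=1e-6, rng=rng)
            if out.proposal == 0:  # downhill move
                assert out.accepted
                break

    def test_zero_temperature_limit_rejects_uphill(self, rng):
        ens = _single_atom_ensemble([[0.0], [0.5, 50.0], [1.0]])
        state = pm.PathState([0, 0, 0])
        for _ in range(200):
            out = pm.mc_step(ens, state, T=1e-9, rng=rng)
            if out.delta_e > 0:
                assert not out.accepted

    def test_pinned_endpoints_never_proposed(self, rng):
        ens = _single_atom_ensemble([[0.0], [1.0, 2.0], [1.5, 2.5], [3.0]])
        for _ in range(100):
            out = pm.mc_step(ens, pm.PathState([0, 0, 0, 0]), T=5.0, rng=rng)
            assert out.window in (1, 2)

    def test_uphill_acceptance_matches_metropolis(self):
        """Empirical uphill acceptance frequency equals exp(-dE/T) within
        3 standard errors over many proposals (binomial oracle)."""
        ens = fx.make_random_ensemble(6, 3, jitter=1.5, seed=21)
        costs = EdgeCosts.from_ensemble(ens)
        rng = np.random.default_rng(77)
        T = 0.05  # comparable to typical dE so acceptance is informative
        state = pm.PathState([0] + [0] * 4 + [0])
        n_uphill = 0
        n_accept = 0.0
        expected = 0.0
        var = 0.0
        for _ in range(100_000):
            out = pm.mc_step(costs, state, T, rng)
            if out.delta_e > 0:
                p = math.exp(-out.delta_e / T)
                n_uphill += 1
                expected += p
                var += p * (1.0 - p)
                n_accept += out.accepted
            state = out.state
        assert n_uphill > 1000
        z = (n_accept - expected) / math.sqrt(var)
        assert abs(z) < 3.0


class TestAnneal:
    def test_single_model_ensemble_returns_only_path(self):
        ens = _single_atom_ensemble([[0.0], [1.0], [2.5], [3.0]])
        res = pm.anneal(ens, seed=0)
        assert res.best_path.as_tuple() == (0, 0, 0, 0)
        assert np.isclose(res.energy, pm.path_energy(ens, [0, 0, 0, 0]))

    def test_planted_path_recovered(self):
        ens, truth = fx.make_planted_ensemble(8, 5, jitter=2.0, seed=5)
        res = pm.run_replicates(ens, base_seed=42)
        assert res.best_path.as_tuple() == truth.as_tuple()

    def test_energy_matches_recomputation(self):
        ens = fx.make_random_ensemble(7, 4, seed=9)
        res = pm.anneal(ens, seed=3)
        assert abs(res.energy - pm.path_energy(ens, res.best_path)) < 1e-10

    def test_running_minimum_of_trace_nonincreasing_and_bounded(self):
        ens = fx.make_random_ensemble(6, 3, seed=10)
        res = pm.anneal(ens, seed=4)
        running = np.minimum.accumulate(res.energy_trace)
        assert np.all(np.diff(running) <= 1e-12)
        assert res.energy <= running[-1] + 1e-10

    def test_seed_determinism(self):
        ens = fx.make_random_ensemble(6, 3, seed=11)
        a = pm.anneal(ens, seed=6)
        b = pm.anneal(ens, seed=6)
        assert a.best_path.as_tuple() == b.best_path.as_tuple()
        assert np.array_equal(a.energy_trace, b.energy_trace)

    def test_matches_exhaustive_on_random_instances(self):
        sched = pm.AnnealSchedule(s_max=2000)
        hits = 0
        for seed in range(10):
            ens = fx.make_random_ensemble(6, 3, seed=100 + seed)
            costs = EdgeCosts.from_ensemble(ens)
            _, best = pm.exhaustive_search(costs)
            res = pm.run_replicates(costs, sched, n_replicates=6, base_seed=seed)
            hits += np.isclose(res.energy, best, atol=1e-9)
        assert hits >= 9


class TestReplicates:
    def test_single_replicate_identical_to_anneal(self):
        ens = fx.make_random_ensemble(5, 3, seed=12)
        reps = pm.run_replicates(ens, n_replicates=1, base_seed=5)
        solo = pm.anneal(ens, seed=5)
        assert reps.best.best_path.as_tuple() == solo.best_path.as_tuple()
        assert reps.energy == solo.energy

    def test_best_not_worse_than_any_replicate(self):
        ens = fx.make_random_ensemble(6, 3, seed=13)
        reps = pm.run_replicates(ens, n_replicates=4, base_seed=0)
        assert all(reps.energy <= r.energy for r in reps.replicates)

    def test_default_replicate_count_is_12(self):
        ens = fx.make_random_ensemble(4, 2, seed=14)
        sched = pm.AnnealSchedule(s_max=50)
        reps = pm.run_replicates(ens, sched)
        assert len(reps.replicates) == 12


class TestExactOracles:
    def test_exhaustive_enumerates_all_interior_paths(self):
        pos = [[0.0], [1.0, 9.0], [2.0, 7.0], [3.0]]
        ens = _single_atom_ensemble(pos)
        state, energy = pm.exhaustive_search(ens)
        # brute force by hand over the 4 interior combinations
        best = min(
            (math.sqrt((abs(pos[1][i]) ** 2 + (pos[2][j] - pos[1][i]) ** 2
                        + (3.0 - pos[2][j]) ** 2) / 3.0), (0, i, j, 0))
            for i in range(2) for j in range(2))
        assert np.isclose(energy, best[0])
        assert state.as_tuple() == best[1]

    def test_guard_refuses_huge_spaces(self):
        ens = fx.make_random_ensemble(12, 5, seed=15)
        costs = EdgeCosts.from_ensemble(ens)
        costs.sizes = [1] + [1000] * 10 + [1]  # simulate a huge space
        with pytest.raises(ValueError, match="search space"):
            pm.exhaustive_search(costs)

    @pytest.mark.parametrize("seed", range(5))
    def test_dp_agrees_with_enumeration(self, seed):
        ens = fx.make_random_ensemble(8, 5, jitter=1.0, seed=200 + seed)
        costs = EdgeCosts.from_ensemble(ens)
        p_enum, e_enum = pm.exhaustive_search(costs)
        p_dp, e_dp = pm.dp_search(costs)
        assert np.isclose(e_enum, e_dp, atol=1e-10)
        assert np.isclose(costs.energy(p_dp.p), e_dp, atol=1e-10)

    def test_dp_unpinned_ensemble(self):
        ens = fx.make_random_ensemble(5, 3, seed=16)
        free = pm.ModelEnsemble([list(w) for w in ens.windows][1:-1], 3,
                                pinned_endpoints=False)
        p_enum, e_enum = pm.exhaustive_search(free)
        p_dp, e_dp = pm.dp_search(free)
        assert np.isclose(e_enum, e_dp, atol=1e-10)
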