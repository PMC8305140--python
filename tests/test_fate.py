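"""Fate rules: Wnt/Notch thresholds, specification mapping, cycling, lifecycle."""

import numpy as np
import pytest
from scipy import stats

from cryptsim import fate as F
from cryptsim.fate import (
    EC, FIB, GC, PC, PSEUDO_GC, SC,
    CellPopulation, FateParams,
    contact_inhibited, cycle_step, divide, lifecycle_update, notch_active,
    specify, wnt_active,
)

V0 = 4.0 / 3.0 * np.pi * 3.5 ** 3


def population(lineages, positions=None):
    pop = CellPopulation()
    n = len(lineages)
    pos = positions if positions is not None else np.zeros((n, 3))
    for i, lin in enumerate(lineages):
        pop.add(pos[i], lin, V0)
    return pop


def chain_pairs(n):
    """Contact graph of a linear chain 0-1-2-...-(n-1)."""
    return np.array([[i, i + 1] for i in range(n - 1)], dtype=int)


@pytest.fixture
def params():
    return FateParams()


class TestWntActivity:
    def test_external_region_while_on(self, params):
        pop = population([SC])
        active = wnt_active(pop, np.empty((0, 2), int), params,
                            external_on=True, in_region=np.array([True]))
        assert active[0]

    def test_external_region_after_switch_off(self, params):
        pop = population([SC])
        active = wnt_active(pop, np.empty((0, 2), int), params,
                            external_on=False, in_region=np.array([True]))
        assert not active[0]

    def test_pc_neighbour_threshold_inclusive(self, params):
        # exactly N_W Paneth neighbours activates Wnt
        pop = population([SC] + [PC] * params.N_W)
        pairs = np.array([[0, j] for j in range(1, params.N_W + 1)])
        active = wnt_active(pop, pairs, params, external_on=False,
                            in_region=np.zeros(pop.n, bool))
        assert active[0]

    def test_no_pc_neighbours_inactive(self, params):
        pop = population([SC, EC, GC])
        active = wnt_active(pop, chain_pairs(3), params, external_on=False,
                            in_region=np.zeros(3, bool))
        assert not active[0]

    def test_fibroblasts_never_wnt_active(self, params):
        pop = population([FIB, PC])
        active = wnt_active(pop, np.array([[0, 1]]), params,
                            external_on=True, in_region=np.ones(2, bool))
        assert not active[0]


class TestNotchActivity:
    def test_threshold_met(self, params):
        pop = population([SC] + [GC] * params.N_N)
        pairs = np.array([[0, j] for j in range(1, params.N_N + 1)])
        assert notch_active(pop, pairs, params)[0]

    def test_one_below_threshold(self, params):
        pop = population([SC] + [PC] * (params.N_N - 1)) \
            if params.N_N > 1 else population([SC])
        pairs = (np.array([[0, j] for j in range(1, params.N_N)])
                 if params.N_N > 1 else np.empty((0, 2), int))
        assert not notch_active(pop, pairs, params)[0]

    def test_enterocytes_not_secretory(self, params):
        pop = population([SC, EC, EC, EC])
        pairs = np.array([[0, 1], [0, 2], [0, 3]])
        assert not notch_active(pop, pairs, params)[0]

    def test_all_secretory_types_count(self, params):
        for sec in (PC, GC, PSEUDO_GC):
            pop = population([SC] + [sec] * params.N_N)
            pairs = np.array([[0, j] for j in range(1, params.N_N + 1)])
            assert notch_active(pop, pairs, params)[0]


class TestSpecify:
    def run_specify(self, lineage, wnt, notch, curv, params, rng=None):
        pop = population([lineage])
        rng = rng or np.random.default_rng(0)
        specify(pop, np.array([wnt]), np.array([notch]),
                np.array([curv]), params, rng)
        return pop

    def test_high_high_keeps_stem(self, params):
        pop = self.run_specify(SC, True, True, 0.0, params)
        assert pop.lineage[0] == SC

    def test_curvature_gate_selects_paneth(self, params):
        pop = self.run_specify(SC, True, False, params.C_0, params)
        assert pop.lineage[0] == PC
        assert np.isfinite(pop.pc_death_time[0])

    def test_low_curvature_gives_pseudo_goblet(self, params):
        pop = self.run_specify(SC, True, False, params.C_0 / 2, params)
        assert pop.lineage[0] == PSEUDO_GC

    def test_nan_curvature_below_gate(self, params):
        pop = self.run_specify(SC, True, False, np.nan, params)
        assert pop.lineage[0] == PSEUDO_GC

    def test_low_wnt_high_notch_gives_enterocyte(self, params):
        pop = self.run_specify(SC, False, True, 0.0, params)
        assert pop.lineage[0] == EC

    def test_low_low_gives_goblet(self, params):
        pop = self.run_specify(SC, False, False, 0.0, params)
        assert pop.lineage[0] == GC

    def test_ec_progenitor_reverts_to_stem(self, params):
        pop = self.run_specify(SC, False, True, 0.0, params)
        assert pop.lineage[0] == EC and not pop.terminal[0]
        specify(pop, np.array([True]), np.array([True]),
                np.array([0.0]), params, np.random.default_rng(0))
        assert pop.lineage[0] == SC

    def test_terminal_cells_never_respecify(self, params):
        pop = population([EC])
        pop.terminal[0] = True
        specify(pop, np.array([True]), np.array([True]), np.array([0.0]),
                params, np.random.default_rng(0))
        assert pop.lineage[0] == EC

    def test_fibroblasts_never_specify(self, params):
        pop = population([FIB])
        specify(pop, np.array([False]), np.array([False]), np.array([0.0]),
                params, np.random.default_rng(0))
        assert pop.lineage[0] == FIB

    def test_pseudo_goblet_converts_to_paneth_when_curvature_rises(
            self, params):
        pop = self.run_specify(SC, True, False, 0.0, params)
        assert pop.lineage[0] == PSEUDO_GC
        specify(pop, np.array([True]), np.array([False]),
                np.array([2 * params.C_0]), params,
                np.random.default_rng(0))
        assert pop.lineage[0] == PC

    def test_committed_paneth_does_not_revert(self, params):
        pop = self.run_specify(SC, True, False, params.C_0, params)
        assert pop.lineage[0] == PC and pop.last_cycle[0]
        specify(pop, np.array([True]), np.array([True]),
                np.array([0.0]), params, np.random.default_rng(0))
        assert pop.lineage[0] == PC

    def test_specification_log_replay(self, params):
        """Replaying the logged (wnt, notch, curvature) inputs through the
        mapping reproduces the logged lineage transitions exactly."""
        rng = np.random.default_rng(21)
        pop = population([SC] * 30)
        log = []
        for step in range(40):
            wnt = rng.random(pop.n) < 0.6
            notch = rng.random(pop.n) < 0.6
            curv = rng.uniform(-0.1, 0.15, pop.n)
            specify(pop, wnt, notch, curv, params, rng, log=log,
                    time=float(step))
        for (_, _, event, detail, wnt, notch, curv) in log:
            assert event == "specify"
            src, dst = detail.split("->")
            if not wnt and notch:
                assert dst == "EC"
            elif not wnt:
                assert dst == "GC"
            elif notch:
                assert dst == "SC"
            elif curv >= params.C_0:
                assert dst == "PC"
            else:
                assert dst == "pseudoGC"


class TestContactInhibition:
    def test_uncompressed_not_inhibited(self, params):
        pop = population([SC])
        pop.VA[0] = pop.V0[0]
        assert not contact_inhibited(pop, params)[0]

    def test_boundary_value_still_proliferates(self, params):
        pop = population([SC])
        pop.VA[0] = pop.V0[0] * (1 - params.dV_frac)
        assert not contact_inhibited(pop, params)[0]

    def test_below_threshold_inhibited(self, params):
        pop = population([SC])
        pop.VA[0] = pop.V0[0] * (1 - params.dV_frac) - 1e-9
        assert contact_inhibited(pop, params)[0]

    def test_release_restarts_cycling(self, params):
        pop = population([SC])
        pop.VA[0] = 0.5 * pop.V0[0]
        assert contact_inhibited(pop, params)[0]
        pop.VA[0] = pop.V0[0]
        assert not contact_inhibited(pop, params)[0]

    def test_monotone_in_tolerated_compression(self):
        """Raising dV_frac never reduces the number of cycling cells."""
        rng = np.random.default_rng(4)
        pop = population([SC] * 50)
        pop.VA = pop.V0 * rng.uniform(0.7, 1.0, 50)
        counts = []
        for dv in (0.05, 0.10, 0.15, 0.20, 0.25):
            p = FateParams(dV_frac=dv)
            counts.append(int(np.sum(~contact_inhibited(pop, p))))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestCycleAndDivision:
    def test_inhibited_cell_frozen(self, params):
        pop = population([SC])
        rng = np.random.default_rng(0)
        for _ in range(200):
            cycle_step(pop, np.array([True]), params, 0.5, rng)
        assert pop.growth_step[0] == 0

    def test_daughters_reset(self, params):
        pop = population([SC])
        pop.growth_step[0] = params.N_P - 1
        pop.VT[0] = 2 * V0 - V0 / params.N_P
        rng = np.random.default_rng(1)
        for _ in range(2000):
            idx = cycle_step(pop, np.zeros(pop.n, bool), params, 0.05, rng)
            if len(idx):
                break
        assert len(idx) == 1
        divide(pop, idx, np.array([[1.0, 0, 0]]))
        assert pop.n == 2
        np.testing.assert_allclose(pop.VT, V0)
        assert np.all(pop.growth_step == 0)
        assert np.all(pop.lineage == SC)
        # daughters placed +-0.4 R along the division axis, where R is
        # the mother's doubled-volume radius 3.5 * 2^(1/3)
        gap = np.linalg.norm(pop.pos[1] - pop.pos[0])
        assert gap == pytest.approx(0.8 * 3.5 * 2 ** (1 / 3), rel=1e-6)

    def test_cycle_time_is_erlang(self, params):
        """Uninhibited cycle time follows Erlang(N_P, N_P/tau): mean tau,
        CV = 1/sqrt(N_P); KS statistic below the 1% critical value."""
        rng = np.random.default_rng(11)
        n = 10_000
        dt = 0.005  # small vs the stage mean so discreteness is negligible
        p_step = params.N_P * dt / params.tau
        # simulate stage waiting times directly (geometric per stage)
        steps = rng.geometric(p_step, size=(n, params.N_P)).sum(axis=1)
        durations = steps * dt
        assert durations.mean() == pytest.approx(
            params.tau, abs=3 * durations.std() / np.sqrt(n))
        cv = durations.std() / durations.mean()
        assert cv == pytest.approx(1 / np.sqrt(params.N_P), rel=0.1)
        ks = stats.kstest(
            durations, stats.erlang(params.N_P,
                                    scale=params.tau / params.N_P).cdf)
        assert ks.statistic < 1.63 / np.sqrt(n)  # 1% critical value

    def test_population_division_flux(self, params):
        """A population of uninhibited SCs divides at rate ~N/tau."""
        pop = population([SC] * 200)
        rng = np.random.default_rng(3)
        pop.growth_step[:] = rng.integers(0, params.N_P, 200)
        pop.VT[:] = pop.V0 * (1 + pop.growth_step / params.N_P)
        dt = 0.1
        births = 0
        t = 0.0
        while t < 20.0:
            idx = cycle_step(pop, np.zeros(pop.n, bool), params, dt, rng)
            if len(idx):
                axes = np.tile([1.0, 0, 0], (len(idx), 1))
                divide(pop, idx, axes)
                births += len(idx)
            t += dt
        # 200 cells, 20 h, tau = 10 h: expect ~500 divisions (growing pop)
        assert births > 300


class TestLifecycle:
    def test_enterocyte_terminal_after_window(self, params):
        pop = population([EC])
        lifecycle_update(pop, params.t_prol, params)
        assert pop.terminal[0]

    def test_fibroblast_window_closes(self, params):
        pop = population([FIB])
        lifecycle_update(pop, params.t_prol, params)
        assert pop.terminal[0]
        assert not pop.proliferation_capable()[0]

    def test_paneth_death(self, params):
        pop = population([PC])
        pop.pc_death_time[0] = 5.0
        removed = lifecycle_update(pop, 6.0, params)
        assert len(removed["pc_death"]) == 1
        assert pop.n == 0

    def test_detached_cell_shrinks_and_dies(self, params):
        pop = population([EC])
        pop.shrinking[0] = True
        # V_T halves every 0.5 h; below 0.05 V_0 the cell is removed
        removed = lifecycle_update(pop, 0.5, params)
        assert pop.VT[0] == pytest.approx(V0 / 2)
        assert len(removed["detachment"]) == 0
        removed = lifecycle_update(pop, 2.0, params)
        assert len(removed["detachment"]) == 1

    def test_last_cycle_daughters_terminal(self, params):
        pop = population([SC])
        specify(pop, np.array([True]), np.array([False]),
                np.array([params.C_0]), params, np.random.default_rng(0))
        assert pop.lineage[0] == PC and pop.last_cycle[0]
        pop.growth_step[0] = params.N_P
        divide(pop, np.array([0]), np.array([[1.0, 0, 0]]))
        assert np.all(pop.terminal)
        assert not np.any(pop.proliferation_capable())


class TestBookkeeping:
    def test_ids_stable_across_removal(self):
        pop = population([SC, EC, GC, FIB])
        ids_before = pop.ids.copy()
        pop.remove(np.array([False, True, False, False]))
        assert list(pop.ids) == [ids_before[0], ids_before[2],
                                 ids_before[3]]

    def test_census_counts(self):
        pop = population([SC, SC, PC, GC, EC, FIB])
        c = pop.census()
        assert c == {"SC": 2, "PC": 1, "GC": 1, "pseudoGC": 0,
                     "EC": 1, "FIB": 1}

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FateParams(dV_frac=1.5)
        with pytest.raises(ValueError):
            FateParams(N_W=0)
        with pytest.raises(ValueError):
            FateParams(tau=-1.0)
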