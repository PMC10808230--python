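"""Unit and oracle tests of the overdamped filament dynamics."""

import numpy as np
import pytest

from nanocable.params import PRESETS, SimulationParams, get_preset
from nanocable.simulator import (Connectors, KIND_CROSSLINKER, KIND_MOTOR,
                                 _min_image, init_state, run_condition, step,
                                 turnover_filaments, update_connectors)


def small_params(**kw):
    base = dict(n_filaments=40, duration=1.0, seed=1, n_crosslinkers=50)
    base.update(kw)
    return SimulationParams(**base)


class TestInit:
    def test_construction_contract(self):
        st = init_state(small_params(n_filaments=100, seed=1))
        assert st.positions.shape == (100, 6, 2)
        assert np.all(st.positions >= 0) and np.all(st.positions < 3.0)
        assert len(st.connectors) == 0
        # consecutive bead distances at the rest spacing
        seg = _min_image(st.positions[:, 1:] - st.positions[:, :-1], 3.0)
        assert np.allclose(np.linalg.norm(seg, axis=-1), 0.05)

    def test_determinism_from_seed(self):
        a = init_state(small_params(seed=7))
        b = init_state(small_params(seed=7))
        assert np.array_equal(a.positions, b.positions)

    def test_empty_state_steps_are_noops(self):
        st = init_state(small_params(n_filaments=0))
        step(st)
        update_connectors(st)
        turnover_filaments(st)
        assert st.positions.shape[0] == 0

    def test_rejects_implausible_density(self):
        with pytest.raises(ValueError, match="density"):
            init_state(small_params(n_filaments=100000))


class TestStep:
    def test_straight_filament_is_in_equilibrium(self):
        st = init_state(small_params(n_filaments=1, temperature_noise=0.0))
        before = st.positions.copy()
        for _ in range(50):
            step(st)
        assert np.allclose(st.positions, before, atol=1e-12)

    def test_anisotropic_drag_scales_displacement_componentwise(self):
        """Equal force components along x and y move a bead 10x less along y
        when gamma_y = 10 * gamma_x."""
        p = small_params(n_filaments=1, beads_per_filament=2,
                         temperature_noise=0.0, gamma_y=10.0, k_bend=0.0)
        st = init_state(p)
        # stretch the bond along the (1,1) diagonal beyond rest length
        st.positions[0, 0] = [1.0, 1.0]
        st.positions[0, 1] = [1.0 + 0.1, 1.0 + 0.1]
        before = st.positions.copy()
        step(st)
        d = st.positions - before
        assert d[0, 0, 0] > 0  # pulled toward the other bead
        assert np.isclose(d[0, 0, 1], d[0, 0, 0] / 10.0)

    def test_bending_energy_decreases_monotonically(self):
        """Independent energy oracle: E = (k/2) sum |r_{i-1}-2r_i+r_{i+1}|^2
        computed from positions must fall at every noise-free step."""
        p = small_params(n_filaments=1, beads_per_filament=3,
                         temperature_noise=0.0, k_stretch=0.0)
        st = init_state(p)
        st.positions[0] = np.array([[1.0, 1.0], [1.05, 1.02], [1.10, 1.0]])

        def bend_energy(pos):
            lap = pos[0, :-2] - 2 * pos[0, 1:-1] + pos[0, 2:]
            return 0.5 * p.k_bend * np.sum(lap ** 2)

        energies = [bend_energy(st.positions)]
        for _ in range(200):
            step(st)
            energies.append(bend_energy(st.positions))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-15)
        assert energies[-1] < energies[0] * 0.5

    def test_center_of_mass_conserved_without_connectors_or_noise(self):
        p = small_params(n_filaments=3, temperature_noise=0.0)
        st = init_state(p)
        # place the perturbed filament well away from the periodic seam so
        # wrapped coordinates coincide with physical ones
        offsets = (np.arange(p.beads_per_filament) - 2.5) * p.bead_spacing
        st.positions[0] = np.stack([1.5 + offsets, np.full(6, 1.5)], axis=1)
        st.positions[0, 2] += 0.01   # perturb so forces are nonzero
        com = st.positions.mean(axis=1).copy()
        for _ in range(100):
            step(st)
        assert np.allclose(st.positions.mean(axis=1), com, atol=1e-9)

    def test_instability_guard_raises(self):
        p = small_params(n_filaments=1, beads_per_filament=2,
                         temperature_noise=0.0, k_stretch=1e6)
        st = init_state(p)
        st.positions[0, 1] = st.positions[0, 0] + [0.1, 0.0]
        with pytest.raises(RuntimeError, match="unstable"):
            step(st)


def _preplaced_connectors(n, kind=KIND_CROSSLINKER):
    return Connectors(np.full(n, kind, np.int8),
                      np.zeros(n, np.int32), np.ones(n, np.int32),
                      np.full(n, 0.1), np.full(n, 0.1), np.zeros(n))


class TestConnectors:
    def test_zero_bind_rate_leaves_connectors_unchanged(self):
        p = small_params(bind_rate=0.0, unbind_rate_crosslinker=0.0)
        st = init_state(p)
        st.connectors = _preplaced_connectors(10)
        update_connectors(st)
        assert len(st.connectors) == 10

    def test_infinite_unbind_rate_releases_all(self):
        p = small_params(bind_rate=0.0, unbind_rate_crosslinker=1e9)
        st = init_state(p)
        st.connectors = _preplaced_connectors(10)
        update_connectors(st)
        assert len(st.connectors) == 0

    def test_mean_bound_lifetime_matches_exponential(self):
        """Monte-Carlo check of the unbinding process: with rate r the mean
        lifetime over many events approaches 1/r."""
        rate = 2.0
        n_cohort = 20000
        p = small_params(bind_rate=0.0, unbind_rate_crosslinker=rate,
                         n_crosslinkers=0, temperature_noise=0.0, seed=11)
        st = init_state(p)
        st.connectors = _preplaced_connectors(n_cohort)
        dt = 0.01
        total_life = 0.0
        # follow the whole cohort to extinction so lifetimes are uncensored
        while len(st.connectors):
            before = st.connectors.age.copy()
            update_connectors(st, dt)
            released = len(before) - len(st.connectors)
            if released:
                total_life += (before.sum() - st.connectors.age.sum()
                               + released * dt / 2)
            st.connectors.age += dt
        assert np.isclose(total_life / n_cohort, 1.0 / rate, rtol=0.05)

    def test_binding_is_within_capture_radius_and_across_filaments(self):
        p = small_params(n_filaments=30, bind_rate=100.0,
                         unbind_rate_crosslinker=0.0, seed=3)
        st = init_state(p)
        update_connectors(st, dt=0.5)
        con = st.connectors
        assert len(con) > 0
        assert np.all(con.fil_a != con.fil_b)
        for k in range(len(con)):
            ia = int(round(con.s_a[k] / p.bead_spacing))
            ib = int(round(con.s_b[k] / p.bead_spacing))
            d = _min_image(st.positions[con.fil_a[k], ia]
                           - st.positions[con.fil_b[k], ib], p.box_size)
            assert np.linalg.norm(d) <= p.capture_radius + 1e-9


class TestTurnover:
    def test_zero_rate_is_identity(self):
        st = init_state(small_params(filament_turnover_rate=0.0))
        before = st.positions.copy()
        turnover_filaments(st, dt=10.0)
        assert np.array_equal(st.positions, before)

    def test_filament_count_conserved(self):
        st = init_state(small_params(filament_turnover_rate=5.0))
        turnover_filaments(st, dt=1.0)
        assert st.positions.shape[0] == 40

    def test_survival_curve_is_exponential(self):
        """Fraction of original filaments surviving to T approximates
        exp(-rate * T) (Monte-Carlo over filaments and repeats)."""
        rate, T = 0.5, 2.0
        survived = total = 0
        for seed in range(30):
            p = small_params(n_filaments=200, filament_turnover_rate=rate,
                             temperature_noise=0.0, bind_rate=0.0, seed=seed)
            st = init_state(p)
            original = st.positions.copy()
            for _ in range(20):
                turnover_filaments(st, dt=T / 20)
            survived += int(np.sum(np.all(st.positions == original,
                                          axis=(1, 2))))
            total += 200
        assert np.isclose(survived / total, np.exp(-rate * T), atol=0.02)

    def test_released_connectors_of_renewed_filaments(self):
        p = small_params(filament_turnover_rate=1e9, bind_rate=0.0)
        st = init_state(p)
        st.connectors = _preplaced_connectors(5)
        turnover_filaments(st, dt=1.0)
        assert len(st.connectors) == 0


class TestPresetsAndRun:
    def test_grid_has_exactly_twelve_conditions(self):
        assert len(PRESETS) == 12
        assert {p.crosslinker_level for p in PRESETS.values()} == {"L", "M", "H"}
        p4m = get_preset("4-M").params()
        assert p4m.n_motors > 0 and p4m.gamma_y > p4m.gamma_x
        p1l = get_preset("1-L").params()
        assert p1l.n_motors == 0 and p1l.gamma_y == p1l.gamma_x
        assert p1l.n_crosslinkers < p4m.n_crosslinkers

    def test_run_condition_snapshots_and_determinism(self):
        traj1 = run_condition(get_preset("1-L"),
                              {"duration": 2.0, "seed": 5, "n_filaments": 60})
        traj2 = run_condition(get_preset("1-L"),
                              {"duration": 2.0, "seed": 5, "n_filaments": 60})
        assert len(traj1) == 3      # t = 0, 1, 2 s at the default stride
        assert np.array_equal(traj1.positions[-1], traj2.positions[-1])
        assert np.all(traj1.positions[-1] >= 0)
        assert np.all(traj1.positions[-1] < traj1.params.box_size)
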