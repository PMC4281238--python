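"""Alarm-pheromone lattice model: rules, conservation, determinism."""

import math

import numpy as np
import pytest

from antescape.ensemble import summarise_runs
from antescape.pheromone import (
    AntState,
    LatticeConfig,
    PheromoneWorld,
    bracket,
    check_escape,
    deposit,
    evaporate,
    init_world,
    move,
    run_escape,
    run_many,
    sense_gradient,
    step,
    tau_to_kappa,
    _run_kernel,
    _seed_kernel,
)


def make_world(config=None, ants=(), field=None):
    config = config or LatticeConfig()
    n = max(len(ants), 1)
    world = init_world(config, n, np.random.default_rng(0))
    if ants:
        world.pos = np.array([a.pos for a in ants], dtype=np.int64)
        world.vel = np.array([a.vel for a in ants], dtype=np.int64)
        world.active = np.ones(len(ants), dtype=bool)
    if field is not None:
        world.field = np.asarray(field, dtype=float)
    else:
        world.field = np.zeros((config.L, config.L))
    return world


class TestTauKappa:
    def test_step_duration_arithmetic(self):
        # 0.4 cm per locus at 0.94 cm/s -> about 0.4255 s per step;
        # tau = 60 s then gives kappa within 1% of 0.00709.
        assert tau_to_kappa(60.0) == pytest.approx(0.00709, rel=0.01)

    def test_one_step_fadeout_limit(self):
        dt = (8.0 / 20) / 0.94
        assert tau_to_kappa(dt, threshold_T=1.0) == pytest.approx(1.0)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            tau_to_kappa(0.0)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L": 2},
            {"deposit_eta": 0.0},
            {"deposit_eta": 1.5},  # above threshold
            {"evap_kappa": 2.0},
            {"threshold_T": -1.0},
            {"exit_width_loci": 0},
            {"max_steps": 0},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            LatticeConfig(**kwargs)

    def test_exit_rows_centred(self):
        rows = LatticeConfig().exit_rows
        assert list(rows) == [8, 9, 10]

    def test_from_tau(self):
        cfg = LatticeConfig.from_tau(6.0, deposit_eta=0.1)
        assert cfg.evap_kappa == pytest.approx(tau_to_kappa(6.0))
        assert cfg.deposit_eta == 0.1


class TestInitWorld:
    def test_deterministic_given_seed(self):
        a = init_world(LatticeConfig(), 7, np.random.default_rng(42))
        b = init_world(LatticeConfig(), 7, np.random.default_rng(42))
        assert np.array_equal(a.pos, b.pos) and np.array_equal(a.vel, b.vel)

    def test_empty_field_and_bounds(self, rng):
        w = init_world(LatticeConfig(), 400, rng)
        assert w.field.sum() == 0.0
        assert w.pos.min() >= 0 and w.pos.max() <= 19
        assert np.all(np.abs(w.vel).max(axis=1) == 1)

    def test_needs_an_ant(self, rng):
        with pytest.raises(ValueError):
            init_world(LatticeConfig(), 0, rng)


class TestFieldDynamics:
    def test_deposit_single_ant(self):
        w = make_world(ants=[AntState((5, 5), (1, 0))])
        deposit(w, 0.5)
        assert w.field[5, 5] == 0.5
        assert w.field.sum() == 0.5

    def test_colocated_ants_add(self):
        w = make_world(ants=[AntState((5, 5), (1, 0)), AntState((5, 5), (0, 1))])
        deposit(w, 0.25)
        assert w.field[5, 5] == 0.5

    def test_evaporation_clamps_at_zero(self):
        w = make_world()
        w.field[3, 3] = 0.003
        evaporate(w, 0.0071)
        assert w.field[3, 3] == 0.0
        assert (w.field >= 0).all()

    def test_deposit_evaporate_cancel(self):
        w = make_world(ants=[AntState((5, 5), (1, 0))])
        deposit(w, 0.25)
        evaporate(w, 0.25)
        assert w.field.sum() == 0.0


class TestSenseGradient:
    def test_unique_maximum_below_threshold(self, rng):
        w = make_world(ants=[AntState((5, 5), (1, 0))])
        w.field[6, 6] = 0.4  # NE neighbour
        assert sense_gradient(w, w.ant(0), rng=rng) == (1, 1)

    def test_saturated_values_tie(self, rng):
        # 6 and 1 both clip to T=1: either side should be picked.
        w = make_world(ants=[AntState((5, 5), (1, 0))])
        w.field[6, 5] = 6.0
        w.field[4, 5] = 1.0
        picks = {sense_gradient(w, w.ant(0), rng=rng) for _ in range(200)}
        assert picks == {(1, 0), (-1, 0)}

    def test_zero_field_gives_uniform_steer(self, rng):
        w = make_world(ants=[AntState((5, 5), (1, 0))])
        picks = {sense_gradient(w, w.ant(0), rng=rng) for _ in range(500)}
        assert len(picks) == 8  # all Moore directions occur

    def test_own_locus_not_sensed(self, rng):
        w = make_world(ants=[AntState((5, 5), (1, 0))])
        w.field[5, 5] = 0.9  # own standing deposit
        w.field[6, 5] = 0.1
        assert sense_gradient(w, w.ant(0), rng=rng) == (1, 0)

    def test_off_lattice_neighbours_excluded(self, rng):
        w = make_world(ants=[AntState((0, 0), (1, 0))])
        w.field[1, 0] = 0.2
        assert sense_gradient(w, w.ant(0), rng=rng) == (1, 0)


class TestBracket:
    @pytest.mark.parametrize("x,expected", [(0, 0), (1.7, 1), (-0.2, -1), (2, 1)])
    def test_sign_quantiser(self, x, expected):
        assert bracket(x) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bracket(float("nan"))


class TestMove:
    def test_persistence_without_gradient(self):
        w = make_world()
        ant = move(w, AntState((5, 5), (1, 0)), None)
        assert ant.pos == (6, 5) and ant.vel == (1, 0)

    def test_turn_toward_gradient(self):
        w = make_world()
        ant = move(w, AntState((5, 5), (1, 0)), (0, 1))
        assert ant.vel == (1, 1) and ant.pos == (6, 6)

    def test_opposing_gradient_reorients_randomly(self, rng):
        w = make_world()
        seen = set()
        for _ in range(200):
            ant = move(w, AntState((5, 5), (1, 0)), (-1, 0), rng=rng)
            assert ant.vel != (0, 0)
            assert max(abs(ant.pos[0] - 5), abs(ant.pos[1] - 5)) == 1
            seen.add(ant.vel)
        assert len(seen) == 8

    def test_reflection_at_wall(self):
        w = make_world()
        L = w.config.L
        ant = move(w, AntState((L - 1, 5), (1, 0)), None)
        assert ant.pos == (L - 2, 5) and ant.vel == (-1, 0)

    def test_corner_reflection(self):
        w = make_world()
        ant = move(w, AntState((0, 0), (-1, -1)), None)
        assert ant.pos == (1, 1) and ant.vel == (1, 1)


class TestCheckEscape:
    def test_adjacent_to_left_exit(self):
        w = make_world(ants=[AntState((1, 9), (1, 0))])
        assert check_escape(w, w.ant(0)) == "left"

    def test_adjacent_to_right_exit(self):
        w = make_world(ants=[AntState((18, 10), (1, 0))])
        assert check_escape(w, w.ant(0)) == "right"

    def test_centre_is_safe(self):
        w = make_world(ants=[AntState((10, 10), (1, 0))])
        assert check_escape(w, w.ant(0)) is None

    def test_edge_but_outside_exit_rows(self):
        w = make_world(ants=[AntState((0, 2), (1, 0))])
        assert check_escape(w, w.ant(0)) is None


class TestStep:
    def test_zero_active_ants(self, rng):
        w = make_world(ants=[AntState((5, 5), (1, 0))])
        w.active[:] = False
        w.field[3, 3] = 0.5
        step(w, rng)
        assert w.step_count == 1
        assert w.field[3, 3] == pytest.approx(0.5 - w.config.evap_kappa)

    def test_population_conserved(self, rng):
        cfg = LatticeConfig()
        w = init_world(cfg, 50, rng)
        for _ in range(100):
            step(w, rng)
        assert w.n_active + w.escaped_left + w.escaped_right == 50
        assert (w.field >= 0).all()

    def test_deterministic_trajectory(self):
        worlds = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            w = init_world(LatticeConfig(), 10, rng)
            for _ in range(50):
                step(w, rng)
            worlds.append(w)
        assert np.array_equal(worlds[0].pos, worlds[1].pos)
        assert np.array_equal(worlds[0].field, worlds[1].field)
        assert worlds[0].escaped_left == worlds[1].escaped_left

    def test_kernel_matches_reference_step(self):
        # Tie-free staircase field far from the exits: both the interpreted
        # step() and the compiled whole-run kernel are deterministic there and
        # must produce the same trajectory.
        cfg = LatticeConfig(max_steps=3)
        field = np.zeros((20, 20))
        for x in range(3, 9):
            field[x, 10] = 0.05 + 0.1 * (x - 3)  # unique values, below T
        w_ref = make_world(cfg, ants=[AntState((5, 9), (0, -1))], field=field.copy())
        rng = np.random.default_rng(3)
        for _ in range(3):
            step(w_ref, rng)
        w_k = make_world(cfg, ants=[AntState((5, 9), (0, -1))], field=field.copy())
        _seed_kernel(123)
        rows = cfg.exit_rows
        _run_kernel(
            w_k.field, w_k.pos, w_k.vel, w_k.active, cfg.L,
            cfg.deposit_eta, cfg.evap_kappa, cfg.threshold_T,
            rows.start, rows.stop - 1, cfg.max_steps,
        )
        assert np.array_equal(w_ref.pos, w_k.pos)
        assert np.array_equal(w_ref.vel, w_k.vel)
        assert np.allclose(w_ref.field, w_k.field)


class TestRunEscape:
    def test_single_ant_trivial_asymmetry(self):
        r = run_escape(LatticeConfig(), 1, rng=4)
        assert r.n_escaped == 1
        assert not r.truncated

    def test_deterministic_given_seed(self):
        a = run_escape(LatticeConfig(), 20, rng=11)
        b = run_escape(LatticeConfig(), 20, rng=11)
        assert a == b

    def test_degenerate_field_is_fair(self, rng):
        # Deposit wiped by evaporation in the same step: the field stays zero
        # at sensing time, ants are independent symmetric walkers, and the
        # mean collective asymmetry is statistically zero.
        cfg = LatticeConfig(deposit_eta=0.25, evap_kappa=0.25, max_steps=5000)
        df = run_many(cfg, 10, 300, rng)
        s = summarise_runs(df)
        assert s.runs_used > 250
        assert abs(s.mean_delta_c) < 3 * s.se

    def test_run_many_schema_and_determinism(self):
        df1 = run_many(LatticeConfig(), 5, 4, rng=2)
        df2 = run_many(LatticeConfig(), 5, 4, rng=2)
        assert list(df1.columns) == [
            "run_id", "n_requested", "n_escaped", "n_left", "n_right", "steps", "truncated",
        ]
        assert df1.equals(df2)
        assert (df1.n_escaped <= 5).all()
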