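from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from runtumble.engine import (SimulationConfig, initialize_population,
                              run_simulation, run_two_ligand_grid, step_cell)
from runtumble.fields import ConstantFieldSpec, ExponentialFieldSpec
from runtumble.motor import MotorSpec


def small_config(**kwargs):
    defaults = dict(n_cells=12, n_steps=50, record_stride=10, master_seed=3,
                    field=ExponentialFieldSpec(l0=0.1, d=1.0))
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestInitialization:
    def test_population_size_and_domain(self):
        pop = initialize_population(small_config(n_cells=30))
        assert pop.n == 30
        assert np.all((pop.x >= -2) & (pop.x <= 2))
        assert np.all((pop.y >= -2) & (pop.y <= 2))
        assert len({(xx, yy) for xx, yy in zip(pop.x, pop.y)}) == 30

    def test_same_seed_identical_population(self):
        a = initialize_population(small_config())
        b = initialize_population(small_config())
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.z, b.z)

    def test_beta_round_robin_allocation(self):
        betas = (0.25, 0.5, 1, 2, 4, 6, 8, 10)
        pop = initialize_population(small_config(n_cells=16,
                                                 beta_values=betas))
        counts = pd.Series(pop.betas).value_counts()
        assert set(counts.index) == set(betas)
        assert np.all(counts.values == 2)

    def test_paired_init_shares_positions_across_betas(self):
        pop = initialize_population(small_config(
            n_cells=8, beta_values=(1.0, 4.0), paired_init=True))
        assert np.array_equal(pop.x[::2], pop.x[1::2])
        assert not np.array_equal(pop.z[::2], pop.z[1::2])  # cascades differ

    def test_cells_preadapted_to_local_concentration(self):
        pop = initialize_population(small_config(n_cells=5))
        # pre-adapted anywhere: CheY-P equals the unstimulated reference
        assert np.allclose(pop.z[:, 3], pop.yp_star, rtol=1e-6)

    def test_reference_is_background_steady_state(self, default_cascade,
                                                  background,
                                                  background_steady_state):
        pop = initialize_population(small_config(n_cells=3))
        assert np.allclose(pop.yp_star, background_steady_state.Yp, rtol=1e-9)


class TestStepCell:
    def test_bias_forced_to_zero_runs_straight(self):
        cfg = small_config(motor=MotorSpec(prefactor=1e30))
        pop = initialize_population(cfg)
        cell = pop.as_cell_states()[0]
        theta0 = cell.theta
        for _ in range(10):
            cell = step_cell(cell, cfg)
        assert cell.theta == pytest.approx(theta0)

    def test_bias_forced_to_one_reorients_every_step(self):
        cfg = small_config(motor=MotorSpec(prefactor=1e-30))
        pop = initialize_population(cfg)
        cell = pop.as_cell_states()[0]
        thetas = set()
        for _ in range(10):
            cell = step_cell(cell, cfg)
            thetas.add(round(cell.theta, 12))
        assert len(thetas) == 10

    def test_displacement_per_step_is_speed_dt(self):
        cfg = small_config()
        pop = initialize_population(cfg)
        cell = pop.as_cell_states()[0]
        before = cell.position
        cell = step_cell(cell, cfg)
        disp = np.hypot(cell.position[0] - before[0],
                        cell.position[1] - before[1])
        assert disp == pytest.approx(cfg.kinematics.speed * cfg.dt, rel=1e-9)


class TestRunSimulation:
    def test_zero_steps_returns_initial_state(self):
        res = run_simulation(small_config(n_steps=0))
        assert sorted(res.trajectories["step"].unique()) == [0]

    def test_bitwise_reproducibility(self):
        r1 = run_simulation(small_config(n_steps=100))
        r2 = run_simulation(small_config(n_steps=100))
        pd.testing.assert_frame_equal(r1.trajectories, r2.trajectories)

    def test_cells_confined_to_domain(self):
        res = run_simulation(small_config(n_steps=300))
        t = res.trajectories
        assert t["x"].abs().max() <= 2.0
        assert t["y"].abs().max() <= 2.0

    def test_record_stride_and_final_step_recorded(self):
        res = run_simulation(small_config(n_steps=55, record_stride=25))
        assert sorted(res.trajectories["step"].unique()) == [0, 25, 50, 55]

    def test_uniform_field_holds_steady_state_and_background_bias(self):
        cfg = small_config(n_cells=40, n_steps=400,
                           field=ConstantFieldSpec(level=0.1),
                           record_stride=40)
        res = run_simulation(cfg)
        t = res.trajectories
        last = t[t["step"] == 400]
        # closed loop: CheY-P pinned at the unstimulated steady state
        assert np.allclose(last["Yp"], 4.043, rtol=1e-3)
        assert np.allclose(last["bias"], 1 / 4.7, rtol=1e-2)
        # tumble frequency across the whole run matches the resting bias
        moved = t[t["step"] > 0]
        frac = (moved["state"] == "tumble").mean()
        n = len(moved)
        sigma = np.sqrt((1 / 4.7) * (1 - 1 / 4.7) / n)
        assert abs(frac - 1 / 4.7) < 4 * sigma

    def test_uniform_field_no_net_drift(self):
        cfg = small_config(n_cells=60, n_steps=600,
                           field=ConstantFieldSpec(level=0.1),
                           record_stride=600)
        res = run_simulation(cfg)
        t = res.trajectories
        d = t[t["step"] == 600].merge(t[t["step"] == 0], on="cell",
                                      suffixes=("_f", "_i"))
        dx = (d["x_f"] - d["x_i"]).mean()
        dy = (d["y_f"] - d["y_i"]).mean()
        rms = np.sqrt(((d["x_f"] - d["x_i"]) ** 2 +
                       (d["y_f"] - d["y_i"]) ** 2).mean() / len(d))
        assert abs(dx) < 3 * rms and abs(dy) < 3 * rms

    def test_single_cell_loop_matches_population_loop(self):
        cfg = small_config(n_cells=3, n_steps=20, record_stride=1)
        res = run_simulation(cfg)
        pop = initialize_population(cfg)
        cell = pop.as_cell_states()[1]
        for _ in range(20):
            cell = step_cell(cell, cfg)
        row = res.trajectories.query("step == 20 and cell == 1").iloc[0]
        assert row["x"] == pytest.approx(cell.position[0], rel=1e-9)
        assert row["theta"] == pytest.approx(cell.theta, rel=1e-9)
        assert row["Yp"] == pytest.approx(cell.cascade.Yp, rel=1e-9)


class TestExperimentDrivers:
    def test_two_ligand_grid_empty_upsilons(self):
        table = run_two_ligand_grid(small_config(n_steps=5),
                                    omega_values=(1.0,), upsilon_values=())
        assert len(table) == 0

    def test_two_ligand_grid_counts_partition(self):
        table = run_two_ligand_grid(small_config(n_cells=10, n_steps=20),
                                    omega_values=(1.0,),
                                    upsilon_values=(1e-3,))
        row = table.iloc[0]
        assert row["n_meAsp"] + row["n_serine"] + row["n_boundary"] == 10
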