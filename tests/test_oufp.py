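"""Fokker-Planck engine: click input, propagation against OU closed forms,
non-decision time, joint distributions, and the trial likelihood."""

import numpy as np
import pytest

from clickchange.params import ModelParams, ParameterError, SolverConfig, TaskConfig
from clickchange.oufp import (
    DVGrid,
    build_grid,
    click_drive,
    fp_step,
    initial_mass,
    run_trial,
    apply_ndt,
    joint_rt,
    single_rt,
    trial_loglik,
    dataset_loglik,
)
from clickchange.task import generate_trial


def _point_state(params, solver, at=0.0):
    grid = build_grid(params, solver)
    return DVGrid(values=grid, mass=initial_mass(grid, at))


class TestClickDrive:
    def test_without_depression_each_click_counts_once(self):
        p = ModelParams(bound_up=80.0)
        clicks = np.array([0.001, 0.005, 0.03, 0.5])
        counts, drive = click_drive(clicks, 1.0, p)
        assert counts.sum() == pytest.approx(4.0)
        assert counts[0] == 2.0 and counts[1] == 1.0
        np.testing.assert_allclose(drive, counts / 0.02)

    def test_depression_relaxation_closed_form(self):
        # two clicks 10 ms apart: the second carries 1 - 0.55 e^{-1/2}
        p = ModelParams(bound_up=80.0, depression_enabled=True,
                        dep_scale=0.45, dep_tau=0.02)
        counts, _ = click_drive(np.array([0.001, 0.011]), 0.1, p)
        expected_second = 1.0 - 0.55 * np.exp(-0.5)
        assert counts[0] == pytest.approx(1.0 + expected_second, abs=1e-9)

    def test_widely_spaced_clicks_fully_recover(self):
        p = ModelParams(bound_up=80.0, depression_enabled=True)
        clicks = np.arange(10) * (10 * p.dep_tau)
        from clickchange.oufp import _depressed_magnitudes

        mags = _depressed_magnitudes(clicks, p.dep_scale, p.dep_tau)
        assert mags[0] == 1.0
        assert np.all(mags[1:] >= 0.999)

    def test_unsorted_clicks_rejected(self):
        with pytest.raises(ValueError):
            click_drive(np.array([0.5, 0.1]), 1.0, ModelParams(bound_up=80.0))


class TestFPStep:
    def test_fixed_point_without_noise_or_drive(self):
        p = ModelParams(tau=0.4, bound_up=80.0, sigma_process=0.0)
        solver = SolverConfig()
        state = _point_state(p, solver)
        for _ in range(50):
            state = fp_step(state, 0.0, solver.dt, p, bounds_active=False)
        h = state.spacing
        assert abs(state.mean()) < h
        assert state.total() == pytest.approx(1.0, abs=1e-9)

    def test_mean_follows_ou_closed_form(self):
        p = ModelParams(tau=0.4, bound_up=80.0, sigma_process=0.0)
        solver = SolverConfig()
        state = _point_state(p, solver)
        t = 0.0
        for _ in range(60):
            state = fp_step(state, 60.0, solver.dt, p, bounds_active=False)
            t += solver.dt
            expected = 60.0 * (1.0 - np.exp(-t / p.tau))
            assert abs(state.mean() - expected) < state.spacing

    def test_stationary_variance_matches_ou(self):
        p = ModelParams(tau=0.4, bound_up=84.0, sigma_process=20.0)
        solver = SolverConfig()
        state = _point_state(p, solver)
        for _ in range(200):  # 4 s >> tau: stationary
            state = fp_step(state, 60.0, solver.dt, p, bounds_active=False)
        expected = p.sigma_process**2 * p.tau / 2.0
        assert state.var() == pytest.approx(expected, rel=0.02)
        assert state.total() == pytest.approx(1.0, abs=1e-6)

    def test_sticky_bound_absorbs_and_keeps_mass(self):
        p = ModelParams(tau=0.4, bound_up=66.0, sigma_process=10.0)
        solver = SolverConfig(n_grid=301)
        state = _point_state(p, solver, at=60.0)
        absorbed = [0.0]
        for _ in range(100):
            state = fp_step(state, 60.0, solver.dt, p, bounds_active=True)
            absorbed.append(state.absorbed_up)
        diffs = np.diff(absorbed)
        assert np.all(diffs >= -1e-12)       # absorbed mass never returns
        assert absorbed[-1] > 0.2            # bound close to the mean: crossings happen
        assert state.total() == pytest.approx(1.0, abs=1e-6)


class TestRunTrial:
    @pytest.fixture(scope="class")
    def trial(self):
        return generate_trial(TaskConfig(), np.random.default_rng(11), 0)

    def test_unreachable_bounds_survive_everything(self, trial):
        p = ModelParams(tau=0.4, bound_up=1e6, sigma_process=4.0)
        res = run_trial(trial.clicks, trial.max_time, p, "increase_only")
        assert res.survival_end == pytest.approx(1.0, abs=1e-9)

    def test_total_probability_partitions(self, trial):
        p = ModelParams(tau=0.4, bound_up=78.3, sigma_process=4.0)
        res = run_trial(trial.clicks, trial.max_time, p, "increase_only")
        total = res.cross_up.sum() + res.survival_end
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_raising_the_bound_cannot_increase_crossing(self, trial):
        crossings = []
        for b in (78.3, 90.0, 120.0):
            p = ModelParams(tau=0.4, bound_up=b, sigma_process=4.0)
            res = run_trial(trial.clicks, trial.max_time, p, "increase_only")
            crossings.append(res.cross_up.sum())
        assert crossings[0] >= crossings[1] >= crossings[2]

    def test_inverted_bounds_rejected(self, trial):
        p = ModelParams(tau=0.4, sigma_process=4.0)
        p.bound_up = 30.0
        p.bound_down = 50.0
        with pytest.raises(ParameterError):
            run_trial(trial.clicks, trial.max_time, p, "both")

    def test_substep_refinement_changes_loglik_little(self, trial):
        # halving the propagation step moves any trial log-likelihood < 0.05
        p = ModelParams(tau=0.4, bound_up=78.3, sigma_process=4.0)
        lls = []
        for nsub in (1, 2):
            res = run_trial(
                trial.clicks, trial.max_time, p, "increase_only",
                SolverConfig(n_substeps=nsub),
            )
            rt = single_rt(res.cross_up, res.survival_end, p, "up")
            lls.append(trial_loglik(rt, "miss", None, None,
                                    max_time=trial.max_time))
        assert abs(lls[0] - lls[1]) < 0.05


class TestNDT:
    def test_mass_conserved(self):
        cross = np.zeros(100)
        cross[[30, 40, 55]] = [0.2, 0.1, 0.05]
        p = ModelParams(bound_up=80.0, ndt_mean=0.35, ndt_sd=0.06)
        dens = apply_ndt(cross, p)
        assert dens.sum() == pytest.approx(cross.sum(), abs=1e-9)

    def test_mean_shift_equals_ndt_mean(self):
        cross = np.zeros(200)
        cross[50:60] = 0.08
        p = ModelParams(bound_up=80.0, ndt_mean=0.3, ndt_sd=0.05)
        dens = apply_ndt(cross, p)
        dt = 0.02
        t_in = (np.arange(cross.size) + 0.5) * dt
        t_out = (np.arange(dens.size) + 0.5) * dt
        m_in = (t_in * cross).sum() / cross.sum()
        m_out = (t_out * dens).sum() / dens.sum()
        assert m_out - m_in == pytest.approx(p.ndt_mean, abs=1e-3)

    def test_narrow_ndt_reduces_to_pure_shift(self):
        cross = np.zeros(100)
        cross[40] = 1.0
        p = ModelParams(bound_up=80.0, ndt_mean=0.2, ndt_sd=1e-4)
        dens = apply_ndt(cross, p)
        assert np.argmax(dens) == 40 + round(0.2 / 0.02)


class TestJointRT:
    @pytest.fixture(scope="class")
    def runs(self):
        trial = generate_trial(TaskConfig(), np.random.default_rng(13), 0)
        p_up = ModelParams(tau=0.4, bound_up=78.3, sigma_process=4.0)
        p_dn = ModelParams(tau=0.15, bound_down=28.0, sigma_process=4.0)
        up = run_trial(trial.clicks, trial.max_time, p_up, "increase_only")
        dn = run_trial(trial.clicks, trial.max_time, p_dn, "decrease_only")
        return trial, p_up, up, dn

    def test_reduces_to_single_process_when_other_unreachable(self, runs):
        trial, p_up, up, _ = runs
        dead = run_trial(
            trial.clicks, trial.max_time,
            ModelParams(tau=0.15, bound_down=-1e6, sigma_process=4.0),
            "decrease_only",
        )
        joint = joint_rt(up.cross_up, up.survival, dead.cross_down,
                         dead.survival, p_up)
        single = single_rt(up.cross_up, up.survival_end, p_up, "up")
        np.testing.assert_allclose(joint.density_up, single.density_up, atol=1e-12)
        assert joint.miss_mass == pytest.approx(single.miss_mass, abs=1e-12)

    def test_total_probability_is_one(self, runs):
        trial, p_up, up, dn = runs
        joint = joint_rt(up.cross_up, up.survival, dn.cross_down, dn.survival, p_up)
        assert joint.total() == pytest.approx(1.0, abs=1e-4)

    def test_grid_mismatch_rejected(self, runs):
        _, p_up, up, dn = runs
        with pytest.raises(ValueError):
            joint_rt(up.cross_up[:-5], up.survival[:-5], dn.cross_down,
                     dn.survival, p_up)


class TestTrialLoglik:
    @pytest.fixture(scope="class")
    def rtdist(self):
        trial = generate_trial(TaskConfig(), np.random.default_rng(17), 0)
        p = ModelParams(tau=0.4, bound_up=78.3, sigma_process=4.0)
        res = run_trial(trial.clicks, trial.max_time, p, "increase_only")
        return trial, single_rt(res.cross_up, res.survival_end, p, "up")

    def test_unreachable_bound_makes_miss_certain(self):
        trial = generate_trial(TaskConfig(), np.random.default_rng(19), 0)
        p = ModelParams(tau=0.4, bound_up=1e6, sigma_process=4.0)
        res = run_trial(trial.clicks, trial.max_time, p, "increase_only")
        rt = single_rt(res.cross_up, res.survival_end, p, "up")
        ll = trial_loglik(rt, "miss", None, None, max_time=trial.max_time)
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_window_sum_matches_quadrature(self, rtdist):
        trial, rt = rtdist
        t_resp = 2.0
        ll = trial_loglik(rt, "false_alarm", t_resp, "increase")
        # independent quadrature: direct summation over the same window
        sel = np.abs(rt.t - t_resp) <= 0.1 + 1e-9
        expected = np.log(max(rt.density_up[sel].sum(), 1e-10))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_zero_density_region_hits_floor(self, rtdist):
        trial, rt = rtdist
        ll = trial_loglik(rt, "false_alarm", 0.1, "increase")
        assert ll == pytest.approx(np.log(1e-10))

    def test_excluded_outcomes_rejected(self, rtdist):
        _, rt = rtdist
        with pytest.raises(ValueError):
            trial_loglik(rt, "early_excluded", 0.5, "increase")


class TestDatasetLoglik:
    def test_additivity_on_duplicated_data(self, dataset_small):
        trials, clicks = dataset_small
        params = {
            "informed_increase": ModelParams(tau=0.4, bound_up=78.3, sigma_process=4.0),
            "informed_decrease": ModelParams(tau=0.15, bound_down=28.0, sigma_process=4.0),
            "uninformed": (
                ModelParams(tau=0.4, bound_up=83.9, sigma_process=4.0),
                ModelParams(tau=0.15, bound_down=24.0, sigma_process=4.0),
            ),
        }
        sub = trials.head(60)
        subset = (sub, clicks)
        ll1 = dataset_loglik(subset, params)
        dup = sub.copy()
        dup["trial_id"] = dup["trial_id"] + 1_000_000
        clicks2 = dict(clicks)
        clicks2.update({tid: clicks[tid - 1_000_000] for tid in dup["trial_id"]})
        import pandas as pd

        both = (pd.concat([sub, dup], ignore_index=True), clicks2)
        ll2 = dataset_loglik(both, params)
        assert ll2 == pytest.approx(2 * ll1, abs=1e-6)

    def test_unmapped_condition_rejected(self, dataset_small):
        with pytest.raises(ValueError):
            dataset_loglik(
                dataset_small,
                {"informed_increase": ModelParams(tau=0.4, bound_up=78.3)},
            )

    def test_joint_model_requires_shared_ndt(self, dataset_small):
        params = {
            "informed_increase": ModelParams(tau=0.4, bound_up=78.3),
            "informed_decrease": ModelParams(tau=0.15, bound_down=28.0),
            "uninformed": (
                ModelParams(tau=0.4, bound_up=83.9, ndt_mean=0.3),
                ModelParams(tau=0.15, bound_down=24.0, ndt_mean=0.4),
            ),
        }
        with pytest.raises(ParameterError):
            dataset_loglik(dataset_small, params)
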