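"""Initialization scans, the adaptive update rule, losses, and the baseline."""

import numpy as np
import pytest

from hopffit import (
    DegenerateInputError,
    FitConfig,
    FitTrajectory,
    ModelParameters,
    WeightedConnectome,
    actual_loss,
    adaptive_fit,
    approximate_loss,
    compute_falff,
    compute_power_ratio,
    fcd,
    group_coupling,
    normalize,
    scan_global_coupling,
    scan_homogeneous_a,
    simulate,
    traditional_fit,
)
from hopffit.connectome import generate_ws_network, normalize_strength
from hopffit.synth import sample_omega


def _toy_trajectory(ks, conv, corr, a_by_iter=None):
    ks = np.asarray(ks, float)
    n_it = ks.size
    if a_by_iter is None:
        a_by_iter = np.zeros((n_it, 3))
    return FitTrajectory(
        a_by_iter=np.asarray(a_by_iter, float),
        ks_by_iter=ks,
        conv_by_iter=np.asarray(conv, float),
        corr_by_iter=np.asarray(corr, float),
        seed_schedule=np.zeros((n_it, 1), dtype=int),
    )


@pytest.fixture(scope="module")
def small_system():
    """A 30-region system with data generated at known G and homogeneous a."""
    net = normalize_strength(generate_ws_network(30, 0.35, 0.35, seed=21), 0.6)
    omega = sample_omega(30, seed=22)
    template = ModelParameters(
        a=np.zeros(30), G=0.0, omega=omega, tr=2.0, duration=300.0, seed=0
    )
    return net, template


class TestInitializationScans:
    def test_singleton_grids_return_their_value(self, small_system):
        net, template = small_system
        emp = simulate(template.replace(a=np.zeros(30), G=0.8, seed=4), net)
        cfg = FitConfig(seed=4)
        g = scan_global_coupling(emp, net, [0.7], template, cfg)
        assert g.opt == 0.7
        a0 = scan_homogeneous_a(emp, net, 0.7, [0.02], template, cfg)
        assert a0.opt == 0.02

    def test_recovers_generating_coupling_from_critical_data(self, small_system):
        # data generated at the critical point with known G*: the KS-vs-G
        # curve should dip near G* and be U-shaped (interior minimum)
        net, template = small_system
        grid = np.round(np.arange(0.0, 2.01, 0.2), 10)
        hits, interior = 0, 0
        n_trials = 5
        for trial in range(n_trials):
            emp = simulate(template.replace(a=np.zeros(30), G=1.0, seed=100 + trial), net)
            res = scan_global_coupling(emp, net, grid, template, FitConfig(seed=trial))
            if abs(res.opt - 1.0) <= 0.2 + 1e-9:
                hits += 1
            if 0 < np.argmin(res.ks) < grid.size - 1:
                interior += 1
        assert hits >= 4
        assert interior >= 4

    def test_recovers_homogeneous_a_near_truth(self, small_system):
        net, template = small_system
        grid = np.round(np.arange(-0.05, 0.051, 0.01), 10)
        hits = 0
        n_trials = 10
        for trial in range(n_trials):
            emp = simulate(
                template.replace(a=np.full(30, 0.02), G=1.0, seed=200 + trial), net
            )
            res = scan_homogeneous_a(emp, net, 1.0, grid, template, FitConfig(seed=trial))
            if abs(res.opt - 0.02) <= 0.02 + 1e-9:
                hits += 1
        assert hits >= n_trials // 2

    def test_mdd_style_grid_accepted(self, small_system):
        net, template = small_system
        emp = simulate(template.replace(a=np.zeros(30), G=1.0, seed=9), net)
        grid = np.round(np.arange(-0.075, 0.051, 0.005), 10)
        res = scan_homogeneous_a(emp, net, 1.0, grid, template, FitConfig(seed=9))
        assert res.opt in grid


class TestAdaptiveFit:
    def test_update_rule_reproduces_trajectory(self, small_system):
        # recompute every gradient step independently from the recorded seeds
        net, template = small_system
        rng = np.random.default_rng(31)
        a_star = rng.uniform(-1.5, 1.5, 30)
        emp = simulate(template.replace(a=a_star, G=1.0, seed=11), net)
        cfg = FitConfig(max_iters=4, seed=11)
        traj = adaptive_fit(emp, net, 1.0, 0.0, cfg, template)

        f_emp = normalize(compute_falff(emp, cfg.band), cfg.normalization)
        emp_fcd = fcd(emp, cfg.window_length, cfg.stride, cfg.band)
        eta = cfg.learning_rate
        for t in range(cfg.max_iters - 1):
            ts = simulate(
                template.replace(a=traj.a_by_iter[t], G=1.0, seed=int(traj.seed_schedule[t, 0])),
                net,
            )
            f_sim = normalize(compute_falff(ts, cfg.band), cfg.normalization)
            sim_fcd = fcd(ts, cfg.window_length, cfg.stride, cfg.band)
            expected = traj.a_by_iter[t] + eta * (
                f_emp - f_sim + (emp_fcd.mean - sim_fcd.mean)
            )
            np.testing.assert_allclose(traj.a_by_iter[t + 1], expected, atol=1e-10)
            assert traj.conv_by_iter[t] == pytest.approx(np.max(np.abs(f_emp - f_sim)))

    def test_full_determinism(self, small_system):
        net, template = small_system
        emp = simulate(template.replace(a=np.full(30, 0.3), G=1.0, seed=13), net)
        cfg = FitConfig(max_iters=5, seed=13)
        t1 = adaptive_fit(emp, net, 1.0, 0.0, cfg, template)
        t2 = adaptive_fit(emp, net, 1.0, 0.0, cfg, template)
        np.testing.assert_array_equal(t1.a_by_iter, t2.a_by_iter)
        np.testing.assert_array_equal(t1.ks_by_iter, t2.ks_by_iter)
        assert t1.selected_iter == t2.selected_iter

    def test_first_iteration_starts_at_a0(self, small_system):
        net, template = small_system
        emp = simulate(template.replace(a=np.zeros(30), G=1.0, seed=14), net)
        traj = adaptive_fit(emp, net, 1.0, 0.04, FitConfig(max_iters=2, seed=14), template)
        np.testing.assert_allclose(traj.a_by_iter[0], 0.04)


class TestTraditionalFit:
    def test_huge_threshold_stops_immediately(self, small_system):
        net, template = small_system
        emp = simulate(template.replace(a=np.zeros(30), G=1.0, seed=15), net)
        cfg = FitConfig(max_iters=50, seed=15, threshold_r=10.0)
        traj = traditional_fit(emp, net, 1.0, cfg, template)
        assert traj.n_iters == 1
        assert traj.converged

    def test_unattainable_threshold_runs_out(self, small_system):
        net, template = small_system
        emp = simulate(template.replace(a=np.zeros(30), G=1.0, seed=16), net)
        cfg = FitConfig(max_iters=3, seed=16, threshold_r=1e-12)
        traj = traditional_fit(emp, net, 1.0, cfg, template)
        assert traj.n_iters == 3
        assert not traj.converged

    def test_update_follows_power_ratio_difference(self, small_system):
        net, template = small_system
        emp = simulate(template.replace(a=np.full(30, 0.5), G=1.0, seed=17), net)
        cfg = FitConfig(max_iters=2, seed=17, threshold_r=1e-12)
        traj = traditional_fit(emp, net, 1.0, cfg, template)
        p_emp = compute_power_ratio(emp, cfg.band)
        ts = simulate(
            template.replace(a=traj.a_by_iter[0], G=1.0, seed=int(traj.seed_schedule[0, 0])),
            net,
        )
        p_sim = compute_power_ratio(ts, cfg.band)
        expected = np.clip(
            traj.a_by_iter[0] + cfg.trad_learning_rate * (p_emp - p_sim), -6, 6
        )
        np.testing.assert_allclose(traj.a_by_iter[1], expected, atol=1e-10)


class TestLossFunctions:
    def test_dominant_iteration_selected(self):
        traj = _toy_trajectory(
            ks=[0.5, 0.1, 0.4], conv=[0.3, 0.05, 0.2], corr=[0.2, 0.9, 0.4]
        )
        loss = approximate_loss(traj)
        assert np.argmin(loss) == 1

    def test_permutation_equivariance(self):
        ks = np.array([0.5, 0.1, 0.4, 0.3])
        conv = np.array([0.3, 0.05, 0.2, 0.1])
        corr = np.array([0.2, 0.9, 0.4, 0.5])
        loss = approximate_loss(_toy_trajectory(ks, conv, corr))
        perm = [2, 0, 3, 1]
        loss_p = approximate_loss(_toy_trajectory(ks[perm], conv[perm], corr[perm]))
        np.testing.assert_allclose(loss[perm], loss_p, atol=1e-12)

    def test_higher_correlation_lowers_loss(self):
        # identical KS and convergence curves; only the final corr differs
        ks, conv = [0.4, 0.3, 0.2], [0.3, 0.2, 0.1]
        low = approximate_loss(_toy_trajectory(ks, conv, [0.1, 0.2, 0.3]))
        high = approximate_loss(_toy_trajectory(ks, conv, [0.1, 0.2, 0.9]))
        assert high[2] < low[2]

    def test_actual_loss_exact_iteration_wins_raw_components(self):
        a_star = np.array([1.0, -2.0, 0.5])
        a_by_iter = np.array([[0.0, 0.0, 0.0], [1.0, -2.0, 0.5], [2.0, -3.0, 1.0]])
        traj = _toy_trajectory([0.5, 0.1, 0.2], [0.3, 0.1, 0.2], [0.1, 0.9, 0.5], a_by_iter)
        loss = actual_loss(traj, a_star)
        assert np.argmin(loss) == 1

    def test_two_iteration_zscores_are_unit(self):
        # iteration 1 hits the truth exactly: both components z-score to -1
        a_star = np.array([1.0, 0.0, -1.0])
        a_by_iter = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, -1.0]])
        traj = _toy_trajectory([0.5, 0.2], [0.3, 0.1], [0.0, 0.5], a_by_iter)
        loss = actual_loss(traj, a_star)
        np.testing.assert_allclose(loss, [2.0, -2.0], atol=1e-12)

    def test_argmin_invariant_to_constant_shift(self):
        ks = np.array([0.4, 0.2, 0.3])
        conv = np.array([0.2, 0.1, 0.15])
        corr = np.array([0.5, 0.8, 0.6])
        l0 = approximate_loss(_toy_trajectory(ks, conv, corr))
        l1 = approximate_loss(_toy_trajectory(ks + 0.7, conv + 0.3, corr))
        assert np.argmin(l0) == np.argmin(l1)

    def test_constant_component_raises(self):
        traj = _toy_trajectory([0.3, 0.3], [0.1, 0.2], [0.5, 0.6])
        with pytest.raises(DegenerateInputError):
            approximate_loss(traj)

    def test_single_iteration_loss_is_zero(self):
        traj = _toy_trajectory([0.3], [0.1], [0.5])
        np.testing.assert_allclose(approximate_loss(traj), [0.0])


def test_group_coupling_is_mean():
    assert group_coupling([0.8, 1.2, 1.0]) == pytest.approx(1.0)
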