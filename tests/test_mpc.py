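import itertools

import numpy as np
import pytest

from vnsmpc.mpc import (ControllerConfig, DisturbanceState, cost_min_energy,
                        cost_min_overshoot, cost_sparsity, disturbance_update,
                        solve_offset_free, solve_receding_horizon)


@pytest.fixture
def cfg55():
    return ControllerConfig(variant="sparsity", Np=10, Nc=5, lam=1e-3)


class TestCosts:
    def test_perfect_tracking_zero_input_costs_nothing(self, cfg55):
        r = np.tile([380.0, 120.0], (10, 1))
        u = np.zeros((5, 6))
        assert cost_sparsity(r, u, r, cfg55) == pytest.approx(0.0, abs=1e-5)
        cfg = ControllerConfig(variant="min_energy", Np=10, Nc=5)
        assert cost_min_energy(r, u, r, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_l1_arithmetic(self, cfg55):
        # one input channel at 2 held over Nc=5 with lambda=0.001
        r = np.tile([380.0, 120.0], (10, 1))
        u = np.zeros((5, 6))
        u[:, 0] = 2.0
        assert cost_sparsity(r, u, r, cfg55) == pytest.approx(0.01, rel=1e-5)

    def test_l2_arithmetic(self):
        cfg = ControllerConfig(variant="min_energy", Np=10, Nc=5, lam=1e-3)
        r = np.tile([380.0, 120.0], (10, 1))
        u = np.zeros((5, 6))
        u[:, 0] = 2.0
        assert cost_min_energy(r, u, r, cfg) == pytest.approx(0.02, rel=1e-12)

    def test_overshoot_term_vanishes_at_previous_action(self):
        cfg = ControllerConfig(variant="min_overshoot", Np=10, Nc=5,
                               lam1=1e-3, lam2=5e-5)
        r = np.tile([380.0, 120.0], (10, 1))
        u_prev = np.array([0.1, 10, 0, 0, 0.2, 30.0])
        u = np.tile(u_prev, (5, 1))
        with_hold = cost_min_overshoot(r, u, r, u_prev, cfg)
        assert with_hold == pytest.approx(
            cfg.lam1 * 5 * np.abs(u_prev).sum(), rel=1e-4)

    def test_overshoot_from_rest_degenerates_to_scaled_sparsity(self):
        cfg = ControllerConfig(variant="min_overshoot", Np=10, Nc=5,
                               lam1=0.0, lam2=5e-5)
        r = np.tile([380.0, 120.0], (10, 1))
        c = np.array([0.2, 20, 0.1, 5, 0.0, 0.0])
        u = np.tile(c, (5, 1))
        val = cost_min_overshoot(r, u, r, np.zeros(6), cfg)
        assert val == pytest.approx(cfg.lam2 * 5 * np.abs(c).sum(), rel=1e-4)

    def test_dimension_mismatch_rejected(self, cfg55):
        r = np.tile([380.0, 120.0], (10, 1))
        with pytest.raises(ValueError):
            cost_sparsity(r, np.zeros((4, 6)), r, cfg55)
        with pytest.raises(ValueError):
            cost_sparsity(r[:8], np.zeros((5, 6)), r, cfg55)


class TestConfig:
    def test_decision_variable_counts(self):
        assert ControllerConfig(Nc=5, Np=10).n_decision == 30
        assert ControllerConfig(Nc=20, Np=20).n_decision == 120
        assert ControllerConfig(Nc=1, Np=10).n_decision == 6
        assert ControllerConfig(variant="offset_free", Nc=10,
                                Np=20).n_decision == 68

    def test_invalid_horizons_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(Nc=11, Np=10)
        with pytest.raises(ValueError):
            ControllerConfig(variant="bogus")


class TestRecedingHorizon:
    def test_reference_at_rest_needs_no_actuation(self, linear_model):
        cfg = ControllerConfig(variant="sparsity", Np=8, Nc=3, lam=1e-3)
        # y0 = 0 is a fixed point of the toy model under u = 0
        sol = solve_receding_horizon(linear_model, linear_model.init_state(1),
                                     np.zeros(2), np.zeros((8, 2)), cfg)
        assert np.abs(sol.u_seq).max() < 1e-3
        assert sol.cost < 1e-3

    def test_solution_respects_bounds(self, linear_model):
        cfg = ControllerConfig(variant="min_energy", Np=6, Nc=4, lam=1e-4)
        r = np.tile([0.9, 0.9], (6, 1))  # aggressive target
        sol = solve_receding_horizon(linear_model, linear_model.init_state(1),
                                     np.zeros(2), r, cfg)
        assert np.all(sol.u_seq >= cfg.u_min - 1e-9)
        assert np.all(sol.u_seq <= cfg.u_max + 1e-9)

    def test_huge_sparsity_weight_shuts_all_locations_off(self, linear_model):
        cfg = ControllerConfig(variant="sparsity", Np=6, Nc=3, lam=1e3)
        r = np.tile([0.5, 0.4], (6, 1))
        sol = solve_receding_horizon(linear_model, linear_model.init_state(1),
                                     np.zeros(2), r, cfg,
                                     warm_start=np.full((3, 6), 0.2))
        assert np.abs(sol.u_seq / cfg.u_max).max() < 1e-3

    def test_matches_exhaustive_grid_oracle(self, linear_model, unit_norm):
        # brute-force oracle: all 2^6 corner commands for Nc = 1
        rng = np.random.default_rng(8)
        cfg = ControllerConfig(variant="sparsity", Np=5, Nc=1, lam=1e-3,
                               tol=1e-9, max_iter=300)
        A, B = linear_model.A, linear_model.B
        span = unit_norm.span[2:]
        corners = np.array(list(itertools.product(*[(0.0, 1.0)] * 6)))
        for _ in range(20):
            y0 = rng.uniform(-0.5, 0.5, 2)
            r = rng.uniform(-0.6, 0.6, 2)
            rn = np.tile(r, (cfg.Np, 1))
            best = np.inf
            for c in corners:  # independent arithmetic rollout of the oracle
                u_raw = c * cfg.u_max
                y, cost = y0.copy(), 0.0
                for _ in range(cfg.Np):
                    y = A @ y + B @ (u_raw / span)
                    cost += float((r - y) @ (r - y))
                cost += cfg.lam * np.abs(c).sum()
                best = min(best, cost)
            sol = solve_receding_horizon(
                linear_model, linear_model.init_state(1), y0, rn, cfg)
            assert sol.cost <= best + 1e-4

    def test_offset_free_variant_routed_elsewhere(self, linear_model):
        cfg = ControllerConfig(variant="offset_free", Np=6, Nc=3)
        with pytest.raises(ValueError):
            solve_receding_horizon(linear_model, linear_model.init_state(1),
                                   np.zeros(2), np.zeros((6, 2)), cfg)


class TestDisturbance:
    def test_zero_innovation_keeps_estimate(self):
        ds = DisturbanceState(Ld=np.array([0.06, 0.05]))
        ds.y_aug_pred = np.array([0.2, 0.1])
        out = disturbance_update(ds, np.array([0.2, 0.1]))
        assert np.allclose(out.d, 0.0)

    def test_no_update_before_first_prediction(self):
        ds = DisturbanceState()
        out = disturbance_update(ds, np.array([0.3, 0.3]))
        assert np.allclose(out.d, 0.0)

    @pytest.mark.parametrize("ld", [0.05, 0.5, 1.5])
    def test_constant_offset_converges_geometrically(self, ld):
        # static model f = 0, plant output b: d must approach b with ratio
        # |1 - Ld| per step (closed form of the linear recursion)
        b = np.array([0.4, -0.3])
        ds = DisturbanceState(Ld=np.array([ld, ld]))
        errs = []
        for _ in range(30):
            ds.y_aug_pred = ds.d  # model prediction 0 + d
            ds = disturbance_update(ds, b)
            errs.append(np.abs(b - ds.d).max())
        ratio = errs[-1] / errs[-2]
        assert errs[-1] < 1e-2 or abs(ratio - abs(1 - ld)) < 1e-6
        assert errs[-1] < errs[0]

    def test_paper_gain_presets(self):
        from vnsmpc.closed_loop import scenario_preset
        intra = scenario_preset("offset_free_intra_patient")
        symp = scenario_preset("offset_free_sympathetic")
        assert np.allclose(intra.config.Ld, [0.06, 0.05])
        assert np.allclose(symp.config.Ld, [0.06, 0.018])


class TestOffsetFree:
    def test_steady_state_matches_linear_algebra(self, linear_model, unit_norm):
        # algebraic oracle: the optimized pair must satisfy the fixed-point
        # system y_s = A y_s + B u_s + d with y_s at the (reachable) target
        cfg = ControllerConfig(variant="offset_free", Np=8, Nc=4,
                               tol=1e-9, max_iter=300)
        ds = DisturbanceState(d=np.array([0.02, -0.01]))
        r = np.array([0.2, 0.1])
        sol = solve_offset_free(linear_model, linear_model.init_state(1),
                                np.zeros(2), r, ds, cfg)
        span = unit_norm.span[2:]
        y_s_n = sol.y_s  # toy norm is identity on outputs
        fp = (linear_model.A @ y_s_n + linear_model.B @ (sol.u_s / span)
              + ds.d) - y_s_n
        assert np.abs(fp).max() < 1e-5
        assert np.abs(y_s_n - r).max() < 5e-3
        assert np.all(sol.u_s >= -1e-9)

    def test_consistent_fixed_point_costs_nothing(self, linear_model):
        # r at the model's origin fixed point with d = 0: u_s = 0, cost ~ 0
        cfg = ControllerConfig(variant="offset_free", Np=6, Nc=3, tol=1e-9,
                               max_iter=200)
        sol = solve_offset_free(linear_model, linear_model.init_state(1),
                                np.zeros(2), np.zeros(2),
                                DisturbanceState(), cfg)
        assert sol.cost < 1e-6
        assert np.abs(sol.u_s).max() < 1e-3

    def test_bias_rejection_in_closed_loop(self, linear_model):
        # plant = surrogate + constant output bias; the offset-free loop
        # must reduce the tracking error well below the bias magnitude
        cfg = ControllerConfig(variant="offset_free", Np=8, Nc=4,
                               Ld=np.array([0.06, 0.05]), tol=1e-9,
                               max_iter=200)
        bias = np.array([0.03, -0.02])
        r = np.array([0.2, 0.1])
        ds = DisturbanceState(Ld=cfg.Ld)
        y = np.zeros(2)
        A, B = linear_model.A, linear_model.B
        span = linear_model.norm.span[2:]
        for k in range(100):
            ds = disturbance_update(ds, y)
            sol = solve_offset_free(linear_model, linear_model.init_state(1),
                                    y, r, ds, cfg)
            u = sol.first
            y_model = A @ y + B @ (u / span)
            ds.y_aug_pred = y_model + ds.d
            y = y_model + bias  # the "true" plant
        assert np.abs(y - r).max() < 0.05 * np.abs(bias).max()
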