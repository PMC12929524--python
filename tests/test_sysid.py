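"""System identification: estimators, l1 input recovery, alternating fit."""

import numpy as np
import pytest

import neuromodes as nm
from neuromodes.errors import (
    DegenerateDesignError,
    DomainError,
    SingularDataError,
)
from neuromodes.panels import TimeSeriesPanel
from neuromodes.sysid import _simulate, input_support


def _panel(data, dt=2.0):
    return TimeSeriesPanel(data=data, dt=dt)


class TestEstimateAOnestep:
    def test_identity_recovery_noise_free(self):
        # a repeated eigenvalue is unidentifiable from one trajectory (the
        # whole orbit is rank one), so pool runs with independent x0
        sys_ = nm.make_stable_system(3, [(0.5, 0.0, 3)], basis=np.eye(3))
        panels = [
            nm.simulate_run(sys_, 20, noise_sd=0.0, x0=x0)
            for x0 in np.eye(3) + 0.1
        ]
        A = nm.estimate_A_group(panels, objective="onestep")
        np.testing.assert_allclose(A, 0.5 * np.eye(3), atol=1e-12)

    def test_constant_zero_series_is_singular(self):
        with pytest.raises(SingularDataError):
            nm.estimate_A_onestep(_panel(np.zeros((3, 10))))

    def test_matches_bruteforce_normal_equations(self, rng):
        """Independent oracle: explicitly inverted normal equations."""
        for _ in range(5):
            n, T = rng.integers(2, 8), int(rng.integers(20, 50))
            X = rng.standard_normal((n, T + 1))
            panel = _panel(X)
            A = nm.estimate_A_onestep(panel)
            Xm, Xp = X[:, :-1], X[:, 1:]
            oracle = Xp @ Xm.T @ np.linalg.inv(Xm @ Xm.T)
            np.testing.assert_allclose(A, oracle, atol=1e-10)

    def test_recovers_generator_matrix(self, rng):
        from neuromodes.experiments import random_stable_spec

        sys_ = nm.make_stable_system(10, random_stable_spec(10, rng), seed=3)
        panel = nm.simulate_run(sys_, 500, noise_sd=0.0, x0=rng.standard_normal(10))
        assert np.linalg.norm(nm.estimate_A_onestep(panel) - sys_.A_true) < 1e-8


class TestEstimateAGroup:
    def test_single_panel_onestep_reduces(self, rng):
        X = rng.standard_normal((4, 30))
        panel = _panel(X)
        a = nm.estimate_A_group([panel], objective="onestep")
        b = nm.estimate_A_onestep(panel)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_duplication_invariance(self, rng):
        X = rng.standard_normal((4, 30))
        panel = _panel(X)
        one = nm.estimate_A_group([panel], objective="onestep")
        many = nm.estimate_A_group([panel] * 5, objective="onestep")
        np.testing.assert_allclose(one, many, atol=1e-10)

    def test_freerun_recovers_noise_free(self, rng):
        from neuromodes.experiments import random_stable_spec

        sys_ = nm.make_stable_system(6, random_stable_spec(6, rng), seed=5)
        panels = [
            nm.simulate_run(sys_, 80, noise_sd=0.0, x0=rng.standard_normal(6))
            for _ in range(2)
        ]
        A = nm.estimate_A_group(panels, objective="freerun")
        assert np.linalg.norm(A - sys_.A_true) < 1e-6

    def test_freerun_gradient_matches_finite_differences(self, rng):
        from neuromodes.sysid import _freerun_value_grad

        X = rng.standard_normal((3, 12)) * 0.5
        panel = _panel(X)
        A0 = 0.3 * rng.standard_normal(9)
        f0, g = _freerun_value_grad(A0, [panel], 3)
        eps = 1e-6
        for i in range(9):
            d = np.zeros(9)
            d[i] = eps
            fp, _ = _freerun_value_grad(A0 + d, [panel], 3)
            fm, _ = _freerun_value_grad(A0 - d, [panel], 3)
            assert abs((fp - fm) / (2 * eps) - g[i]) < 1e-4 * max(1.0, abs(g[i]))

    def test_noisy_recovery_improves_with_T(self, rng):
        """A-recovery error is monotone decreasing in run length
        (Monte-Carlo mean over replicates)."""
        from neuromodes.experiments import random_stable_spec

        sys_ = nm.make_stable_system(6, random_stable_spec(6, rng), seed=2)
        errs = []
        for T in (60, 240, 960):
            e = []
            for rep in range(20):
                panel = nm.simulate_run(sys_, T, noise_sd=0.1, seed=1000 + rep)
                e.append(np.linalg.norm(nm.estimate_A_onestep(panel) - sys_.A_true))
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]


class TestEstimateInputs:
    def test_huge_penalty_zeroes_inputs(self, small_system, driven_panel):
        panel, B, _ = driven_panel
        U, _ = nm.estimate_inputs(panel, small_system.A_true, B, reg_weight=1e8)
        np.testing.assert_array_equal(U, 0.0)

    def test_identity_B_unpenalised_interpolates(self, small_system):
        panel = nm.simulate_run(small_system, 25, noise_sd=0.2, seed=8)
        A = small_system.A_true
        U, z0 = nm.estimate_inputs(panel, A, np.eye(6), reg_weight=0.0)
        np.testing.assert_allclose(z0, panel.data[:, 0])
        np.testing.assert_allclose(
            U, panel.data[:, 1:] - A @ panel.data[:, :-1], atol=1e-8
        )
        Z = _simulate(A, np.eye(6), U, z0)
        np.testing.assert_allclose(Z, panel.data, atol=1e-8)

    def test_matches_reference_convex_solver(self, small_system, driven_panel):
        """Dual-route check: coordinate-descent lasso on the explicit
        stacked design must reach the same objective (1e-6 relative)."""
        from sklearn.linear_model import Lasso

        from neuromodes.sysid import _free_traj, _input_design

        panel, B, _ = driven_panel
        A = small_system.A_true
        lam = 0.5
        U_hat, z0 = nm.estimate_inputs(panel, A, B, reg_weight=lam)
        G = _input_design(A, B, panel.T)
        y = (panel.data - _free_traj(A, panel.data[:, 0], panel.T)).T.ravel()
        m = y.size
        ref = Lasso(alpha=lam / (2 * m), fit_intercept=False, tol=1e-12, max_iter=200000)
        ref.fit(G, y)

        def objective(u):
            r = y - G @ u
            return float(r @ r + lam * np.abs(u).sum())

        ours = objective(U_hat.T.ravel())
        theirs = objective(ref.coef_)
        assert ours <= theirs * (1 + 1e-6)

    def test_planted_support_recovered(self, small_system, driven_panel):
        panel, B, U_true = driven_panel
        U_hat, _ = nm.estimate_inputs(panel, small_system.A_true, B, reg_weight=0.5)
        est = input_support(U_hat)
        tru = U_true != 0
        tp = (est & tru).sum()
        f1 = 2 * tp / (2 * tp + (est & ~tru).sum() + (~est & tru).sum())
        assert f1 > 0.9

    def test_negative_penalty_rejected(self, small_system, driven_panel):
        panel, B, _ = driven_panel
        with pytest.raises(DomainError):
            nm.estimate_inputs(panel, small_system.A_true, B, reg_weight=-1.0)


class TestEstimateB:
    def test_unpenalised_recovery(self, small_system, rng):
        A = small_system.A_true
        B_true = rng.standard_normal((6, 2))
        U = [rng.standard_normal((2, 30)), rng.standard_normal((2, 25))]
        Z = [_simulate(A, B_true, u, rng.standard_normal(6)) for u in U]
        B = nm.estimate_B(Z, U, A, reg_weight=0.0)
        np.testing.assert_allclose(B, B_true, atol=1e-8)

    def test_huge_penalty_shrinks_to_zero(self, small_system, rng):
        A = small_system.A_true
        B_true = rng.standard_normal((6, 2))
        U = [rng.standard_normal((2, 30))]
        Z = [_simulate(A, B_true, U[0], np.zeros(6))]
        B = nm.estimate_B(Z, U, A, reg_weight=1e9)
        np.testing.assert_allclose(B, 0.0, atol=1e-8)

    def test_scale_ambiguity_and_gauge(self, small_system, rng):
        """Scaling U by c and B by 1/c leaves the data unchanged; the
        unit-column gauge restores comparability."""
        A = small_system.A_true
        B_true = rng.standard_normal((6, 2))
        U = [rng.standard_normal((2, 40))]
        Z = [_simulate(A, B_true, U[0], np.zeros(6))]
        B1 = nm.estimate_B(Z, U, A, reg_weight=0.0)
        B2 = nm.estimate_B(Z, [U[0] * 2.0], A, reg_weight=0.0)
        assert not np.allclose(B1, B2)
        np.testing.assert_allclose(
            B1 / np.linalg.norm(B1, axis=0),
            B2 / np.linalg.norm(B2, axis=0),
            atol=1e-8,
        )

    def test_zero_inputs_degenerate(self, small_system):
        A = small_system.A_true
        Z = [np.zeros((6, 10))]
        with pytest.raises(DegenerateDesignError):
            nm.estimate_B(Z, [np.zeros((2, 9))], A)


class TestFitUnknownInputs:
    def test_trace_monotone_and_selfconsistent(self, small_system, driven_panel):
        panel, _, _ = driven_panel
        res = nm.fit_unknown_inputs(
            [panel], small_system.A_true, p=2, reg_weight=0.5, max_iter=10, seed=0
        )
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 0)
        assert res.objective() == pytest.approx(trace[-1], rel=1e-9)
        # stored latent trajectories satisfy the constraint dynamics exactly
        for Z, U, z0 in zip(res.Z_by_subject, res.U_by_subject, res.z0_by_subject):
            np.testing.assert_allclose(
                Z, _simulate(res.model.A, res.model.B, U, z0), atol=1e-12
            )

    def test_zero_input_cohort_yields_tiny_inputs(self, small_system):
        rest = [
            nm.simulate_run(small_system, 40, noise_sd=0.02, seed=50 + i)
            for i in range(3)
        ]
        res_rest = nm.fit_unknown_inputs(
            rest, small_system.A_true, p=2, reg_weight=0.5, max_iter=8, seed=1
        )
        rng = np.random.default_rng(0)
        B = rng.standard_normal((6, 2))
        B /= np.linalg.norm(B, axis=0)
        task = [
            nm.simulate_run(
                small_system, 40,
                B_true=B, U=nm.make_sparse_inputs(2, 40, 0.1, 1.0, seed=60 + i),
                noise_sd=0.02, seed=70 + i,
            )
            for i in range(3)
        ]
        res_task = nm.fit_unknown_inputs(
            task, small_system.A_true, p=2, reg_weight=0.5, max_iter=8, seed=1
        )
        l1_rest = sum(np.abs(u).sum() for u in res_rest.U_by_subject)
        l1_task = sum(np.abs(u).sum() for u in res_task.U_by_subject)
        assert l1_rest < 0.05 * l1_task

    def test_normalized_gauge_preserves_dynamics(self, small_system, driven_panel):
        panel, _, _ = driven_panel
        res = nm.fit_unknown_inputs(
            [panel], small_system.A_true, p=2, reg_weight=0.5, max_iter=5, seed=0
        )
        norm = res.normalized()
        np.testing.assert_allclose(np.linalg.norm(norm.model.B, axis=0), 1.0)
        np.testing.assert_allclose(
            norm.model.B @ norm.U_by_subject[0],
            res.model.B @ res.U_by_subject[0],
            atol=1e-10,
        )


class TestResidualsAndInputDim:
    def test_noise_free_residuals_vanish(self, small_system):
        panels = [
            nm.simulate_run(small_system, 30, noise_sd=0.0, x0=np.ones(6) * (i + 1))
            for i in range(2)
        ]
        R = nm.onestep_residuals(panels, small_system.A_true)
        assert R.shape == (6, 60)
        np.testing.assert_allclose(R, 0.0, atol=1e-10)

    def test_planted_low_rank_structure_visible(self, small_system, rng):
        B = rng.standard_normal((6, 3))
        panels = [
            nm.simulate_run(
                small_system, 200,
                B_true=B, U=nm.make_sparse_inputs(3, 200, 0.2, 1.0, seed=i),
                noise_sd=1e-4, seed=10 + i,
            )
            for i in range(2)
        ]
        R = nm.onestep_residuals(panels, small_system.A_true)
        s = np.linalg.svd(R, compute_uv=False)
        assert s[2] > 100 * s[3]  # rank 3 above the noise floor

    def test_constructed_spectrum(self):
        # exactly 3 orthogonal directions of variance
        R = np.zeros((6, 9))
        R[0, :3] = 5.0
        R[1, 3:6] = 5.0
        R[2, 6:9] = 5.0
        assert nm.select_input_dim(R, 0.99) == 3

    def test_isotropic_spectrum_ceil(self, rng):
        from scipy.stats import ortho_group

        R = ortho_group.rvs(10, random_state=rng)
        assert nm.select_input_dim(R, 0.70) == 7

    def test_target_near_one_gives_rank(self, rng):
        R = rng.standard_normal((4, 2)) @ rng.standard_normal((2, 30))
        assert nm.select_input_dim(R, 1 - 1e-9) == 2

    def test_bad_target_rejected(self):
        with pytest.raises(DomainError):
            nm.select_input_dim(np.ones((3, 5)), 1.5)
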