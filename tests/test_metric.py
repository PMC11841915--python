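import numpy as np
import pytest

from gridci.geometry import hex_mesh, rotation_matrix, sample_uniform
from gridci.metric import (
    ConformalScale,
    ci_loss,
    ci_loss_and_grad,
    ci_loss_general,
    cis,
    conformal_scale_theory,
    ellipse_fit,
    fit_conformal_scale,
    metric_tensor,
    trajectory_lengths,
)
from gridci.model import GridModule, concatenate


class TestMetricTensor:
    def test_zero_at_single_cell_peak(self):
        mod = GridModule(np.zeros((1, 2)))
        f = metric_tensor(mod, np.zeros((1, 2)))
        assert np.allclose([f.Gxx, f.Gxy, f.Gyy], 0.0, atol=1e-20)

    def test_positive_semidefinite_everywhere(self, cell, rng):
        mod = GridModule(sample_uniform(9, cell, 5))
        f = metric_tensor(mod, rng.uniform(-1, 1, (200, 2)))
        evals = np.linalg.eigvalsh(f.as_matrices())
        assert evals.min() > -1e-10

    def test_spatial_mean_matches_theory(self, cell):
        # holds for any phase set: cross-wave terms integrate to zero
        mod = GridModule(sample_uniform(7, cell, 2))
        f = metric_tensor(mod, hex_mesh(128, cell))
        sigma = conformal_scale_theory(2.0 / 9.0, 7).sigma
        assert f.Gxx.mean() == pytest.approx(sigma, rel=1e-6)
        assert f.Gyy.mean() == pytest.approx(sigma, rel=1e-6)
        assert sigma == pytest.approx(28.0 * np.pi**2 / 27.0)

    def test_additivity_under_concatenation(self, cell, rng):
        a = GridModule(sample_uniform(3, cell, 1))
        b = GridModule(sample_uniform(4, cell, 2))
        pts = rng.uniform(-1, 1, (20, 2))
        fa, fb = metric_tensor(a, pts), metric_tensor(b, pts)
        fc = metric_tensor(concatenate([a, b]), pts)
        assert np.allclose(fc.Gxx, fa.Gxx + fb.Gxx, atol=1e-12)
        assert np.allclose(fc.Gxy, fa.Gxy + fb.Gxy, atol=1e-12)


class TestCILoss:
    def test_zero_for_converged_solution(self, ci7, cell):
        samples = sample_uniform(500, cell, 6)
        assert ci_loss(ci7.module, samples, ci7.sigma) < 1e-10

    def test_order_ten_for_random_phases(self, cell):
        mod = GridModule(sample_uniform(7, cell, 17))
        sigma = fit_conformal_scale(metric_tensor(mod, hex_mesh(32, cell))).sigma
        loss = ci_loss(mod, hex_mesh(32, cell), sigma)
        assert 1.0 < loss < 1e2

    def test_doubling_solution_keeps_zero_loss_at_doubled_scale(self, ci7, cell):
        double = concatenate([ci7.module, ci7.module.with_phases(ci7.phases + 0.123)])
        samples = sample_uniform(400, cell, 8)
        assert ci_loss(double, samples, 2.0 * ci7.sigma) < 1e-8

    def test_invalid_scale_rejected(self, ci7, cell):
        with pytest.raises(ValueError):
            ci_loss(ci7.module, np.zeros((1, 2)), -1.0)

    def test_gradients_match_finite_differences(self, cell):
        mod = GridModule(sample_uniform(5, cell, 4))
        samples = sample_uniform(64, cell, 5)
        sigma = conformal_scale_theory(2.0 / 9.0, 5).sigma
        loss, dph, dsig = ci_loss_and_grad(mod, samples, sigma)
        eps = 1e-6
        for i in range(5):
            for a in range(2):
                pp, pm = mod.phases.copy(), mod.phases.copy()
                pp[i, a] += eps
                pm[i, a] -= eps
                fd = (
                    ci_loss(GridModule(pp), samples, sigma)
                    - ci_loss(GridModule(pm), samples, sigma)
                ) / (2 * eps)
                assert fd == pytest.approx(dph[i, a], rel=1e-4, abs=1e-6)
        fd_sig = (
            ci_loss(mod, samples, sigma + eps) - ci_loss(mod, samples, sigma - eps)
        ) / (2 * eps)
        assert fd_sig == pytest.approx(dsig, rel=1e-6)


class TestGeneralLoss:
    def test_reduces_to_ci_loss_for_isotropic_target(self, cell):
        mod = GridModule(sample_uniform(6, cell, 3))
        samples = sample_uniform(100, cell, 1)
        sigma = 5.0
        assert ci_loss_general(mod, samples, sigma * np.eye(2)) == pytest.approx(
            ci_loss(mod, samples, sigma)
        )

    def test_non_spd_target_rejected(self, cell):
        mod = GridModule(sample_uniform(3, cell, 3))
        with pytest.raises(ValueError):
            ci_loss_general(mod, np.zeros((1, 2)), np.diag([1.0, -1.0]))

    def test_anisotropic_target_trains_to_eccentric_pattern(self, cell):
        # learning an isometry of diag(sigma, c*sigma) requires deforming the
        # pattern itself: phases alone give an isotropic mean metric, so the
        # fit trains a linear deformation jointly with the phases and the
        # iso-rate contour becomes eccentric relative to the flat-metric case
        from gridci.optimise import GridPhaseModel

        sigma = conformal_scale_theory(2.0 / 9.0, 7).sigma

        def eccentricity(target):
            m = GridPhaseModel(7, "ci", target_metric=target, train_deformation=True)
            res = m.fit(steps=1500, seed=0)
            th = np.linspace(0, 2 * np.pi, 72, endpoint=False)
            from scipy.optimize import brentq
            from gridci.model import activity

            pts = []
            for t in th:
                u = np.array([np.cos(t), np.sin(t)])
                fun = lambda r: activity(
                    res.module, res.phases[0] + r * u[None, :]
                )[0, 0] - 0.8
                # upper bracket stays below half a lattice period so the
                # level is crossed exactly once
                pts.append(res.phases[0] + brentq(fun, 1e-4, 0.35) * u)
            return ellipse_fit(np.array(pts)).eccentricity, res

        flat, _ = eccentricity(
            lambda p: np.broadcast_to(sigma * np.eye(2), (len(p), 2, 2))
        )
        distorted, res = eccentricity(
            lambda p: np.broadcast_to(np.diag([sigma, 2.0 * sigma]), (len(p), 2, 2))
        )
        assert distorted > flat + 0.2
        # the fitted deformation stretches the y wave components by ~sqrt(2)
        sv = np.linalg.svd(res.deformation, compute_uv=False)
        assert sv.max() / sv.min() == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_distorted_training_improves_loss(self, cell):
        from gridci.optimise import GridPhaseModel

        sigma = conformal_scale_theory(2.0 / 9.0, 7).sigma
        target = lambda p: np.broadcast_to(np.diag([sigma, 1.5 * sigma]), (len(p), 2, 2))
        m = GridPhaseModel(7, "ci", target_metric=target)
        res = m.fit(steps=800, seed=1)
        head = res.loss_history[:50].mean()
        tail = res.loss_history[-50:].mean()
        assert tail < head


class TestCIS:
    def test_zero_for_constant_diagonal_field(self, ci7, cell):
        f = metric_tensor(ci7.module, hex_mesh(32, cell))
        assert cis(f) < 1e-10
        # and the components really are sigma * I everywhere
        assert np.abs(f.Gxx - ci7.sigma).max() < 1e-4 * ci7.sigma
        assert np.abs(f.Gxy).max() < 1e-4 * ci7.sigma

    def test_optimised_far_below_random(self, ci7, cell):
        mesh = hex_mesh(32, cell)
        for seed in range(5):
            rand = GridModule(sample_uniform(7, cell, 100 + seed))
            assert cis(metric_tensor(ci7.module, mesh)) < 1e-6 * cis(
                metric_tensor(rand, mesh)
            )

    def test_quartic_rate_scaling(self, cell):
        mod = GridModule(sample_uniform(6, cell, 8))
        mesh = hex_mesh(24, cell)
        c = 1.7
        scaled = GridModule(mod.phases, dc_offset=c / 3.0, wave_amplitude=c * 2.0 / 9.0)
        assert cis(metric_tensor(scaled, mesh)) == pytest.approx(
            c**4 * cis(metric_tensor(mod, mesh)), rel=1e-9
        )

    def test_zero_iff_ci_loss_zero(self, ci7, cell, rng):
        mesh = hex_mesh(24, cell)
        f = metric_tensor(ci7.module, mesh)
        sigma = fit_conformal_scale(f).sigma
        assert (cis(f) < 1e-10) == (ci_loss(ci7.module, mesh, sigma) < 1e-10)
        rand = GridModule(sample_uniform(7, cell, 55))
        frand = metric_tensor(rand, mesh)
        assert cis(frand) > 1e-10
        assert ci_loss(rand, mesh, fit_conformal_scale(frand).sigma) > 1e-10

    def test_single_position_rejected(self, ci7):
        f = metric_tensor(ci7.module, np.zeros((1, 2)))
        with pytest.raises(ValueError):
            cis(f)


class TestConformalScale:
    def test_printed_values(self):
        assert conformal_scale_theory(1.0, 1).sigma == pytest.approx(3 * np.pi**2)
        assert conformal_scale_theory(2.0 / 9.0, 7).sigma == pytest.approx(10.235, abs=1e-3)

    def test_square_ratio_is_three_halves(self):
        h = conformal_scale_theory(0.2, 10, pattern="hexagonal").sigma
        s = conformal_scale_theory(0.2, 10, pattern="square").sigma
        assert h / s == pytest.approx(1.5)

    def test_frequency_scaling(self):
        assert conformal_scale_theory(0.5, 3, f=2.0).sigma == pytest.approx(
            4.0 * conformal_scale_theory(0.5, 3, f=1.0).sigma
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            conformal_scale_theory(-1.0, 5)
        with pytest.raises(ValueError):
            ConformalScale(0.0)


class TestTrajectoryLengths:
    def test_constant_path_is_zero(self, ci7):
        path = np.tile([[0.1, 0.1]], (5, 1))
        assert trajectory_lengths(ci7.module, path) == (0.0, 0.0)

    def test_ci_ratio_is_sqrt_sigma(self, ci7):
        t = np.linspace(0, 1, 2001)
        path = np.column_stack([0.3 * t, 0.2 * np.sin(2 * np.pi * t)])
        phys, neural = trajectory_lengths(ci7.module, path)
        assert neural / phys == pytest.approx(np.sqrt(ci7.sigma), rel=0.01)

    def test_clustered_phases_distort_local_ratio(self, cell, rng):
        clustered = GridModule(0.05 * rng.normal(size=(7, 2)))
        steps = np.linspace(0, 1, 400)
        seg1 = np.column_stack([0.1 * steps, np.zeros_like(steps)])
        seg2 = seg1 + np.array([0.45, 0.3])
        r1 = np.divide(*trajectory_lengths(clustered, seg1)[::-1])
        r2 = np.divide(*trajectory_lengths(clustered, seg2)[::-1])
        assert abs(r1 - r2) / max(r1, r2) > 0.10

    def test_short_path_rejected(self, ci7):
        with pytest.raises(ValueError):
            trajectory_lengths(ci7.module, np.zeros((1, 2)))


class TestEllipseFit:
    def test_circle_has_zero_eccentricity(self):
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        e = ellipse_fit(np.column_stack([np.cos(t), np.sin(t)]))
        assert e.eccentricity == pytest.approx(0.0, abs=1e-6)

    def test_two_to_one_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        e = ellipse_fit(np.column_stack([2 * np.cos(t), np.sin(t)]))
        assert e.eccentricity == pytest.approx(np.sqrt(3.0) / 2.0, abs=1e-10)
        assert (e.semi_major, e.semi_minor) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_rotation_invariance(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([2 * np.cos(t), np.sin(t)])
        e0 = ellipse_fit(pts)
        e30 = ellipse_fit(pts @ rotation_matrix(np.pi / 6).T)
        assert abs(e30.eccentricity - e0.eccentricity) < 1e-8
        assert np.degrees(e30.orientation) == pytest.approx(30.0, abs=1e-6)

    def test_degenerate_input_rejected(self):
        line = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            ellipse_fit(line)
        with pytest.raises(ValueError):
            ellipse_fit(np.zeros((4, 2)))
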