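import numpy as np
import pytest

from hopflow.energies import (LandscapeField, MemoryGeometry,
                              diffusion_energy, diffusion_energy_grad,
                              equivalence_gap, extended_memory_energy,
                              gradient_flow, landscape_energy,
                              numerical_gradient, reconstructive_energy,
                              render_landscape, semantic_energy)
from hopflow.hopfield import modern_energy
from hopflow.patterns import generate_patterns
from hopflow.schedule import DiffusionSchedule

SCHEDULE = DiffusionSchedule()


def unit_norm_patterns(n, d, seed):
    Y = generate_patterns(n, d, seed=seed)
    return Y / np.linalg.norm(Y, axis=1, keepdims=True)


class TestDiffusionEnergy:
    def test_single_pattern_quadratic_bowl(self, rng):
        y = generate_patterns(1, 4, seed=0)
        t = 0.5
        v = SCHEDULE.ve_variance(t)
        x = rng.standard_normal(4)
        # up to a constant, the energy is ||x - y||^2 / (2 v) * sigma^2
        diff = (diffusion_energy(x, t, y, SCHEDULE)
                - diffusion_energy(y[0], t, y, SCHEDULE))
        assert diff == pytest.approx(
            np.sum((x - y[0]) ** 2) / (2 * v) * SCHEDULE.sigma**2)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        Y = generate_patterns(3, 5, seed=1)
        t = 0.5
        for _ in range(10):
            x = rng.standard_normal(5)
            num = numerical_gradient(
                lambda z: diffusion_energy(z, t, Y, SCHEDULE), x)
            assert np.abs(num - diffusion_energy_grad(x, t, Y, SCHEDULE)
                          ).max() < 1e-8

    def test_grid_minimizer_is_nearest_pattern(self):
        Y = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0]])
        t = 1.0 - 0.05  # sharp wells
        xs = np.linspace(-1.5, 1.5, 61)
        X, Yg = np.meshgrid(xs, xs, indexing="ij")
        pts = np.column_stack([X.ravel(), Yg.ravel()])
        e = diffusion_energy(pts, t, Y, SCHEDULE)
        argmin = pts[np.argmin(e)]
        dists = np.linalg.norm(Y - argmin, axis=1)
        assert dists.min() < 0.1

    def test_invariant_under_pattern_relabeling(self, rng):
        Y = generate_patterns(4, 5, seed=2)
        x = rng.standard_normal(5)
        perm = np.random.default_rng(0).permutation(4)
        assert diffusion_energy(x, 0.4, Y, SCHEDULE) == pytest.approx(
            diffusion_energy(x, 0.4, Y[perm], SCHEDULE))


class TestHopfieldEquivalence:
    def test_gap_vanishes_for_unit_norm_patterns(self):
        # the scaled diffusion energy equals the softmax-network energy
        # up to an x-independent constant
        for seed in range(5):
            Y = unit_norm_patterns(4, 5, seed)
            for t in (0.2, 0.5, 0.9):
                assert equivalence_gap(Y, t, SCHEDULE, n_probes=100,
                                       seed=seed) < 1e-8

    def test_single_pattern_gap_constant(self):
        Y = unit_norm_patterns(1, 6, 1)
        assert equivalence_gap(Y, 0.5, SCHEDULE, n_probes=50, seed=0) < 1e-10

    def test_unnormalized_patterns_share_argmin_at_low_temperature(self):
        # ±1 patterns are not unit-norm, but at (T-t) sigma^2 = 1e-3 the
        # pattern norms only shift both energies by a constant
        Y = generate_patterns(3, 2, seed=3)
        t = 1.0 - 1e-3
        beta = 1.0 / SCHEDULE.ve_variance(t)
        xs = np.linspace(-1.5, 1.5, 41)
        X, Yg = np.meshgrid(xs, xs, indexing="ij")
        pts = np.column_stack([X.ravel(), Yg.ravel()])
        a = diffusion_energy(pts, t, Y, SCHEDULE)
        b = modern_energy(pts, Y, beta)
        assert np.argmin(a) == np.argmin(b)


class TestExtendedMemoryEnergy:
    def test_single_point_subspaces_reduce_to_point_memory(self, rng):
        Y = generate_patterns(3, 4, seed=4)
        geom = MemoryGeometry.extended([y[None, :] for y in Y])
        x = rng.standard_normal(4)
        beta = 2.0
        from scipy.special import logsumexp
        expected = logsumexp(beta * (x @ Y.T))
        assert extended_memory_energy(x, geom, beta) == pytest.approx(expected)

    def test_segment_attracts_gradient_flow(self, rng):
        seg = np.column_stack([np.linspace(-1, 1, 40), np.full(40, 0.8)])
        geom = MemoryGeometry.extended([seg])
        energy = lambda p: landscape_energy(p, geom, beta=4.0)
        for start in rng.uniform(-1.8, 1.8, size=(10, 2)):
            end = gradient_flow(energy, start, step=0.1, n_steps=300)[-1]
            dist = np.hypot(max(0.0, abs(end[0]) - 1.0), end[1] - 0.8)
            assert dist < 0.1

    def test_quadrature_refinement_consistency(self, rng):
        # doubling the (midpoint-rule) subspace discretization barely
        # moves the energy
        def midpoint_segment(n):
            s = -1.0 + (2.0 * np.arange(n) + 1.0) / n
            return np.column_stack([s, s * 0.5])

        coarse = MemoryGeometry.extended([midpoint_segment(200)])
        fine = MemoryGeometry.extended([midpoint_segment(400)])
        for _ in range(20):
            x = rng.uniform(-1.5, 1.5, size=2)
            assert abs(extended_memory_energy(x, coarse, 3.0)
                       - extended_memory_energy(x, fine, 3.0)) < 1e-3

    def test_rejects_wrong_geometry_kind(self):
        geom = MemoryGeometry.points(np.ones((1, 2)))
        with pytest.raises(ValueError):
            extended_memory_energy(np.zeros(2), geom, 1.0)


class TestSemanticEnergy:
    def test_point_mass_reduces_to_single_pattern_energy(self, rng):
        y = np.array([[0.5, -0.25]])
        geom = MemoryGeometry.semantic(y)
        x = rng.standard_normal(2)
        assert semantic_energy(x, geom, beta=3.0, sigma=1.5) == pytest.approx(
            1.5**2 * 3.0 * float(x @ y[0]))

    def test_flow_pushes_probes_toward_circle(self, rng):
        angles = np.random.default_rng(0).uniform(0, 2 * np.pi, 300)
        circle = 1.2 * np.column_stack([np.cos(angles), np.sin(angles)])
        geom = MemoryGeometry.semantic(circle)
        energy = lambda p: landscape_energy(p, geom, beta=4.0)
        for start in rng.uniform(-1.8, 1.8, size=(6, 2)):
            if np.linalg.norm(start) < 0.3:
                continue  # near the centre the pull direction is ambiguous
            traj = gradient_flow(energy, start, step=0.1, n_steps=300)
            r0 = np.linalg.norm(traj[0])
            r1 = np.linalg.norm(traj[-1])
            assert abs(r1 - 1.2) < max(0.2, abs(r0 - 1.2))
            assert 0.95 < r1 < 1.4

    def test_rotation_invariance(self, rng):
        angles = np.random.default_rng(1).uniform(0, 2 * np.pi, 100)
        circle = np.column_stack([np.cos(angles), np.sin(angles)])
        geom = MemoryGeometry.semantic(circle)
        phi = 0.7
        R = np.array([[np.cos(phi), -np.sin(phi)],
                      [np.sin(phi), np.cos(phi)]])
        geom_rot = MemoryGeometry.semantic(circle @ R.T)
        x = rng.standard_normal(2)
        assert semantic_energy(x, geom, 2.0) == pytest.approx(
            semantic_energy(R @ x, geom_rot, 2.0))


class TestReconstructiveEnergy:
    def circle_geometry(self):
        angles = np.random.default_rng(2).uniform(0, 2 * np.pi, 300)
        circle = 1.2 * np.column_stack([np.cos(angles), np.sin(angles)])
        return MemoryGeometry.reconstructive(
            [np.array([[1.0, 0.0]])], [np.array([1.0])], circle)

    def test_zero_sharpness_gives_constant_energy(self, rng):
        geom = self.circle_geometry()
        vals = [reconstructive_energy(rng.standard_normal(2), geom, 0.0)
                for _ in range(5)]
        assert np.ptp(vals) < 1e-12
        assert vals[0] == pytest.approx(np.log(2))  # one core + one integral

    def test_core_gradient_lies_in_projection_row_space(self):
        # with the semantic samples at the origin, the only x-dependence
        # comes through f(x), so the gradient has no component outside
        # the projection's row space
        geom = MemoryGeometry.reconstructive(
            [np.array([[1.0, 0.0]])], [np.array([1.0])], np.zeros((1, 2)))
        g = numerical_gradient(
            lambda z: reconstructive_energy(z, geom, 2.0),
            np.array([0.3, -0.7]))
        assert abs(g[1]) < 1e-8
        assert abs(g[0]) > 1e-3

    def test_flow_recovers_core_feature_and_reconstructs_rest(self):
        # the stored 1-D core pins the first coordinate near xi = 1 while
        # the second relaxes onto the semantic manifold's basin
        geom = self.circle_geometry()
        energy = lambda p: landscape_energy(p, geom, beta=4.0)
        for start in (np.array([0.5, 1.0]), np.array([1.5, 0.5]),
                      np.array([0.8, -0.8])):
            end = gradient_flow(energy, start, step=0.1, n_steps=400)[-1]
            assert abs(end[0] - 1.0) < 0.15

    def test_validates_projection_shapes(self):
        with pytest.raises(ValueError):
            MemoryGeometry.reconstructive(
                [np.eye(2)], [np.ones(2)], np.zeros((1, 2)))


class TestLandscapeRendering:
    def test_point_memories_are_grid_minima(self):
        pts = np.array([[1.0, 1.0], [-1.0, 0.8], [0.4, -1.2]])
        geom = MemoryGeometry.points(pts)
        field = render_landscape(
            lambda p: landscape_energy(p, geom, beta=4.0), resolution=40)
        cell = field.xs[1] - field.xs[0]
        i, j = np.unravel_index(np.argmin(field.energy), field.energy.shape)
        gmin = np.array([field.xs[i], field.ys[j]])
        assert np.linalg.norm(pts - gmin, axis=1).min() < 2 * cell
        # vector field approximately vanishes at the minimum
        assert np.hypot(field.grad_x[i, j], field.grad_y[i, j]) < 0.5

    def test_trajectories_recorded_and_text_export(self, tmp_path):
        geom = MemoryGeometry.points(np.array([[0.5, 0.5]]))
        field = render_landscape(
            lambda p: landscape_energy(p, geom, beta=4.0), resolution=10,
            starts=[[1.0, -1.0]], flow_steps=50)
        assert len(field.trajectories) == 1
        out = tmp_path / "field.txt"
        field.to_text(out)
        data = np.loadtxt(out)
        assert data.shape == (100, 5)

    def test_rejects_non_planar_starts(self):
        geom = MemoryGeometry.points(np.array([[0.0, 0.0]]))
        with pytest.raises(ValueError):
            render_landscape(
                lambda p: landscape_energy(p, geom, beta=1.0),
                resolution=5, starts=[[1.0, 2.0, 3.0]])
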