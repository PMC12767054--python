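import numpy as np
import pytest

from sparseffr import dynamics as dyn
from sparseffr.contours import RawCell, intra_distance_matrix, resample_contour
from sparseffr.synthetic import double_well_force, double_well_potential
from .conftest import AnalyticForceField, make_egg


BOUNDS = np.array([[-2.2, 2.2], [-1.6, 1.6]])


class TestSimulate:
    def test_deterministic_linear_decay(self, linear_ff):
        ff = linear_ff(-np.eye(2), 0.0)
        x0 = np.array([[1.0, 0.5]] * 10)
        dt = 1e-3
        ens = dyn.simulate(ff, x0, dt=dt, n_steps=1000, n_traj=10, seed=0,
                          bounds=np.array([[-2, 2], [-2, 2]]))
        expect = np.array([1.0, 0.5]) * np.exp(-1.0)
        assert np.allclose(ens.states[-1], expect, atol=5e-3)

    def test_brownian_variance_growth(self):
        D = 0.05
        ff = AnalyticForceField(lambda x: np.zeros_like(np.atleast_2d(x)), D)
        x0 = np.zeros((2000, 2))
        t = 0.5
        ens = dyn.simulate(ff, x0, dt=1e-3, n_steps=500, n_traj=2000, seed=1,
                          bounds=np.array([[-10, 10], [-10, 10]]))
        var = ens.states[-1].var(axis=0)
        assert np.allclose(var, 2 * D * t, rtol=0.10)

    def test_same_seed_identical(self, linear_ff):
        ff = linear_ff(-np.eye(2), 0.01)
        x0 = np.random.default_rng(0).normal(size=(50, 2))
        e1 = dyn.simulate(ff, x0, dt=1e-3, n_steps=200, n_traj=50, seed=42)
        e2 = dyn.simulate(ff, x0, dt=1e-3, n_steps=200, n_traj=50, seed=42)
        assert np.array_equal(e1.states, e2.states)

    def test_reflecting_walls_contain_trajectories(self):
        ff = AnalyticForceField(lambda x: np.zeros_like(np.atleast_2d(x)), 1.0)
        b = np.array([[-0.5, 0.5], [-0.5, 0.5]])
        ens = dyn.simulate(ff, np.zeros((100, 2)), dt=1e-3, n_steps=2000,
                          n_traj=100, seed=2, bounds=b)
        pts = ens.samples()
        assert pts[:, 0].min() >= -0.5 and pts[:, 0].max() <= 0.5

    def test_unstable_dt_rejected(self, linear_ff):
        ff = linear_ff(-1000 * np.eye(2), 0.0)
        with pytest.raises(ValueError, match="dt"):
            dyn.simulate(ff, np.ones((10, 2)), dt=1.0, n_steps=10, n_traj=10,
                        bounds=np.array([[-2, 2], [-2, 2]]))


class TestLandscape:
    @pytest.fixture(scope="class")
    def dw_landscape(self):
        b, D = 0.15, 0.08
        ff = AnalyticForceField(double_well_force(b, 0.0), D)
        rng = np.random.default_rng(3)
        x0 = np.vstack([
            np.column_stack([rng.normal(-1, 0.2, 150), rng.normal(0, 0.3, 150)]),
            np.column_stack([rng.normal(1, 0.2, 150), rng.normal(0, 0.3, 150)]),
        ])
        ens = dyn.simulate(ff, x0, dt=2e-3, n_steps=40000, n_traj=300,
                          burn_in=4000, seed=3, bounds=BOUNDS)
        land = dyn.steady_state_landscape(ens, grid=96)
        return b, D, ff, ens, land

    def test_boltzmann_correlation(self, dw_landscape):
        b, D, ff, ens, land = dw_landscape
        GX, GY = np.meshgrid(land.xs, land.ys, indexing="ij")
        Phi = double_well_potential(
            np.column_stack([GX.ravel(), GY.ravel()]), b
        ).reshape(land.U.shape)
        mask = land.p_ss > 1e-4
        corr = np.corrcoef(land.U[mask], Phi[mask] / D)[0, 1]
        assert corr >= 0.95

    def test_density_normalized(self, dw_landscape):
        *_, land = dw_landscape
        total = land.p_ss.sum() * land.cell_area
        assert abs(total - 1.0) < 1e-3

    def test_uniform_samples_flat_U(self):
        rng = np.random.default_rng(4)

        class FakeEns:
            states = rng.uniform(-1, 1, (50, 2000, 2))
            bounds = np.array([[-1, 1], [-1, 1]])

            def samples(self):
                return self.states.reshape(-1, 2)

        land = dyn.steady_state_landscape(FakeEns(), grid=32, smooth_bw=1.0)
        inner = land.U[4:-4, 4:-4]
        assert inner.max() - inner.min() < 0.25

    def test_find_basins_double_well(self, dw_landscape):
        *_, land = dw_landscape
        basins = dyn.find_basins(land, max_depth_merge=0.3)
        assert basins.n_basins == 2
        xs = np.sort(basins.minima[:, 0])
        assert abs(xs[0] + 1) < 0.15 and abs(xs[1] - 1) < 0.15

    def test_single_well_one_basin(self, linear_ff):
        ff = linear_ff(-np.eye(2), 0.05)
        x0 = np.random.default_rng(5).normal(0, 0.2, (200, 2))
        ens = dyn.simulate(ff, x0, dt=2e-3, n_steps=20000, n_traj=200,
                          burn_in=2000, seed=5,
                          bounds=np.array([[-1.5, 1.5], [-1.5, 1.5]]))
        land = dyn.steady_state_landscape(ens, grid=64)
        basins = dyn.find_basins(land, max_depth_merge=0.5)
        assert basins.n_basins == 1
        assert np.linalg.norm(basins.minima[0]) < 0.15

    def test_merge_rule(self, dw_landscape):
        *_, land = dw_landscape
        # a merge threshold far above the barrier collapses the two wells
        merged = dyn.find_basins(land, max_depth_merge=50.0)
        assert merged.n_basins == 1
        assert len(merged.merge_log) >= 1


class TestAssignShapeModes:
    def test_cell_at_minimum(self):
        basins = dyn.BasinSet(np.array([[0.0, 0.0], [3.0, 0.0]]),
                              np.array([0.0, 0.1]), np.zeros((4, 4), int))
        labels, post = dyn.assign_shape_modes(np.array([[0.0, 0.0]]), basins)
        assert labels[0] == 0 and post[0, 0] > 0.5

    def test_equidistant_cell_is_boundary(self):
        basins = dyn.BasinSet(np.array([[0.0, 0.0], [2.0, 0.0]]),
                              np.array([0.0, 0.0]), np.zeros((4, 4), int))
        labels, post = dyn.assign_shape_modes(np.array([[1.0, 0.0]]), basins)
        assert labels[0] == -1
        assert np.allclose(post[0], 0.5, atol=1e-9)

    def test_two_cluster_accuracy(self):
        rng = np.random.default_rng(6)
        c0 = rng.normal([0, 0], 0.3, (100, 2))
        c1 = rng.normal([3, 0], 0.3, (100, 2))
        X = np.vstack([c0, c1])
        truth = np.repeat([0, 1], 100)
        basins = dyn.BasinSet(np.array([[0.0, 0.0], [3.0, 0.0]]),
                              np.array([0.0, 0.0]), np.zeros((4, 4), int))
        labels, _ = dyn.assign_shape_modes(X, basins, sigma_mode=1.0)
        assigned = labels >= 0
        acc = (labels[assigned] == truth[assigned]).mean()
        assert acc >= 0.95


class TestMeanShape:
    def _procrustes_rmsd(self, A, B):
        A = A - A.mean(axis=0)
        B = B - B.mean(axis=0)
        # optimal rotation/reflection via SVD over both index shifts
        best = np.inf
        for s in range(len(B)):
            Bs = np.roll(B, s, axis=0)
            U, _, Vt = np.linalg.svd(A.T @ Bs)
            R = U @ Vt
            best = min(best, np.sqrt(np.mean(np.sum((A - Bs @ R.T) ** 2, axis=1))))
            Bs = np.roll(B[::-1], s, axis=0)
            U, _, Vt = np.linalg.svd(A.T @ Bs)
            R = U @ Vt
            best = min(best, np.sqrt(np.mean(np.sum((A - Bs @ R.T) ** 2, axis=1))))
        return best

    def test_single_member_roundtrip(self):
        c = resample_contour(RawCell("e", 0.0, make_egg()), K=60)
        rec = dyn.mean_shape([c])
        diam = np.linalg.norm(c.points.max(axis=0) - c.points.min(axis=0))
        assert self._procrustes_rmsd(c.points, rec) <= 1e-3 * diam

    def test_two_identical_members(self):
        c = resample_contour(RawCell("e", 0.0, make_egg()), K=40)
        r1 = dyn.mean_shape([c])
        r2 = dyn.mean_shape([c, c])
        assert self._procrustes_rmsd(r1, r2) < 1e-9

    def test_circles_bounded_interpolation(self):
        th = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        mk = lambda r: resample_contour(
            RawCell("c", 0.0, np.column_stack([r * np.cos(th), r * np.sin(th)])),
            K=50,
        )
        rec = dyn.mean_shape([mk(1.0), mk(3.0)])
        radii = np.linalg.norm(rec - rec.mean(axis=0), axis=1)
        assert 1.0 < radii.mean() < 3.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dyn.mean_shape([])


class TestFluxField:
    def test_equilibrium_flux_small(self):
        b, D = 0.15, 0.08
        ff = AnalyticForceField(double_well_force(b, 0.0), D)
        rng = np.random.default_rng(7)
        x0 = np.vstack([
            np.column_stack([rng.normal(-1, 0.2, 150), rng.normal(0, 0.3, 150)]),
            np.column_stack([rng.normal(1, 0.2, 150), rng.normal(0, 0.3, 150)]),
        ])
        ens = dyn.simulate(ff, x0, dt=2e-3, n_steps=40000, n_traj=300,
                          burn_in=4000, seed=7, bounds=BOUNDS)
        land = dyn.steady_state_landscape(ens, grid=96)
        fl = dyn.flux_field(ff, land)
        mask = land.p_ss > 1e-2
        v_mag = np.linalg.norm(fl.V_ss[mask], axis=-1).mean()
        g_mag = (np.linalg.norm(fl.gradU[mask], axis=-1) * D).mean()
        assert v_mag <= 0.12 * g_mag / D * D + 0.1 * g_mag  # ~10% bound
        assert v_mag <= 0.15 * g_mag

    def test_rotational_ou_curl_flux(self, linear_ff):
        w, D = 1.0, 0.1
        A = np.array([[-1.0, w], [-w, -1.0]])
        ff = linear_ff(A, D)
        rng = np.random.default_rng(8)
        x0 = rng.normal(0, np.sqrt(D), (400, 2))
        s = 6 * np.sqrt(D)
        ens = dyn.simulate(ff, x0, dt=2e-3, n_steps=30000, n_traj=400,
                          burn_in=3000, seed=8,
                          bounds=np.array([[-s, s], [-s, s]]))
        land = dyn.steady_state_landscape(ens, grid=96)
        fl = dyn.flux_field(ff, land)
        GX, GY = np.meshgrid(land.xs, land.ys, indexing="ij")
        pts = np.column_stack([GX.ravel(), GY.ravel()])
        Om = np.array([[0.0, w], [-w, 0.0]])
        truth = (pts @ Om.T).reshape(fl.V_ss.shape)
        mask = land.p_ss > 1e-4 / land.cell_area * land.cell_area  # p > 1e-4
        mask = land.p_ss > 0.05 * land.p_ss.max()
        err = np.sqrt(np.mean(np.sum((fl.V_ss[mask] - truth[mask]) ** 2, axis=-1)))
        mag = np.sqrt(np.mean(np.sum(truth[mask] ** 2, axis=-1)))
        assert err / mag <= 0.15

    def test_flux_divergence_small_at_steady_state(self, linear_ff):
        ff = linear_ff(np.array([[-1.0, 1.0], [-1.0, -1.0]]), 0.1)
        rng = np.random.default_rng(9)
        x0 = rng.normal(0, 0.3, (400, 2))
        ens = dyn.simulate(ff, x0, dt=2e-3, n_steps=30000, n_traj=400,
                          burn_in=5000, seed=9,
                          bounds=np.array([[-2, 2], [-2, 2]]))
        land = dyn.steady_state_landscape(ens, grid=96)
        fl = dyn.flux_field(ff, land)
        divJ = (np.gradient(fl.J[..., 0], land.xs, axis=0)
                + np.gradient(fl.J[..., 1], land.ys, axis=1))
        mask = land.p_ss > 0.05 * land.p_ss.max()
        h = land.xs[1] - land.xs[0]
        mean_J = np.linalg.norm(fl.J[mask], axis=-1).mean()
        assert np.abs(divJ[mask]).mean() <= 0.05 * mean_J / h
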