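import numpy as np
import pytest

from sparseffr.field import ForceField, SmoothField, kernel_bandwidth, vfc_fit


def linear_field_data(A, n=200, noise=0.0, seed=0, box=2.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-box, box, (n, 2))
    Y = X @ np.asarray(A, float).T + noise * rng.standard_normal((n, 2))
    return X, Y


class TestKernelBandwidth:
    def test_two_points(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0], [3.0, 4.0], [0.0, 0.0]])
        # mean squared nn distance is dominated by the duplicate structure;
        # use the clean two-point case via direct formula instead
        X2 = np.array([[0.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            kernel_bandwidth(X2)  # N < 5

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        b1 = kernel_bandwidth(X)
        b2 = kernel_bandwidth(3.0 * X)
        assert np.isclose(b2, b1 / 9.0, rtol=1e-10)

    def test_brute_force_grid(self):
        g = np.linspace(0, 1, 10)
        GX, GY = np.meshgrid(g, g, indexing="ij")
        X = np.column_stack([GX.ravel(), GY.ravel()])
        frac = 0.2
        k = int(np.ceil(len(X) * frac))
        # independent brute-force double loop
        acc = []
        for i in range(len(X)):
            d2 = np.sum((X - X[i]) ** 2, axis=1)
            d2 = np.sort(d2)[1:k + 1]
            acc.append(d2.mean())
        expect = 2.0 / np.mean(acc)
        assert np.isclose(kernel_bandwidth(X, frac), expect, atol=1e-10)

    def test_duplicate_only_data_raises(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            kernel_bandwidth(X)


class TestVFCFit:
    def test_zero_targets_zero_field(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        f = vfc_fit(X, np.zeros((50, 2)), seed=0)
        assert np.abs(f(X)).max() < 1e-8

    def test_linear_field_recovery(self):
        A = np.array([[-1.0, 0.5], [0.2, -0.8]])
        X, Y = linear_field_data(A, n=300, noise=0.0, seed=1)
        f = vfc_fit(X, Y, seed=1)
        rng = np.random.default_rng(2)
        Xh = rng.uniform(-1.5, 1.5, (100, 2))  # inside the hull
        rmse = np.sqrt(np.mean(np.sum((f(Xh) - Xh @ A.T) ** 2, axis=1)))
        assert rmse <= 1e-2 * np.linalg.norm(A) * 2.0

    def test_outlier_robustness(self):
        A = np.array([[-1.0, 0.3], [-0.3, -1.0]])
        rng = np.random.default_rng(3)
        X, Y = linear_field_data(A, n=250, noise=0.02, seed=3)
        n_out = 50  # 20% gross outliers on top of 250 inliers -> 300 total
        Xo = rng.uniform(-2, 2, (n_out, 2))
        Yo = rng.uniform(-5, 5, (n_out, 2))
        Xa = np.vstack([X, Xo])
        Ya = np.vstack([Y, Yo])
        f = vfc_fit(Xa, Ya, seed=3)
        f_clean = vfc_fit(X, Y, seed=3)
        rmse = np.sqrt(np.mean(np.sum((f(X) - X @ A.T) ** 2, axis=1)))
        rmse_clean = np.sqrt(np.mean(np.sum((f_clean(X) - X @ A.T) ** 2, axis=1)))
        true_inlier_frac = 250 / 300
        assert abs(f.gamma - true_inlier_frac) <= 0.1
        assert rmse <= 2.0 * max(rmse_clean, 1e-3)

    def test_mstep_energy_decreases_each_iteration(self):
        A = np.array([[-1.0, 0.0], [0.0, -1.0]])
        X, Y = linear_field_data(A, n=120, noise=0.3, seed=4)
        f = vfc_fit(X, Y, seed=4)
        # the coefficient solve minimizes the energy at that iteration's
        # (responsibilities, sigma^2); verify it never increased it
        assert len(f.energy_trace) == len(f.energy_pre)
        assert np.all(f.energy_trace <= f.energy_pre + 1e-9 * np.abs(f.energy_pre))

    def test_smoothness_increases_with_lambda(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (150, 2))
        Y = np.sin(3 * X) + 0.1 * rng.standard_normal((150, 2))
        norms = [vfc_fit(X, Y, lambda_=lam, seed=5).rkhs_norm2()
                 for lam in (0.3, 3.0, 30.0)]
        assert norms[0] >= norms[1] >= norms[2]

    def test_translation_equivariance(self):
        # anchored regime (M < N): sigma^2 settles at the noise level so the
        # regularized solve is numerically stable under translation
        A = np.array([[-1.0, 0.2], [0.1, -0.5]])
        X, Y = linear_field_data(A, n=600, noise=0.05, seed=6)
        t = np.array([5.0, -3.0])
        f0 = vfc_fit(X, Y, M=300, seed=6)
        f1 = vfc_fit(X + t, Y, M=300, beta=f0.beta, seed=6)
        Xq = np.array([[0.2, 0.1], [-0.5, 0.7]])
        assert np.allclose(f0(Xq), f1(Xq + t), atol=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            vfc_fit(np.zeros((5, 2)), np.zeros((5, 2)))

    def test_jacobian_matches_finite_difference(self):
        rng = np.random.default_rng(7)
        f = SmoothField(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)), 0.7)
        x = np.array([0.1, -0.3])
        h = 1e-6
        J_fd = np.empty((2, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            J_fd[:, j] = (f(x + e) - f(x - e)) / (2 * h)
        assert np.allclose(f.jacobian(x), J_fd, atol=1e-6)

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        f = SmoothField(rng.normal(size=(6, 2)), rng.normal(size=(6, 2)),
                        0.5, 0.8, 0.01, 3.0, 5.0)
        p = tmp_path / "field.json"
        f.to_json(p)
        g = SmoothField.from_json(p)
        x = rng.normal(size=(5, 2))
        assert np.allclose(f(x), g(x))
        assert g.gamma == f.gamma and g.beta == f.beta


class TestForceField:
    def test_decomposition_identity_at_random_points(self):
        rng = np.random.default_rng(9)
        V = SmoothField(rng.normal(size=(8, 2)), rng.normal(size=(8, 2)), 0.5)
        S = SmoothField(rng.normal(size=(8, 2)), rng.normal(size=(8, 2)), 0.5)
        ff = ForceField(V, S, D=0.13)
        X = rng.normal(size=(100, 2))
        assert np.allclose(ff.force(X), V(X) + 0.13 * S(X), atol=1e-12)

    def test_zero_diffusion_limit(self):
        rng = np.random.default_rng(10)
        V = SmoothField(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), 1.0)
        S = SmoothField(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), 1.0)
        ff = ForceField(V, S, D=0.0)
        X = rng.normal(size=(20, 2))
        assert np.allclose(ff.force(X), V(X))

    def test_changing_D_needs_no_refit(self):
        rng = np.random.default_rng(11)
        V = SmoothField(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), 1.0)
        S = SmoothField(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), 1.0)
        ff = ForceField(V, S, D=0.003)
        ff2 = ff.with_D(0.05)
        assert ff2.V is ff.V and ff2.S is ff.S and ff2.D == 0.05
        x = np.zeros(2)
        assert np.allclose(ff2.force(x), V(x) + 0.05 * S(x))

    def test_zero_score_fit_gives_pure_flow(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 2))
        V = vfc_fit(X, X @ np.array([[-1.0, 0], [0, -1.0]]), seed=0)
        S = vfc_fit(X, np.zeros((60, 2)), seed=0)
        ff = ForceField(V, S, D=0.7)
        assert np.allclose(ff.force(X), V(X), atol=1e-7)
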