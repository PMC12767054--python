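"""Smooth, outlier-robust global vector fields by regularized kernel
regression with EM (vector-field-consensus style).

The field is a Gaussian-kernel expansion f(x) = sum_m exp(-beta ||x - z_m||^2) c_m
over M anchor points. Observed vectors are modeled as a two-component
mixture: inliers carry isotropic Gaussian residuals (variance sigma^2),
outliers a uniform density 1/a over the outlier variation volume. EM
alternates responsibilities with a Tikhonov-regularized weighted
least-squares solve for the coefficients; the smoothness weight lambda
balances data fidelity against the RKHS norm of f. The flow field V and the
score field S are fitted independently, so the force F(x; D) = V(x) + D S(x)
is available for any diffusion coefficient without refitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = ["SmoothField", "ForceField", "kernel_bandwidth", "vfc_fit"]


@dataclass
class SmoothField:
    """Gaussian-kernel vector field f(x) = sum_m k_beta(x, z_m) c_m."""

    anchors: np.ndarray  # (M, 2)
    coeffs: np.ndarray  # (M, 2)
    beta: float
    gamma: float = 1.0  # final inlier fraction
    sigma2: float = 0.0  # final residual variance
    lambda_: float = 3.0
    a_vol: float = 5.0
    energy_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    energy_pre: np.ndarray = field(default_factory=lambda: np.zeros(0))
    responsibilities: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        K = np.exp(-self.beta * cdist(X, self.anchors, "sqeuclidean"))
        out = K @ self.coeffs
        return out[0] if single else out

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """(2, 2) Jacobian d f_i / d x_j at a single point (analytic)."""
        x = np.asarray(x, float)
        diff = x[None, :] - self.anchors  # (M, 2)
        k = np.exp(-self.beta * np.sum(diff**2, axis=1))  # (M,)
        # d f / d x_j = sum_m c_m * (-2 beta diff_j) k_m
        return np.einsum("mi,mj->ij", self.coeffs * k[:, None], -2.0 * self.beta * diff)

    def rkhs_norm2(self) -> float:
        Kmm = np.exp(-self.beta * cdist(self.anchors, self.anchors, "sqeuclidean"))
        return float(np.sum(self.coeffs * (Kmm @ self.coeffs)))

    def to_json(self, path) -> None:
        doc = {
            "anchors": self.anchors.tolist(),
            "coeffs": self.coeffs.tolist(),
            "beta": self.beta,
            "gamma": self.gamma,
            "sigma2": self.sigma2,
            "lambda_": self.lambda_,
            "a_vol": self.a_vol,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "SmoothField":
        doc = json.loads(Path(path).read_text())
        return cls(
            np.asarray(doc["anchors"], float),
            np.asarray(doc["coeffs"], float),
            doc["beta"],
            doc["gamma"],
            doc["sigma2"],
            doc["lambda_"],
            doc["a_vol"],
        )


@dataclass
class ForceField:
    """F(x) = V(x) + D * S(x); V, S independently parameterized.

    V and S may be fitted SmoothFields or any callables mapping (n, 2) ->
    (n, 2) (analytic benchmark fields plug in directly).
    """

    V: SmoothField
    S: SmoothField
    D: float

    def force(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.V(x)) + self.D * np.asarray(self.S(x))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.force(x)

    def with_D(self, D: float) -> "ForceField":
        """Same fitted fields at a different diffusion coefficient."""
        return ForceField(self.V, self.S, float(D))

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        for f in (self.V, self.S):
            if not hasattr(f, "jacobian"):
                return _fd_jacobian(self.force, x)
        return self.V.jacobian(x) + self.D * self.S.jacobian(x)


def _fd_jacobian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        J[:, j] = (np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * h)
    return J


def kernel_bandwidth(X: np.ndarray, frac: float = 0.2) -> float:
    """beta = 2 / <mean squared distance to the ceil(N*frac) nearest neighbors>.

    The empirical bandwidth rule: for each point take its N*frac nearest
    neighbors, average their squared distances, average over points.
    """
    X = np.asarray(X, float)
    N = len(X)
    if N < 5:
        raise ValueError("need at least 5 points")
    k = int(np.ceil(N * frac))
    d2 = cdist(X, X, "sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    d2s = np.sort(d2, axis=1)[:, :k]
    mean_d2 = float(d2s.mean())
    if mean_d2 <= 0:
        raise ValueError("all pairwise distances are zero; cannot set bandwidth")
    return 2.0 / mean_d2


def vfc_fit(
    X: np.ndarray,
    Y: np.ndarray,
    M: int = 1000,
    gamma0: float = 0.9,
    a_vol: float = 5.0,
    lambda_: float = 3.0,
    beta: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: int = 0,
) -> SmoothField:
    """Robust EM fit of a smooth vector field to (X, Y) samples.

    E-step: inlier responsibility p_n = gamma phi_n / (gamma phi_n + (1-gamma)/a).
    M-step: coefficients minimize E = (1/2 sigma^2) sum p_n ||y_n - f(x_n)||^2
    + (lambda/2) ||f||_H^2 via the anchor (Nystrom) linear system, then the
    responsibility-weighted updates sigma^2 = sum p_n r_n^2 / (2 sum p_n) and
    gamma = sum p_n / N. Iterations stop when the relative energy change
    drops below ``tol``; the energy trace is kept for diagnostics.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    N = len(X)
    if N < 10:
        raise ValueError("need at least 10 samples")
    # the outlier volume a is a fixed density constant; normalizing the
    # targets to unit RMS keeps the mixture balanced for any field scale
    y_scale = float(np.sqrt(np.mean(np.sum(Y**2, axis=1)))) or 1.0
    Y = Y / y_scale
    rng = np.random.default_rng(seed)
    if N < 500 or N <= M:
        anchors = X.copy()
    else:
        anchors = X[rng.choice(N, size=min(M, N), replace=False)]
    Mn = len(anchors)
    if beta is None:
        beta = kernel_bandwidth(X)

    Knm = np.exp(-beta * cdist(X, anchors, "sqeuclidean"))
    Kmm = np.exp(-beta * cdist(anchors, anchors, "sqeuclidean"))

    # whitened Nystrom basis: with C = Q_r L_r^{-1/2} W the RKHS penalty is
    # ||W||^2 and the M-step becomes an identity-ridge solve, which stays
    # well-conditioned even when K_MM itself is numerically singular
    evals, evecs = np.linalg.eigh(Kmm)
    keep = evals > 1e-12 * evals.max()
    Qr = evecs[:, keep]
    Lr_isqrt = 1.0 / np.sqrt(evals[keep])
    Phi = Knm @ (Qr * Lr_isqrt[None, :])  # (N, r)
    r_dim = Phi.shape[1]

    C = np.zeros((Mn, 2))
    gamma = float(gamma0)
    resid = Y.copy()
    sigma2 = float(np.sum(resid**2) / (2.0 * N))
    sigma2 = max(sigma2, 1e-12)

    def _energy(Cm, pw, s2, r2):
        return 0.5 / s2 * float(np.sum(pw * r2)) + 0.5 * lambda_ * float(
            np.sum(Cm * (Kmm @ Cm))
        )

    energies: list[float] = []
    energies_pre: list[float] = []
    p = np.ones(N)
    for it in range(max_iter):
        # E-step
        f_at_X = Knm @ C
        r2 = np.sum((Y - f_at_X) ** 2, axis=1)
        phi = np.exp(-0.5 * r2 / sigma2) / (2.0 * np.pi * sigma2)
        p = gamma * phi / (gamma * phi + (1.0 - gamma) / a_vol + 1e-300)
        energies_pre.append(_energy(C, p, sigma2, r2))
        # M-step: coefficients minimize the energy at this iteration's (p, sigma^2)
        sp = p.sum()
        A = Phi.T @ (p[:, None] * Phi) + lambda_ * sigma2 * np.eye(r_dim)
        B = Phi.T @ (p[:, None] * Y)
        try:
            W = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            logger.warning("vfc_fit: singular M-step system, adding 1e-8 jitter")
            W = np.linalg.solve(A + 1e-8 * np.eye(r_dim), B)
        C = (Qr * Lr_isqrt[None, :]) @ W
        f_at_X = Knm @ C
        r2 = np.sum((Y - f_at_X) ** 2, axis=1)
        E = _energy(C, p, sigma2, r2)
        energies.append(E)
        # parameter updates (responsibility-weighted; D = 2 coordinates)
        sigma2_new = max(float(np.sum(p * r2) / (2.0 * sp)), 1e-12)
        gamma = float(np.clip(sp / N, 1e-6, 1.0))
        stable = abs(sigma2_new - sigma2) <= 1e-6 * sigma2
        sigma2 = sigma2_new
        if it > 0 and (
            stable or abs(energies[-2] - E) <= tol * max(abs(energies[-2]), 1.0)
        ):
            break

    return SmoothField(
        anchors, C * y_scale, beta, gamma, sigma2 * y_scale**2, lambda_, a_vol,
        energy_trace=np.asarray(energies), energy_pre=np.asarray(energies_pre),
        responsibilities=p,
    )
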