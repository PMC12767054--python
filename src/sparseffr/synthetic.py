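"""Ground-truth benchmark generators.

Three families of synthetic data exercise the full pipeline without any
external download:

* Ornstein–Uhlenbeck snapshots — linear drift F(x) = A x with additive
  isotropic noise; every marginal is Gaussian with mean and covariance
  available in closed form (matrix exponential + Lyapunov integral), so the
  flow V, score S and force F are attached analytically at each sample.
* Tilted double-well with curl — F = -grad(Phi) + omega_c R grad(Phi) with
  Phi = barrier (x^2-1)^2 + y^2/2; the rotational part is divergence-free
  and orthogonal to grad(Phi), so p_ss = exp(-Phi/D)/Z exactly and every
  landscape/flux/thermo quantity has an analytic reference.
* Morphing contours — star-shaped polygons whose radial Fourier profile
  interpolates a spindle template (dominant 2nd harmonic, aspect ratio > 3)
  into a branched template (5th/7th harmonics) along a noisy per-cell
  progress variable tied to the day label; emulates an 11-day daily-imaging
  design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .contours import RawCell

__all__ = [
    "AnalyticSystem",
    "SnapshotDataset",
    "MorphingContourDataset",
    "make_ou_snapshots",
    "make_double_well_snapshots",
    "make_morphing_contours",
    "double_well_force",
    "double_well_potential",
]


@dataclass
class AnalyticSystem:
    """A 2D stochastic system with an evaluable true force field."""

    name: str
    F: Callable[[np.ndarray], np.ndarray]
    D: float
    A: np.ndarray | None = None  # linear systems
    stationary_cov: np.ndarray | None = None


@dataclass
class SnapshotDataset:
    """Time-stamped point clouds with the generator's truth attached."""

    coords: np.ndarray  # (N, 2) pooled
    times: np.ndarray  # (N,) time label per sample
    time_points: np.ndarray  # unique times
    V_true: np.ndarray  # (N, 2)
    S_true: np.ndarray  # (N, 2)
    F_true: np.ndarray  # (N, 2)
    system: AnalyticSystem
    seed: int


@dataclass
class MorphingContourDataset:
    cells: list[RawCell]
    progress: np.ndarray  # latent per-cell progress in [0, 1]
    phase: np.ndarray  # 0 = spindle-like, 1 = branched
    days: np.ndarray
    params: dict = field(default_factory=dict)


def _ou_moments(A: np.ndarray, D: float, t: float, mu0: np.ndarray, S0: np.ndarray):
    """Mean and covariance of the OU marginal at time t.

    dX = A X dt + sqrt(2 D) dW;  Sigma_inf solves A S + S A^T + 2 D I = 0 and
    Sigma_t = Sigma_inf - e^{At} (Sigma_inf - Sigma_0) e^{A^T t}.
    """
    Sinf = solve_continuous_lyapunov(A, -2.0 * D * np.eye(2))
    Phi = expm(A * t)
    mu = Phi @ mu0
    St = Sinf - Phi @ (Sinf - S0) @ Phi.T
    return mu, St


def make_ou_snapshots(
    A: np.ndarray,
    D: float,
    times: Sequence[float],
    n_per_time: int,
    x0_mean: np.ndarray | None = None,
    x0_cov: np.ndarray | None = None,
    seed: int = 0,
) -> SnapshotDataset:
    """Exact OU snapshot ensembles (no discretization error).

    Samples are drawn from the closed-form Gaussian marginal at each
    requested time; the attached truth fields are F = A x,
    S = -Sigma_t^{-1} (x - mu_t) and V = F - D S, satisfying F = V + D S
    identically.
    """
    A = np.asarray(A, float)
    if np.any(np.real(np.linalg.eigvals(A)) >= 0):
        raise ValueError("A must be stable (eigenvalues with negative real part)")
    rng = np.random.default_rng(seed)
    mu0 = np.zeros(2) if x0_mean is None else np.asarray(x0_mean, float)
    S0 = 0.05 * np.eye(2) if x0_cov is None else np.asarray(x0_cov, float)

    coords, tl, V, S, F = [], [], [], [], []
    for t in times:
        mu, St = _ou_moments(A, D, float(t), mu0, S0)
        X = rng.multivariate_normal(mu, St, size=n_per_time)
        P = np.linalg.inv(St)
        Fx = X @ A.T
        Sx = -(X - mu) @ P.T
        coords.append(X)
        tl.append(np.full(n_per_time, float(t)))
        F.append(Fx)
        S.append(Sx)
        V.append(Fx - D * Sx)
    Sinf = solve_continuous_lyapunov(A, -2.0 * D * np.eye(2))
    sys = AnalyticSystem("ou", lambda x: np.atleast_2d(x) @ A.T, D, A=A, stationary_cov=Sinf)
    return SnapshotDataset(
        np.vstack(coords), np.concatenate(tl), np.asarray(times, float),
        np.vstack(V), np.vstack(S), np.vstack(F), sys, seed,
    )


def ou_benchmark(seed: int = 7, n_per_time: int = 300) -> SnapshotDataset:
    """Standard rotational-OU drift-recovery benchmark.

    A damped rotation A = [[-1, 1], [-1, -1]] with D = 0.1, six snapshots
    0.2 days apart, initialized away from the fixed point (mean (2, 0),
    isotropic spread 0.3): the ensemble relaxes in a spiral, giving both a
    strong deterministic flow signal and a nontrivial score field.
    """
    A = np.array([[-1.0, 1.0], [-1.0, -1.0]])
    return make_ou_snapshots(
        A, 0.1, times=[0.2 * i for i in range(6)], n_per_time=n_per_time,
        x0_mean=np.array([2.0, 0.0]), x0_cov=0.09 * np.eye(2), seed=seed,
    )


def double_well_potential(x: np.ndarray, barrier: float = 1.0) -> np.ndarray:
    """Phi(x, y) = barrier (x^2 - 1)^2 + y^2 / 2."""
    X = np.atleast_2d(np.asarray(x, float))
    return barrier * (X[:, 0] ** 2 - 1.0) ** 2 + 0.5 * X[:, 1] ** 2


def _grad_phi(X: np.ndarray, barrier: float) -> np.ndarray:
    g = np.empty_like(X)
    g[:, 0] = 4.0 * barrier * X[:, 0] * (X[:, 0] ** 2 - 1.0)
    g[:, 1] = X[:, 1]
    return g


def double_well_force(
    barrier: float = 1.0,
    curl: float = 0.0,
    curl_mode: str = "potential",
    curl_center: tuple[float, float] = (0.3, 0.0),
) -> Callable[[np.ndarray], np.ndarray]:
    """Double-well drift with a rotational (non-gradient) component.

    ``curl_mode="potential"``: F = -grad(Phi) + curl * R grad(Phi), R the
    90-degree rotation. R grad(Phi) is orthogonal to grad(Phi) and
    divergence-free, so the Boltzmann density exp(-Phi/D) stays stationary
    for every curl strength — the analytically controlled benchmark.
    Note the rotational force vanishes wherever grad(Phi) does, in
    particular at the saddle.

    ``curl_mode="rigid"``: F = -grad(Phi) + curl * Omega (x - curl_center),
    a rigid-body rotation about ``curl_center``. Divergence-free but not
    orthogonal to grad(Phi), so the steady state is genuinely
    non-Boltzmann and the rotational force stays finite at the saddle —
    the benchmark whose transition-path flux grows strongly with noise.
    """

    def F(x: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(x, float))
        g = _grad_phi(X, barrier)
        if curl_mode == "potential":
            rot = np.column_stack([-g[:, 1], g[:, 0]])
        elif curl_mode == "rigid":
            cx, cy = curl_center
            rot = np.column_stack([X[:, 1] - cy, -(X[:, 0] - cx)])
        else:
            raise ValueError(f"unknown curl_mode {curl_mode!r}")
        out = -g + curl * rot
        return out[0] if np.asarray(x).ndim == 1 else out

    return F


def make_double_well_snapshots(
    barrier: float = 1.0,
    curl: float = 0.0,
    D: float = 0.05,
    times: Sequence[float] = (0, 1, 2, 3, 4, 5),
    n_per_time: int = 300,
    dt: float = 1e-3,
    seed: int = 0,
) -> SnapshotDataset:
    """Snapshot ensembles of the tilted double-well, initialized in the left
    well, integrated by fine-step Euler–Maruyama and subsampled at the
    requested times. Truth S is attached from the analytic stationary
    density only for curl-compatible fields (S = -grad(Phi)/D); V = F - D S.
    """
    rng = np.random.default_rng(seed)
    F = double_well_force(barrier, curl)
    n_traj = n_per_time
    x = np.column_stack([
        rng.normal(-1.0, 0.15, n_traj),
        rng.normal(0.0, 0.25, n_traj),
    ])
    times = np.asarray(sorted(times), float)
    coords, tl = [], []
    t_now = 0.0
    sq = np.sqrt(2.0 * D * dt)
    for t_target in times:
        n_steps = int(round((t_target - t_now) / dt))
        for _ in range(n_steps):
            x = x + F(x) * dt + sq * rng.standard_normal(x.shape)
        t_now = t_target
        coords.append(x.copy())
        tl.append(np.full(n_traj, t_target))
    X = np.vstack(coords)
    # stationary-density truth: S_ss = grad log p_ss = -grad(Phi)/D
    S = -_grad_phi(X, barrier) / D
    Fx = F(X)
    sys = AnalyticSystem(f"double_well(b={barrier},c={curl})", F, D)
    return SnapshotDataset(
        X, np.concatenate(tl), times, Fx - D * S, S, Fx, sys, seed
    )


# --- morphing contours -----------------------------------------------------

# radial Fourier amplitudes (cosine harmonics) for the two archetypes; the
# 4th harmonic flattens the spindle's side bulge and the y-squash factor
# sharpens its aspect ratio (> 3 at the spindle end)
_SPINDLE = {2: 0.65, 4: 0.25}
_BRANCHED = {2: 0.05, 5: 0.28, 7: 0.14}
_SPINDLE_Y_SQUASH = 0.75


def _radial_profile(theta: np.ndarray, progress: float) -> np.ndarray:
    r = np.ones_like(theta)
    harmonics = set(_SPINDLE) | set(_BRANCHED)
    for h in harmonics:
        a0 = _SPINDLE.get(h, 0.0)
        a1 = _BRANCHED.get(h, 0.0)
        r = r + ((1.0 - progress) * a0 + progress * a1) * np.cos(h * theta)
    return r


def make_morphing_contours(
    n_per_day: int = 50,
    days: int = 11,
    noise: float = 0.02,
    n_vertices: int = 80,
    progress_jitter: float = 0.08,
    switch_steepness: float = 10.0,
    radius: float = 30.0,
    seed: int = 0,
) -> MorphingContourDataset:
    """Star-shaped polygons morphing spindle -> branched over ``days`` days.

    The day-to-progress mapping is sigmoidal (``switch_steepness`` controls
    how sharp the mid-course switch is), emulating two metastable
    morphological phases with a rapid conversion in between rather than a
    uniform drift; each cell adds Gaussian jitter (SD ``progress_jitter``),
    clipped to [0, 1]. Vertices get radial noise proportional to ``noise``.
    Self-intersecting polygons are rejected and redrawn (the star-shaped
    construction makes this rare); the phase label is 0 for progress <= 0.5
    (spindle-like) and 1 otherwise.
    """
    if n_per_day < 5:
        raise ValueError("need at least 5 cells per day")
    from shapely.geometry import Polygon

    rng = np.random.default_rng(seed)
    # noise = 0 means "templates only": cells differ solely by rigid placement
    progress_jitter = progress_jitter if noise > 0 else 0.0

    def _base_progress(u: float) -> float:
        if switch_steepness <= 0:
            return u
        k = switch_steepness
        s = lambda z: 1.0 / (1.0 + np.exp(-z))
        return float((s(k * (u - 0.5)) - s(-k / 2)) / (s(k / 2) - s(-k / 2)))

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    cells: list[RawCell] = []
    prog_all, phase_all, day_all = [], [], []
    for day in range(days):
        for i in range(n_per_day):
            for attempt in range(20):
                prog = float(np.clip(
                    _base_progress(day / (days - 1)) + rng.normal(0, progress_jitter),
                    0, 1,
                ))
                r = _radial_profile(theta, prog)
                r = r * (1.0 + noise * rng.standard_normal(n_vertices))
                r = np.clip(r, 0.05, None) * radius
                squash = (1.0 - prog) * _SPINDLE_Y_SQUASH + prog * 1.0
                pts = np.column_stack(
                    [r * np.cos(theta), squash * r * np.sin(theta)]
                )
                # random placement + orientation, mimicking raw image frames
                ang = rng.uniform(0, 2 * np.pi)
                R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
                pts = pts @ R.T + rng.uniform(0, 500, 2)
                if noise == 0 or Polygon(pts).is_simple:
                    break
            else:
                raise ValueError("could not draw a simple polygon; lower the noise level")
            cells.append(RawCell(f"d{day:02d}_c{i:03d}", float(day), pts))
            prog_all.append(prog)
            phase_all.append(0 if prog <= 0.5 else 1)
            day_all.append(day)
    return MorphingContourDataset(
        cells,
        np.asarray(prog_all),
        np.asarray(phase_all, int),
        np.asarray(day_all, float),
        params={
            "n_per_day": n_per_day, "days": days, "noise": noise,
            "progress_jitter": progress_jitter, "seed": seed,
        },
    )
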