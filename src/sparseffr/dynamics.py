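"""Langevin simulation, landscape reconstruction, basins and flux.

The fitted force field drives an overdamped Langevin equation
x' = F(x) + sqrt(2 D) xi(t) integrated by Euler–Maruyama inside a
reflecting box padding the data extent. The steady-state density of a long
trajectory ensemble defines the landscape U = -log p_ss; its local minima
are the basins (archetypal shape modes), and the steady-state probability
flux J_ss = F p_ss - D grad(p_ss) with normalized curl flux
V_ss = J_ss / p_ss quantifies the irreversible circulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, minimum_filter

from .contours import Contour, IntraDistanceMatrix, intra_distance_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryEnsemble",
    "Landscape",
    "BasinSet",
    "FluxField",
    "simulate",
    "steady_state_landscape",
    "find_basins",
    "assign_shape_modes",
    "mean_shape",
    "flux_field",
]


@dataclass
class TrajectoryEnsemble:
    states: np.ndarray  # (n_saved, n_traj, 2) post burn-in snapshots
    dt: float
    n_steps: int
    burn_in: int
    D: float
    seed: int
    bounds: np.ndarray  # (2, 2): [[xmin, xmax], [ymin, ymax]]
    n_diverged: int = 0

    def samples(self) -> np.ndarray:
        """All retained states pooled to an (m, 2) cloud."""
        return self.states.reshape(-1, 2)


@dataclass
class Landscape:
    xs: np.ndarray  # grid centers, (nx,)
    ys: np.ndarray  # (ny,)
    p_ss: np.ndarray  # (nx, ny), sums to 1/cell_area
    U: np.ndarray  # -log p_ss
    p_floor: float = 1e-12

    @property
    def cell_area(self) -> float:
        return float((self.xs[1] - self.xs[0]) * (self.ys[1] - self.ys[0]))

    def _clip(self, pts: np.ndarray) -> np.ndarray:
        # the landscape covers the simulation's reflecting box; points are
        # clamped to the grid of cell centers rather than rejected
        pts = np.atleast_2d(np.asarray(pts, float)).copy()
        pts[:, 0] = np.clip(pts[:, 0], self.xs[0], self.xs[-1])
        pts[:, 1] = np.clip(pts[:, 1], self.ys[0], self.ys[-1])
        return pts

    def interp_U(self, pts: np.ndarray) -> np.ndarray:
        from scipy.interpolate import RegularGridInterpolator

        f = RegularGridInterpolator((self.xs, self.ys), self.U)
        return f(self._clip(pts))

    def interp_logp(self, pts: np.ndarray) -> np.ndarray:
        return -self.interp_U(pts)

    def interp_p(self, pts: np.ndarray) -> np.ndarray:
        from scipy.interpolate import RegularGridInterpolator

        f = RegularGridInterpolator((self.xs, self.ys), self.p_ss)
        return f(self._clip(pts))


@dataclass
class BasinSet:
    minima: np.ndarray  # (k, 2) basin minimum locations
    U_min: np.ndarray  # (k,) landscape value at each minimum
    labels: np.ndarray  # grid of basin ids (nx, ny), -1 outside
    merge_log: list = field(default_factory=list)
    boundary_rule: str = "steepest-descent watershed on smoothed U"

    @property
    def n_basins(self) -> int:
        return len(self.minima)


@dataclass
class FluxField:
    xs: np.ndarray
    ys: np.ndarray
    J: np.ndarray  # (nx, ny, 2) steady-state flux
    V_ss: np.ndarray  # J / p_ss
    gradU: np.ndarray  # (nx, ny, 2)
    p_ss: np.ndarray
    D: float


def simulate(
    ff,
    x0: np.ndarray,
    dt: float = 1e-3,
    n_steps: int = 20000,
    n_traj: int = 200,
    burn_in: int = 0,
    seed: int = 0,
    bounds: np.ndarray | None = None,
    pad: float = 0.2,
    save_every: int = 1,
) -> TrajectoryEnsemble:
    """Euler–Maruyama ensemble integration of x' = F(x) + sqrt(2D) noise.

    ``ff`` is a ForceField (or any callable (n,2)->(n,2) with a ``D``
    attribute — pass D via ForceField for fitted fields). ``x0`` is either an
    (n_traj, 2) array of initial states or an (m, 2) empirical cloud sampled
    with replacement. A reflecting box (data extent padded by ``pad``)
    prevents probability leak; trajectories that still diverge beyond 10x
    the domain are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    D = float(ff.D)
    x0 = np.asarray(x0, float)
    if len(x0) == n_traj:
        x = x0.copy()
    else:
        x = x0[rng.integers(0, len(x0), n_traj)]
    if bounds is None:
        lo = x0.min(axis=0)
        hi = x0.max(axis=0)
        span = np.maximum(hi - lo, 1e-6)
        bounds = np.stack([lo - pad * span, hi + pad * span], axis=1)
    bounds = np.asarray(bounds, float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    diam = float(np.linalg.norm(hi - lo))

    # stability check on the initial ensemble
    f0 = np.asarray(ff(x))
    maxF = float(np.abs(f0).max())
    if dt * maxF >= 0.1 * diam:
        raise ValueError(
            f"dt too large for field: dt*max|F| = {dt * maxF:.3g} >= 0.1*diameter"
        )

    sq = np.sqrt(2.0 * D * dt)
    saved = []
    for step in range(1, n_steps + 1):
        x = x + np.asarray(ff(x)) * dt + sq * rng.standard_normal(x.shape)
        # reflecting walls
        for d in range(2):
            over = x[:, d] > hi[d]
            under = x[:, d] < lo[d]
            x[over, d] = 2 * hi[d] - x[over, d]
            x[under, d] = 2 * lo[d] - x[under, d]
        np.clip(x, lo, hi, out=x)  # guard against double-crossings
        if step > burn_in and (step - burn_in) % save_every == 0:
            saved.append(x.copy())
    states = np.asarray(saved)

    # drop diverged trajectories (possible only with huge forces inside the box)
    finite = np.all(np.isfinite(states), axis=(0, 2))
    center = 0.5 * (lo + hi)
    within = np.all(
        np.linalg.norm(states - center, axis=2).max(axis=0) <= 10.0 * diam, axis=0
    ) if states.ndim == 3 else finite
    keep = finite & within
    n_diverged = int((~keep).sum())
    if n_diverged:
        logger.warning("simulate: dropped %d diverged trajectories", n_diverged)
        states = states[:, keep, :]
    return TrajectoryEnsemble(states, dt, n_steps, burn_in, D, seed, bounds, n_diverged)


def steady_state_landscape(
    ens: TrajectoryEnsemble,
    grid: int | tuple[int, int] = 128,
    smooth_bw: float = 1.0,
    p_floor: float = 1e-12,
    bounds: np.ndarray | None = None,
) -> Landscape:
    """U = -log p_ss from a Gaussian-smoothed, floored 2D histogram.

    ``smooth_bw`` is in grid-cell units. The histogram covers the ensemble's
    reflecting box so no mass is lost at the edges.
    """
    pts = ens.samples()
    if len(pts) < 1e4:
        logger.warning("steady_state_landscape: only %d samples", len(pts))
    nx, ny = (grid, grid) if np.isscalar(grid) else grid
    b = ens.bounds if bounds is None else np.asarray(bounds, float)
    H, xe, ye = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=(nx, ny), range=((b[0, 0], b[0, 1]), (b[1, 0], b[1, 1]))
    )
    if H.sum() == 0:
        raise ValueError("empty histogram; ensemble too small or out of bounds")
    H = gaussian_filter(H, smooth_bw)
    xs = 0.5 * (xe[:-1] + xe[1:])
    ys = 0.5 * (ye[:-1] + ye[1:])
    area = (xs[1] - xs[0]) * (ys[1] - ys[0])
    p = H / (H.sum() * area)
    p = np.maximum(p, p_floor)
    return Landscape(xs, ys, p, -np.log(p), p_floor)


def find_basins(
    land: Landscape,
    min_separation: float = 0.0,
    max_depth_merge: float = 0.5,
    smooth_bw: float = 1.0,
    p_support: float | None = None,
) -> BasinSet:
    """Local minima of (smoothed) U with separation/depth merging.

    Minima are strict 8-neighborhood minima restricted to the sampled region
    (p_ss > ``p_support``; default 1e-3 of the density peak, which excludes
    shot-noise minima in near-empty cells). Pairs closer than
    ``min_separation`` or separated
    by a ridge shallower than ``max_depth_merge`` (in U units, relative to
    the shallower minimum) are merged, keeping the deeper minimum. Labels
    come from watershed steepest-descent assignment.
    """
    from skimage.segmentation import watershed

    U = gaussian_filter(land.U, smooth_bw) if smooth_bw > 0 else land.U.copy()
    if p_support is None:
        p_support = 1e-3 * float(land.p_ss.max())
    support = land.p_ss > p_support
    is_min = (U == minimum_filter(U, size=3, mode="nearest")) & support
    # strictness: reject plateaus (equal neighbor)
    idx = np.argwhere(is_min)
    if len(idx) == 0:
        logger.warning("find_basins: no local minima found")
        return BasinSet(np.zeros((0, 2)), np.zeros(0), np.full(U.shape, -1))

    order = np.argsort(U[is_min])  # deepest first
    idx = idx[order]

    markers = np.zeros(U.shape, int)
    for k, (i, j) in enumerate(idx):
        markers[i, j] = k + 1
    labels = watershed(U, markers, mask=support) - 1  # -1 outside support

    # ridge height between adjacent basins = min U on their shared boundary
    def ridge(a: int, b: int) -> float:
        ra = labels == a
        rb = labels == b
        # boundary cells of a adjacent to b
        from scipy.ndimage import binary_dilation

        touch = binary_dilation(ra) & rb
        touch_b = binary_dilation(rb) & ra
        cells = touch | touch_b
        if not cells.any():
            return np.inf
        return float(U[cells].min())

    active = list(range(len(idx)))
    merge_log = []
    merged = True
    while merged and len(active) > 1:
        merged = False
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                pa, pb = idx[a], idx[b]
                xa = np.array([land.xs[pa[0]], land.ys[pa[1]]])
                xb = np.array([land.xs[pb[0]], land.ys[pb[1]]])
                Ua, Ub = U[tuple(pa)], U[tuple(pb)]
                shallow = max(Ua, Ub)
                r = ridge(a, b)
                close = np.linalg.norm(xa - xb) < min_separation
                low_ridge = np.isfinite(r) and (r - shallow) < max_depth_merge
                if close or low_ridge:
                    keep, drop = (a, b) if Ua <= Ub else (b, a)
                    labels[labels == drop] = keep
                    active.remove(drop)
                    merge_log.append(
                        {"kept": int(keep), "dropped": int(drop),
                         "reason": "separation" if close else "ridge"}
                    )
                    merged = True
                    break
            if merged:
                break

    # compact ids
    remap = {old: new for new, old in enumerate(active)}
    out_labels = np.full(U.shape, -1)
    for old, new in remap.items():
        out_labels[labels == old] = new
    minima = np.array(
        [[land.xs[idx[a][0]], land.ys[idx[a][1]]] for a in active]
    )
    U_min = np.array([land.U[tuple(idx[a])] for a in active])
    return BasinSet(minima, U_min, out_labels, merge_log)


def assign_shape_modes(
    coords: np.ndarray,
    basins: BasinSet,
    sigma_mode: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign cells to basins (frozen-centroid nearest assignment) with GMM
    membership posteriors.

    Returns (labels, posteriors); labels are -1 ("boundary") where the
    maximum posterior does not exceed 0.5. ``sigma_mode`` defaults to half
    the median inter-centroid distance.
    """
    if basins.n_basins < 1:
        raise ValueError("need at least one basin")
    X = np.atleast_2d(np.asarray(coords, float))
    C = basins.minima
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=-1)
    nearest = np.argmin(d2, axis=1)
    if sigma_mode is None:
        if len(C) > 1:
            from scipy.spatial.distance import pdist

            sigma_mode = 0.5 * float(np.median(pdist(C)))
        else:
            sigma_mode = 1.0
    logw = -0.5 * d2 / sigma_mode**2
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    post = w / w.sum(axis=1, keepdims=True)
    labels = nearest.copy()
    labels[post.max(axis=1) <= 0.5 + 1e-12] = -1
    return labels, post


def mean_shape(
    members: list[Contour] | list[IntraDistanceMatrix], n_points: int | None = None
) -> np.ndarray:
    """Archetypal contour of a shape mode.

    The members' intra-distance matrices are averaged element-wise and
    embedded back to the plane by classical multidimensional scaling; the
    result is a closed polyline (K, 2). Negative-eigenvalue dominance (the
    averaged matrix need not be Euclidean) triggers a warning and the top-2
    positive components are used.
    """
    if len(members) == 0:
        raise ValueError("need at least one member contour")
    mats = []
    for m in members:
        D = m.D if isinstance(m, IntraDistanceMatrix) else intra_distance_matrix(m).D
        if n_points is not None and n_points < len(D):
            sel = np.linspace(0, len(D), n_points, endpoint=False).astype(int)
            D = D[np.ix_(sel, sel)]
        mats.append(D)
    Dbar = np.mean(mats, axis=0)
    K = len(Dbar)
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (Dbar**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 0 or np.abs(evals[evals < 0]).sum() > evals[evals > 0].sum():
        logger.warning("mean_shape: negative MDS eigenvalues dominate; using top-2 positive")
    lam = np.clip(evals[:2], 0.0, None)
    return evecs[:, :2] * np.sqrt(lam)[None, :]


def flux_field(ff, land: Landscape) -> FluxField:
    """Steady-state flux J = F p_ss - D grad(p_ss) on the landscape grid
    (central differences), normalized curl flux V_ss = J / p_ss and the
    landscape gradient."""
    xs, ys, p = land.xs, land.ys, land.p_ss
    GX, GY = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    F = np.asarray(ff(pts)).reshape(len(xs), len(ys), 2)
    dpx = np.gradient(p, xs, axis=0)
    dpy = np.gradient(p, ys, axis=1)
    D = float(ff.D)
    J = np.empty((len(xs), len(ys), 2))
    J[..., 0] = F[..., 0] * p - D * dpx
    J[..., 1] = F[..., 1] * p - D * dpy
    V = J / p[..., None]
    gU = np.empty_like(J)
    gU[..., 0] = np.gradient(land.U, xs, axis=0)
    gU[..., 1] = np.gradient(land.U, ys, axis=1)
    return FluxField(xs, ys, J, V, gU, p, D)
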