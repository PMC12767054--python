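"""Cell-wise flow (first Kramers–Moyal coefficient) and state density.

The flow at cell i is the transition-probability-weighted mean displacement
per unit pseudotime over its nearest neighbors,

    V(x_i) = sum_{j in N(x_i)} That_ij (x_j - x_i) / (tau_j - tau_i),

with same-time neighbors (|dtau| < dtau_min) excluded and the retained
weights renormalized. The instantaneous state density is a maximum-entropy
Gaussian mixture: one isotropic kernel of equal weight per sample point,
covariance sigma^2 I, with sigma selected by trading mixture log-likelihood
against closeness to a fixed-bandwidth KDE reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.spatial.distance import cdist

from .embedding import Embedding
from .transitions import BlockTransition, Pseudotime

__all__ = [
    "FlowSamples",
    "DensityModel",
    "SigmaSelection",
    "ScoreSamples",
    "kramers_moyal_flow",
    "gmm_density",
    "select_sigma",
]


@dataclass
class FlowSamples:
    coords: np.ndarray  # (N, 2)
    V: np.ndarray  # (N, 2), embedding units / day
    neighbor_sets: list[np.ndarray]
    no_neighbor_flag: np.ndarray  # True where every neighbor was filtered out


@dataclass
class ScoreSamples:
    coords: np.ndarray
    S: np.ndarray  # (N, 2), 1 / embedding unit


@dataclass
class DensityModel:
    """Equal-weight isotropic GMM centered at the sample points."""

    means: np.ndarray  # (N, 2)
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.means = np.asarray(self.means, float)

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        """log p at points x (m, 2); log-sum-exp keeps far tails finite."""
        x = np.atleast_2d(np.asarray(x, float))
        d2 = cdist(x, self.means, "sqeuclidean")
        s2 = self.sigma**2
        return logsumexp(-0.5 * d2 / s2, axis=1) - np.log(
            len(self.means) * 2.0 * np.pi * s2
        )

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_pdf(x))

    def score(self, x: np.ndarray) -> np.ndarray:
        """S(x) = grad log p(x) via posterior responsibilities.

        score(x) = sum_n w_n(x) (mu_n - x) / sigma^2 with w_n the
        responsibility of component n; computed in log space so that p(x)
        underflow never produces a non-finite score.
        """
        x = np.asarray(x, float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        d2 = cdist(X, self.means, "sqeuclidean")
        s2 = self.sigma**2
        logw = -0.5 * d2 / s2
        logw -= logsumexp(logw, axis=1, keepdims=True)
        w = np.exp(logw)
        S = (w @ self.means - X) / s2
        return S[0] if single else S


@dataclass
class SigmaSelection:
    grid: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    C1_hat: np.ndarray
    C2_hat: np.ndarray
    C: np.ndarray
    sigma_opt: float


def kramers_moyal_flow(
    emb: Embedding,
    bt: BlockTransition,
    tau: Pseudotime,
    k_neighbors: int = 30,
    dtau_min: float = 0.05,
) -> FlowSamples:
    """First Kramers–Moyal coefficient from the OT-informed Markov chain.

    The neighborhood N(x_i) is the support of row i of the transition
    matrix: the ``k_neighbors`` cells with the largest transition
    probability from cell i (morphological similarity within the time
    point, optimal-transport correspondence across time points). Neighbors
    with |tau_j - tau_i| < dtau_min are excluded — they would divide a
    within-cloud displacement by a vanishing time difference — and the
    retained weights are renormalized. Cells whose neighbors are all
    filtered out get V = 0 and a flag.
    """
    X = emb.coords
    t = tau.tau
    N = len(X)
    V = np.zeros((N, 2))
    flags = np.zeros(N, bool)
    neighbor_sets: list[np.ndarray] = []
    T = bt.T_hat
    k = min(k_neighbors, N - 1)
    for i in range(N):
        row = T[i]
        js = np.flatnonzero(row)
        if len(js) > k:
            js = js[np.argsort(row[js])[::-1][:k]]
        dtau = t[js] - t[i]
        keep = (np.abs(dtau) >= dtau_min) & (js != i)
        js, dtau = js[keep], dtau[keep]
        w = row[js]
        tot = w.sum()
        neighbor_sets.append(js)
        if len(js) == 0 or tot <= 0:
            flags[i] = True
            continue
        w = w / tot
        V[i] = ((X[js] - X[i]) / dtau[:, None] * w[:, None]).sum(axis=0)
    return FlowSamples(X, V, neighbor_sets, flags)


def gmm_density(coords: np.ndarray, sigma: float) -> DensityModel:
    """Maximum-entropy GMM: one equal-weight kernel per sample point."""
    return DensityModel(np.asarray(coords, float), float(sigma))


def _kl_on_grid(logp: np.ndarray, logq: np.ndarray, w: np.ndarray) -> float:
    """KL(p || q) by quadrature: weights w are cell areas times p-normalizer."""
    p = np.exp(logp)
    z = np.sum(p * w)
    p = p / z
    return float(np.sum(p * w * (logp - np.log(z) - logq)))


def select_sigma(
    coords: np.ndarray,
    grid: np.ndarray | None = None,
    kde_bandwidth: float | None = None,
    region_labels: np.ndarray | None = None,
    quad_res: int = 128,
) -> SigmaSelection:
    """Bandwidth selection for the maximum-entropy GMM.

    C1(sigma) sums, over regions, the KL divergence of the GMM from a
    fixed-bandwidth KDE reference evaluated by grid quadrature (smoothness
    penalty; the default is a single global region). C2(sigma) is the total
    leave-one-out GMM log-likelihood of the data — each point is scored by
    the mixture of the other N-1 kernels, the standard cross-validated
    bandwidth criterion (scoring a point by a kernel centered on itself
    diverges as sigma -> 0 and would make the selection degenerate). Both
    are min-max normalized to [0, 1] and sigma maximizes
    C = C2_hat - C1_hat; ties break toward the smaller sigma.
    """
    X = np.asarray(coords, float)
    if kde_bandwidth is None:
        # Scott's rule for the 2D reference KDE
        kde_bandwidth = float(len(X) ** (-1.0 / 6.0) * X.std(axis=0).mean())
    if grid is None:
        grid = np.geomspace(0.004, 0.19, 24)
    grid = np.asarray(grid, float)
    if len(grid) < 10:
        raise ValueError("sigma grid needs at least 10 values")
    if grid.min() <= 0.002 or grid.max() >= 0.2:
        raise ValueError("sigma grid must lie inside (0.002, 0.2)")

    # quadrature lattice covering the data +/- 3 reference bandwidths
    lo = X.min(axis=0) - 3 * kde_bandwidth
    hi = X.max(axis=0) + 3 * kde_bandwidth
    gx = np.linspace(lo[0], hi[0], quad_res)
    gy = np.linspace(lo[1], hi[1], quad_res)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    nodes = np.column_stack([GX.ravel(), GY.ravel()])
    area = (gx[1] - gx[0]) * (gy[1] - gy[0])

    kde = DensityModel(X, kde_bandwidth)
    log_kde = kde.log_pdf(nodes)

    if region_labels is None:
        regions = [np.arange(len(nodes))]
    else:
        # region of a quadrature node = region of its nearest sample
        lab = np.asarray(region_labels)
        nearest = np.argmin(cdist(nodes, X, "sqeuclidean"), axis=1)
        node_lab = lab[nearest]
        regions = [np.flatnonzero(node_lab == r) for r in np.unique(lab)]

    N = len(X)
    d2_self = cdist(X, X, "sqeuclidean")
    np.fill_diagonal(d2_self, np.inf)  # leave-one-out
    # exact duplicates act as a point's own kernel and would re-introduce
    # the sigma -> 0 divergence; leave identical twins out as well
    d2_self[d2_self <= 1e-24] = np.inf

    C1 = np.empty(len(grid))
    C2 = np.empty(len(grid))
    for k, s in enumerate(grid):
        gmm = DensityModel(X, s)
        log_g = gmm.log_pdf(nodes)
        kl = 0.0
        for idx in regions:
            w = np.full(len(idx), area)
            kl += _kl_on_grid(log_g[idx], log_kde[idx], w)
        C1[k] = kl
        loo = logsumexp(-0.5 * d2_self / s**2, axis=1) - np.log(
            (N - 1) * 2.0 * np.pi * s**2
        )
        C2[k] = float(loo.sum())

    def _minmax(v):
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    # C1 is a *smoothness penalty*: large KL = far from the smooth reference.
    C1_hat = _minmax(C1)
    C2_hat = _minmax(C2)
    C = C2_hat - C1_hat
    best = int(np.flatnonzero(C >= C.max() - 1e-12)[0])  # tie -> smaller sigma
    return SigmaSelection(grid, C1, C2, C1_hat, C2_hat, C, float(grid[best]))
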