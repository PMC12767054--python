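"""Static figures for the reconstructed landscape and force field."""

from __future__ import annotations

import numpy as np

from .dynamics import BasinSet, FluxField, Landscape

__all__ = ["plot_landscape", "plot_force_field", "plot_embedding"]


def plot_landscape(
    land: Landscape,
    basins: BasinSet | None = None,
    flux: FluxField | None = None,
    u_max: float | None = None,
    ax=None,
):
    """Filled-contour landscape U = -log p_ss, with optional basin markers
    and normalized curl-flux arrows. Cells with U above ``u_max`` (default:
    the 90th percentile of the sampled region) are masked, matching the
    convention of showing only the attractive region."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    U = land.U.copy()
    sampled = land.p_ss > 1e-3 * land.p_ss.max()
    if u_max is None:
        u_max = float(np.quantile(U[sampled], 0.9)) if sampled.any() else U.max()
    Um = np.ma.masked_where(U > u_max, U)
    GX, GY = np.meshgrid(land.xs, land.ys, indexing="ij")
    im = ax.contourf(GX, GY, Um, levels=24, cmap="viridis")
    plt.colorbar(im, ax=ax, label="U = -log p_ss")
    if flux is not None:
        step = max(1, len(land.xs) // 24)
        sl = (slice(None, None, step),) * 2
        mask = sampled[sl]
        ax.quiver(GX[sl][mask], GY[sl][mask],
                  flux.V_ss[sl][..., 0][mask], flux.V_ss[sl][..., 1][mask],
                  color="orange", width=0.003, label="curl flux")
    if basins is not None and basins.n_basins:
        ax.plot(basins.minima[:, 0], basins.minima[:, 1], "r*",
                markersize=12, label="basins")
        ax.legend(loc="upper right")
    ax.set_xlabel("u1")
    ax.set_ylabel("u2")
    return ax


def plot_force_field(ff, bounds: np.ndarray, n: int = 24, ax=None, D=None):
    """Streamline plot of the force field F = V + D S over a box."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    if D is not None:
        ff = ff.with_D(D)
    b = np.asarray(bounds, float)
    xs = np.linspace(b[0, 0], b[0, 1], n)
    ys = np.linspace(b[1, 0], b[1, 1], n)
    GX, GY = np.meshgrid(xs, ys)  # streamplot wants xy indexing
    F = np.asarray(ff(np.column_stack([GX.ravel(), GY.ravel()])))
    U = F[:, 0].reshape(GX.shape)
    V = F[:, 1].reshape(GY.shape)
    speed = np.hypot(U, V)
    ax.streamplot(GX, GY, U, V, color=speed, cmap="magma",
                  linewidth=1.0 + 1.5 * speed / (speed.max() + 1e-12))
    ax.set_xlabel("u1")
    ax.set_ylabel("u2")
    return ax


def plot_embedding(coords, values, label="time (d)", ax=None):
    """Scatter of the 2D embedding colored by a per-cell quantity
    (recording time, pseudotime, basin label, ...)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=values, s=8, cmap="plasma")
    plt.colorbar(sc, ax=ax, label=label)
    ax.set_xlabel("u1")
    ax.set_ylabel("u2")
    return ax
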