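"""Least-action paths, barriers, first-passage times, accumulated flux and
entropy production, plus the diffusion-coefficient scan.

In the small-noise limit the most probable transition path between basins
minimizes the action S = (1/2) int ||x' - F(x)||^2 / D dt (Freidlin–
Wentzell; the 1/(4D) rate-functional convention is flag-selectable — the
two differ by a constant factor and share the same minimizer). Barriers are
read off the landscape along the optimized path; MFPTs are estimated by
direct Langevin simulation with capture at the target basin; the
accumulated flux integrates the steady-state flux along the path; and the
entropy production rate is the flux-weighted thermodynamic force integral
with k_B T identified with D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .dynamics import (
    BasinSet,
    FluxField,
    Landscape,
    find_basins,
    flux_field,
    simulate,
    steady_state_landscape,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ActionPath",
    "ThermoSummary",
    "path_action",
    "least_action_path",
    "barrier_heights",
    "mfpt",
    "accumulated_flux",
    "entropy_production_rate",
    "epr_trajectory",
    "diffusion_scan",
]


@dataclass
class ActionPath:
    nodes: np.ndarray  # (P, 2)
    total_time: float
    action: float
    converged: bool = True
    endpoints: tuple[int, int] | None = None
    convention: str = "half"  # 1/(2D) prefactor; "fw" uses 1/(4D)


@dataclass
class ThermoSummary:
    D: float
    barrier_fwd: float
    barrier_bwd: float
    mfpt: float
    mfpt_sem: float
    flux_accum: float
    epr: float
    n_basins: int
    seed: int
    mfpt_reliable: bool = True


def _action_prefactor(D: float, convention: str) -> float:
    if convention == "half":
        return 1.0 / (2.0 * D)
    if convention == "fw":
        return 1.0 / (4.0 * D)
    raise ValueError(f"unknown action convention {convention!r}")


def path_action(ff, nodes: np.ndarray, total_time: float, convention: str = "half") -> float:
    """Discretized action of a path: pre * sum_k ||dx/dt - F(x_k)||^2 dt."""
    nodes = np.asarray(nodes, float)
    P = len(nodes)
    dt = total_time / (P - 1)
    vel = np.diff(nodes, axis=0) / dt
    Fk = np.asarray(ff(nodes[:-1]))
    res = vel - Fk
    pre = _action_prefactor(ff.D, convention)
    return pre * float(np.sum(res**2)) * dt


def _action_and_grad(ff, flat, x_a, x_b, P, dt, pre):
    """Action and gradient w.r.t. interior nodes; dt scalar or (P-1,) array."""
    interior = flat.reshape(P - 2, 2)
    nodes = np.vstack([x_a, interior, x_b])
    dtv = np.broadcast_to(np.asarray(dt, float), (P - 1,))
    vel = np.diff(nodes, axis=0) / dtv[:, None]
    Fk = np.asarray(ff(nodes[:-1]))
    r = vel - Fk  # (P-1, 2)
    S = pre * float(np.sum(np.sum(r**2, axis=1) * dtv))
    # dS/dx_k for interior k (1..P-2):
    #   from segment k-1: +2 pre r_{k-1}
    #   from segment k:   -2 pre r_k - 2 pre dt_k J_F(x_k)^T r_k
    grad = np.zeros((P - 2, 2))
    grad += 2.0 * pre * r[:-1]
    grad -= 2.0 * pre * r[1:]
    for i in range(P - 2):
        Jk = ff.jacobian(nodes[i + 1])
        grad[i] -= 2.0 * pre * dtv[i + 1] * (Jk.T @ r[i + 1])
    return S, grad.ravel()


def _speed_matched_dt(ff, nodes: np.ndarray, f_floor_frac: float = 0.05) -> np.ndarray:
    """Per-segment durations with |dx/dt| = ||F||.

    At the zero-noise optimum the path moves at the local deterministic
    speed; matching it removes the uniform-step bias near fixed points
    (where passage time diverges). ||F|| is floored at a fraction of its
    max along the path to keep durations finite.
    """
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    Fm = np.linalg.norm(np.asarray(ff(mid)), axis=1)
    floor = f_floor_frac * max(Fm.max(), 1e-12)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    return seg / np.maximum(Fm, floor)


def _reparam_arclength(nodes: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return nodes
    s = np.linspace(0, cum[-1], len(nodes))
    return np.column_stack([np.interp(s, cum, nodes[:, 0]), np.interp(s, cum, nodes[:, 1])])


def least_action_path(
    ff,
    x_a: np.ndarray,
    x_b: np.ndarray,
    P: int = 40,
    time_grid: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    convention: str = "half",
    n_rounds: int = 4,
) -> ActionPath:
    """Minimum-action path between two fixed endpoints.

    Stage 1: for each candidate transition time T, the interior nodes of a
    straight-line-initialized discrete path are optimized by L-BFGS with
    the analytic action gradient (uniform time steps), re-spacing nodes to
    uniform arc length between rounds. Stage 2: starting from the best
    (path, T) pair, time steps are re-matched to the local deterministic
    speed |dx/dt| = ||F|| and the geometry re-optimized, which removes the
    uniform-step bias near fixed points where the passage time diverges.
    The returned total_time is the sum of the matched segment durations.
    """
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    if np.allclose(x_a, x_b):
        raise ValueError("endpoints must differ")
    pre = _action_prefactor(ff.D, convention)
    if time_grid is None:
        time_grid = np.geomspace(1.0, 100.0, 7)

    def _optimize(nodes, dt):
        res = minimize(
            lambda f: _action_and_grad(ff, f, x_a, x_b, P, dt, pre),
            nodes[1:-1].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol},
        )
        return np.vstack([x_a, res.x.reshape(P - 2, 2), x_b])

    best: ActionPath | None = None
    for T in time_grid:
        dt = T / (P - 1)
        nodes = np.linspace(0, 1, P)[:, None] * (x_b - x_a)[None, :] + x_a[None, :]
        S_prev = path_action(ff, nodes, T, convention)
        converged = False
        for _ in range(n_rounds):
            nodes = _reparam_arclength(_optimize(nodes, dt))
            S_now, _ = _action_and_grad(ff, nodes[1:-1].ravel(), x_a, x_b, P, dt, pre)
            if abs(S_prev - S_now) <= tol * max(abs(S_prev), 1.0):
                converged = True
                S_prev = S_now
                break
            S_prev = S_now
        cand = ActionPath(nodes, float(T), S_prev, converged, convention=convention)
        if best is None or cand.action < best.action:
            best = cand

    # stage 2: speed-matched time steps, geometry-only refinement
    nodes = best.nodes
    S_prev = best.action
    converged = best.converged
    for _ in range(max(2, n_rounds)):
        dtv = _speed_matched_dt(ff, nodes)
        nodes = _reparam_arclength(_optimize(nodes, dtv))
        dtv = _speed_matched_dt(ff, nodes)
        S_now, _ = _action_and_grad(ff, nodes[1:-1].ravel(), x_a, x_b, P, dtv, pre)
        if abs(S_prev - S_now) <= tol * max(abs(S_prev), 1.0):
            converged = True
            S_prev = S_now
            break
        S_prev = S_now
    if S_prev <= best.action:
        best = ActionPath(nodes, float(np.sum(_speed_matched_dt(ff, nodes))),
                          S_prev, converged, convention=convention)
    if not best.converged:
        logger.warning("least_action_path: optimizer did not fully converge")
    return best


def barrier_heights(land: Landscape, path: ActionPath) -> dict:
    """Forward/backward barrier: max U along the (bilinearly interpolated)
    path minus U at each endpoint; reports the saddle location."""
    U_path = land.interp_U(path.nodes)
    k = int(np.argmax(U_path))
    return {
        "forward": float(U_path[k] - U_path[0]),
        "backward": float(U_path[k] - U_path[-1]),
        "saddle": path.nodes[k].copy(),
        "U_saddle": float(U_path[k]),
    }


def mfpt(
    ff,
    source: np.ndarray,
    target: np.ndarray,
    dt: float = 1e-3,
    n_traj: int = 200,
    t_max: float = 200.0,
    capture_radius: float = 0.2,
    seed: int = 0,
    bounds: np.ndarray | None = None,
) -> tuple[float, float, bool]:
    """Mean first-passage time from ``source`` to the capture ball around
    ``target`` by direct Euler–Maruyama simulation.

    Censored trajectories (not captured by ``t_max``) contribute t_max, so
    the estimate is a lower bound when censoring occurs; more than 50%
    censoring flags the result unreliable. Returns (mean, sem, reliable).
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if np.allclose(source, target):
        return 0.0, 0.0, True
    rng = np.random.default_rng(seed)
    D = float(ff.D)
    # contiguous active array; captured rows are compacted away on the fly
    xa = np.tile(source, (n_traj, 1))
    idx_act = np.arange(n_traj)
    t_hit = np.full(n_traj, np.inf)
    sq = np.sqrt(2.0 * D * dt)
    n_steps = int(np.ceil(t_max / dt))
    if bounds is not None:
        lo, hi = np.asarray(bounds, float)[:, 0], np.asarray(bounds, float)[:, 1]
    r2 = capture_radius**2
    for step in range(1, n_steps + 1):
        if len(idx_act) == 0:
            break
        xa = xa + np.asarray(ff(xa)) * dt + sq * rng.standard_normal(xa.shape)
        if bounds is not None:
            np.maximum(xa, 2 * lo - xa, out=xa)  # lower reflecting wall
            np.minimum(xa, 2 * hi - xa, out=xa)  # upper reflecting wall
            np.clip(xa, lo, hi, out=xa)  # guard against double-crossings
        captured = np.sum((xa - target) ** 2, axis=1) <= r2
        if captured.any():
            t_hit[idx_act[captured]] = step * dt
            keep = ~captured
            xa = xa[keep]
            idx_act = idx_act[keep]
    censored = ~np.isfinite(t_hit)
    frac_cens = censored.mean()
    t_hit[censored] = t_max
    reliable = frac_cens <= 0.5
    if not reliable:
        logger.warning("mfpt: %.0f%% trajectories censored at t_max", 100 * frac_cens)
    return float(t_hit.mean()), float(t_hit.std(ddof=1) / np.sqrt(n_traj)), reliable


def accumulated_flux(
    ff, land: Landscape, path: ActionPath, D: float | None = None
) -> float:
    """Path flux along the least-action path:

    Jhat = int F p_ss . dl  -  D (log p_ss(x_b) - log p_ss(x_a)),
    midpoint rule on the path segments.
    """
    D = float(ff.D) if D is None else float(D)
    nodes = path.nodes
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    dl = np.diff(nodes, axis=0)
    Fm = np.asarray(ff(mid))
    p_mid = land.interp_p(mid)
    line = float(np.sum(np.sum(Fm * dl, axis=1) * p_mid))
    logp = land.interp_logp(np.vstack([nodes[0], nodes[-1]]))
    if np.any(np.exp(logp) <= land.p_floor * 1.001):
        logger.warning("accumulated_flux: endpoint density at floor; log term unreliable")
    return line - D * float(logp[1] - logp[0])


def entropy_production_rate(
    ff, land: Landscape, flux: FluxField | None = None, p_min: float = 1e-6
) -> float:
    """EPR = int (F - D grad log p_ss) . J_ss dx over the sampled region
    (p_ss > p_min), with k_B T = D. Equals int ||V_ss||^2 p_ss dx at steady
    state."""
    if flux is None:
        flux = flux_field(ff, land)
    D = float(ff.D)
    p = flux.p_ss
    mask = p > p_min
    xs, ys = flux.xs, flux.ys
    GX, GY = np.meshgrid(xs, ys, indexing="ij")
    F = np.asarray(ff(np.column_stack([GX.ravel(), GY.ravel()]))).reshape(p.shape + (2,))
    # grad log p_ss = -grad U, so the thermodynamic force is F + D grad U
    integrand = np.sum((F + D * flux.gradU) * flux.J, axis=-1)
    area = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return float(np.sum(integrand[mask]) * area)


def epr_trajectory(
    ff,
    x0: np.ndarray,
    dt: float = 1e-3,
    n_steps: int = 50000,
    n_traj: int = 200,
    burn_in: int = 5000,
    seed: int = 0,
    bounds: np.ndarray | None = None,
) -> float:
    """Low-variance Monte-Carlo EPR: time-averaged Stratonovich heat.

    At steady state EPR = int F . J dx = <F o dx>/dt; the midpoint
    (Stratonovich) increment telescopes to a boundary term for gradient
    fields, so the estimator is near-exactly zero under detailed balance —
    unlike the gridded estimator, whose histogram shot noise enters
    quadratically. Integrates its own ensemble (same Euler–Maruyama scheme
    and reflecting box as :func:`sparseffr.dynamics.simulate`).
    """
    rng = np.random.default_rng(seed)
    D = float(ff.D)
    x0 = np.asarray(x0, float)
    x = x0[rng.integers(0, len(x0), n_traj)] if len(x0) != n_traj else x0.copy()
    if bounds is None:
        lo = x0.min(axis=0) - 0.2 * (x0.max(axis=0) - x0.min(axis=0))
        hi = x0.max(axis=0) + 0.2 * (x0.max(axis=0) - x0.min(axis=0))
    else:
        b = np.asarray(bounds, float)
        lo, hi = b[:, 0], b[:, 1]
    sq = np.sqrt(2.0 * D * dt)
    heat = 0.0
    F_prev = np.asarray(ff(x))
    for step in range(1, n_steps + 1):
        x_new = x + F_prev * dt + sq * rng.standard_normal(x.shape)
        for d in range(2):
            over = x_new[:, d] > hi[d]
            under = x_new[:, d] < lo[d]
            x_new[over, d] = 2 * hi[d] - x_new[over, d]
            x_new[under, d] = 2 * lo[d] - x_new[under, d]
        np.clip(x_new, lo, hi, out=x_new)
        F_new = np.asarray(ff(x_new))
        if step > burn_in:
            heat += float(np.sum(0.5 * (F_prev + F_new) * (x_new - x)))
        x, F_prev = x_new, F_new
    T_total = (n_steps - burn_in) * dt * n_traj
    return heat / T_total


def diffusion_scan(
    ff,
    D_list,
    x0: np.ndarray,
    sim_kwargs: dict | None = None,
    land_kwargs: dict | None = None,
    basin_kwargs: dict | None = None,
    mfpt_kwargs: dict | None = None,
    path_kwargs: dict | None = None,
    seed: int = 0,
    share_path: bool = True,
) -> tuple[list[ThermoSummary], dict]:
    """Re-run simulation, landscape, basins, path, barrier, MFPT, flux and
    EPR for each diffusion coefficient; report per-D summaries and Spearman
    trend signs across D.

    ``ff`` must expose ``with_D`` (ForceField does); the source/target pair
    is the deepest two basins found at each D. Because the action functional
    scales as 1/D for a fixed field, its minimizing path is the same at
    every D; the path is therefore optimized once (``share_path=True``,
    default) and reused, which removes optimizer jitter from the cross-D
    comparisons of barrier and accumulated flux.
    """
    sim_kwargs = {**dict(dt=2e-3, n_steps=40000, n_traj=300, burn_in=2000), **(sim_kwargs or {})}
    land_kwargs = {**dict(grid=96), **(land_kwargs or {})}
    basin_kwargs = {**dict(max_depth_merge=0.3), **(basin_kwargs or {})}
    mfpt_kwargs = {**dict(dt=2e-3, n_traj=150, t_max=300.0, capture_radius=0.25),
                   **(mfpt_kwargs or {})}
    path_kwargs = {**dict(P=30), **(path_kwargs or {})}

    summaries: list[ThermoSummary] = []
    shared_path: ActionPath | None = None
    for k, D in enumerate(D_list):
        ffD = ff.with_D(float(D))
        try:
            ens = simulate(ffD, x0, seed=seed + k, **sim_kwargs)
            land = steady_state_landscape(ens, **land_kwargs)
            basins = find_basins(land, **basin_kwargs)
            if basins.n_basins < 2:
                raise RuntimeError(f"only {basins.n_basins} basin(s) at D={D}")
            order = np.argsort(basins.U_min)
            src, tgt = basins.minima[order[0]], basins.minima[order[1]]
            if share_path and shared_path is not None:
                # same endpoints up to grid snap: rescale the stored action
                path = ActionPath(shared_path.nodes, shared_path.total_time,
                                  shared_path.action
                                  * (D_list[0] / D), shared_path.converged,
                                  convention=shared_path.convention)
                src, tgt = path.nodes[0], path.nodes[-1]
            else:
                path = least_action_path(ffD, src, tgt, **path_kwargs)
                if share_path:
                    shared_path = path
            bar = barrier_heights(land, path)
            m, sem, ok = mfpt(ffD, src, tgt, seed=seed + 1000 + k,
                              bounds=ens.bounds, **mfpt_kwargs)
            fl = flux_field(ffD, land)
            jhat = accumulated_flux(ffD, land, path)
            epr = entropy_production_rate(ffD, land, fl)
            summaries.append(
                ThermoSummary(float(D), bar["forward"], bar["backward"], m, sem,
                              jhat, epr, basins.n_basins, seed + k, ok)
            )
        except Exception as exc:  # pragma: no cover - partial results path
            logger.error("diffusion_scan failed at D=%s: %s", D, exc)
            summaries.append(
                ThermoSummary(float(D), np.nan, np.nan, np.nan, np.nan,
                              np.nan, np.nan, 0, seed + k, False)
            )
    trends: dict = {}
    good = [s for s in summaries if np.isfinite(s.barrier_fwd)]
    if len(good) >= 3:
        Ds = np.array([s.D for s in good])
        trends = {
            "barrier_vs_D": float(spearmanr(Ds, [s.barrier_fwd for s in good]).statistic),
            "log_mfpt_vs_barrier": float(
                spearmanr([s.barrier_fwd for s in good],
                          np.log([s.mfpt for s in good])).statistic
            ),
            "flux_vs_D": float(spearmanr(Ds, [abs(s.flux_accum) for s in good]).statistic),
            "epr_vs_D": float(spearmanr(Ds, [s.epr for s in good]).statistic),
        }
    return summaries, trends
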