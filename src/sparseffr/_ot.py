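"""Optimal-transport primitives: Sinkhorn, exact LAP transport, and
Gromov–Wasserstein solvers (conditional-gradient and entropic-projection).

Couplings live on the polytope C(a, b) = {T >= 0 : T 1 = a, T^T 1 = b}.
The GW objective for cost matrices D1 (n x n) and D2 (m x m) is the
quadratic form

    E(T) = 1/2 * sum_{ijkl} L(D1_ij, D2_kl) T_ik T_jl

with L either the absolute difference ("abs") or the squared difference
("sq").
For the square loss the tensor contraction factorizes (Peyre et al. 2016):
    (L x T)_ik = c1_i + c2_k - 2 (D1 T D2^T)_ik
keeping every gradient at O(n^2 m). The absolute loss has no such
factorization; its contraction is evaluated blockwise (O(n^2 m^2)), with a
sparse-support shortcut when the coupling is (near-)permutation sparse.
Because E is quadratic in T for any fixed loss, the Frank–Wolfe line search
is exact: one extra tensor application per iteration.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
from scipy.optimize import linear_sum_assignment

Loss = Literal["abs", "sq"]


def sinkhorn(
    a: np.ndarray,
    b: np.ndarray,
    C: np.ndarray,
    eps: float,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> np.ndarray:
    """Entropic OT plan via log-domain Sinkhorn iterations.

    Returns the (len(a), len(b)) coupling with marginals a, b. Raises
    RuntimeError when the marginal violation stays above 1e-6 (a looser eps
    usually fixes it).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    negC = -np.asarray(C, float)
    g = np.zeros(len(b))
    f = np.zeros(len(a))
    loga = np.log(a)
    logb = np.log(b)
    # epsilon-scaling: anneal from a loose regularization down to the target,
    # warm-starting the potentials — Sinkhorn alone converges very slowly for
    # small eps relative to the cost scale
    scale = float(np.abs(negC).max()) or 1.0
    eps_levels = []
    e = max(eps, 0.1 * scale)
    while e > eps * 1.001:
        eps_levels.append(e)
        e /= 3.0
    eps_levels.append(eps)
    T = np.outer(a, b)
    err = np.inf
    for lvl, e in enumerate(eps_levels):
        iters = 50 if lvl < len(eps_levels) - 1 else max_iter
        for it in range(iters):
            f = e * (loga - _logsumexp_rows((negC + g[None, :]) / e))
            g = e * (logb - _logsumexp_rows((negC.T + f[None, :]) / e))
            if lvl == len(eps_levels) - 1 and (it % 5 == 4 or it == iters - 1):
                T = np.exp((negC + f[:, None] + g[None, :]) / e)
                err = np.abs(T.sum(axis=1) - a).max()
                if err < tol:
                    break
    if err > 1e-5:
        raise RuntimeError(
            f"sinkhorn did not converge (marginal error {err:.2e}); try larger eps"
        )
    return T


def _logsumexp_rows(M: np.ndarray) -> np.ndarray:
    mx = M.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(M - mx).sum(axis=1, keepdims=True))).ravel()


def exact_ot(a: np.ndarray, b: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Exact OT for uniform equal-size marginals via linear assignment."""
    n, m = C.shape
    if n != m:
        raise ValueError("exact_ot requires square cost (equal-size supports)")
    r, c = linear_sum_assignment(C)
    T = np.zeros_like(C, dtype=float)
    T[r, c] = a[r]
    return T


# --- GW quadratic form ------------------------------------------------------


def _apply_sq(D1, D2, T):
    """(L x T) for the square loss, factorized."""
    c1 = (D1**2) @ T.sum(axis=1)
    c2 = (D2**2) @ T.sum(axis=0)
    return c1[:, None] + c2[None, :] - 2.0 * D1 @ T @ D2.T


def _apply_abs(D1, D2, T):
    """(L x T)_ik = sum_{jl} |D1_ij - D2_kl| T_jl, blockwise dense."""
    n, m = T.shape
    out = np.empty((n, m))
    block = max(1, int(2e7 // (n * m * m)) or 1)
    for s in range(0, n, block):
        e = min(n, s + block)
        diff = np.abs(D1[s:e, :, None, None] - D2[None, None, :, :])  # (b, n, m, m)
        out[s:e] = np.einsum("ijkl,jl->ik", diff, T)
    return out


def _apply(D1, D2, T, loss: Loss):
    return _apply_sq(D1, D2, T) if loss == "sq" else _apply_abs(D1, D2, T)


def _energy_sparse(D1, D2, T, loss: Loss) -> float:
    """E(T) over the support of T only: O(nnz^2). Exact for any T."""
    i, k = np.nonzero(T)
    w = T[i, k]
    diff = D1[np.ix_(i, i)] - D2[np.ix_(k, k)]
    diff = np.abs(diff) if loss == "abs" else diff**2
    return 0.5 * float(w @ diff @ w)


def gw_energy(D1, D2, T, loss: Loss = "abs") -> float:
    """GW objective 1/2 <L(D1,D2) x T, T> at coupling T."""
    nnz = int(np.count_nonzero(T))
    if nnz * nnz <= 4 * len(D1) ** 2 * len(D2):
        return _energy_sparse(D1, D2, T, loss)
    return 0.5 * float(np.sum(_apply(D1, D2, T, loss) * T))


def _perm_energy(D1, D2, perm, loss: Loss) -> float:
    """Energy of the permutation coupling P_perm / n (uniform weights)."""
    n = len(D1)
    diff = D1 - D2[np.ix_(perm, perm)]
    diff = np.abs(diff) if loss == "abs" else diff**2
    return 0.5 * float(diff.sum()) / n**2


def _best_cyclic(D1, D2, loss: Loss):
    """Best cyclic-shift / reversed-cyclic permutation coupling.

    Closed contours sampled equidistantly admit a natural family of
    candidate correspondences: rotations of the sample index and their
    orientation reversal. For the square loss all 2K candidates are scored
    at once by 2D circular cross-correlation (FFT, O(K^2 log K)); the abs
    loss falls back to the direct O(K^3) scan. The scan returns the exact
    optimum (zero energy) for any rigidly transformed copy.
    """
    n = len(D1)
    base = np.arange(n)
    if loss == "sq":
        FA = np.conj(np.fft.fft2(D1))
        const = float((D1**2).sum() + (D2**2).sum())
        best_e, best_perm = np.inf, base
        for rev in (False, True):
            B = np.roll(D2[::-1, ::-1], 1, axis=(0, 1)) if rev else D2
            C = np.real(np.fft.ifft2(FA * np.fft.fft2(B)))
            diag = np.einsum("ss->s", C)
            d = int(np.argmax(diag))
            e = 0.5 * (const - 2.0 * diag[d]) / n**2
            perm = ((-d) - base) % n if rev else (base + d) % n
            if e < best_e:
                best_e, best_perm = e, perm
        return best_e, _perm_coupling(best_perm)
    best_e, best_perm = np.inf, base
    Brev = np.roll(D2[::-1, ::-1], 1, axis=(0, 1))  # index-negation of D2
    for rev in (False, True):
        for s in range(n):
            # permuted D2 equals a circular roll of D2 (or its negation)
            M = np.roll(Brev, (s, s), (0, 1)) if rev else np.roll(D2, (-s, -s), (0, 1))
            e = 0.5 * float(np.abs(D1 - M).sum()) / n**2
            if e < best_e:
                perm = ((s - base) % n) if rev else ((base + s) % n)
                best_e, best_perm = e, perm
    return best_e, _perm_coupling(best_perm)


def _perm_coupling(perm: np.ndarray) -> np.ndarray:
    n = len(perm)
    T = np.zeros((n, n))
    T[np.arange(n), perm] = 1.0 / n
    return T


def _product_energy(D1, D2, a, b, loss: Loss) -> float:
    """E at the product coupling in closed form.

    sq: moments factorize. abs: E = 1/2 E|X - Y| for X, Y the weighted
    empirical distributions of D1 and D2 entries, via the CDF identity
    E|X - Y| = int F1 (1 - F2) + F2 (1 - F1) dt on the merged sorted grid.
    """
    w1 = np.outer(a, a).ravel()
    w2 = np.outer(b, b).ravel()
    x = D1.ravel()
    y = D2.ravel()
    if loss == "sq":
        return 0.5 * (
            float(w1 @ x**2) + float(w2 @ y**2) - 2.0 * float(w1 @ x) * float(w2 @ y)
        )
    z = np.concatenate([x, y])
    order = np.argsort(z, kind="stable")
    zs = z[order]
    is_x = order < len(x)
    wz = np.where(is_x, np.concatenate([w1, np.zeros_like(w2)])[order], 0.0)
    wz2 = np.where(~is_x, np.concatenate([np.zeros_like(w1), w2])[order], 0.0)
    F1 = np.cumsum(wz)
    F2 = np.cumsum(wz2)
    dz = np.diff(zs)
    integrand = F1[:-1] * (1.0 - F2[:-1]) + F2[:-1] * (1.0 - F1[:-1])
    return 0.5 * float(np.sum(integrand * dz))


def _enumerate_perms(D1, D2, a, loss: Loss):
    """Exact scan of all permutation couplings; used for tiny instances."""
    import itertools

    n = len(D1)
    best_e, best_perm = np.inf, np.arange(n)
    for p in itertools.permutations(range(n)):
        perm = np.asarray(p)
        e = _perm_energy(D1, D2, perm, loss)
        if e < best_e:
            best_e, best_perm = e, perm
    return best_e, _perm_coupling(best_perm)


def _initial_couplings(a, b, which: str, D1=None, D2=None, loss: Loss = "abs") -> list:
    """Scored warm starts, cheapest-evaluated first: the product coupling
    (closed-form energy), the diagonal / best cyclic-shift permutation for
    equal sizes, and — for tiny instances (n = m <= 6) — the exact best
    permutation by enumeration."""
    starts: list[tuple[float, np.ndarray]] = []
    equal = len(a) == len(b) and np.allclose(a, a[0]) and np.allclose(b, b[0])
    if which in ("multi", "cyclic") and equal and D1 is not None:
        if len(a) <= 6:
            starts.append(_enumerate_perms(D1, D2, a, loss))
        elif which == "cyclic":
            starts.append(_best_cyclic(D1, D2, loss))
        else:
            Td = np.diag(a).astype(float)
            starts.append((_energy_sparse(D1, D2, Td, loss), Td))
    Tp = np.outer(a, b)
    if D1 is not None:
        starts.append((_product_energy(D1, D2, a, b, loss), Tp))
    else:
        starts.append((np.inf, Tp))
    starts.sort(key=lambda s: s[0])
    return starts


def _lap_vertex(G, a, b):
    """Linear minimization oracle over the coupling polytope.

    For uniform equal-size marginals the optimum is a scaled permutation
    (exact LAP); otherwise an entropic inner solve approximates the vertex.
    """
    n, m = G.shape
    if n == m and np.allclose(a, a[0]) and np.allclose(b, b[0]):
        r, c = linear_sum_assignment(G)
        S = np.zeros_like(G)
        S[r, c] = a[r]
        return S
    scale = max(G.max() - G.min(), 1e-30)
    return sinkhorn(a, b, (G - G.min()) / scale, eps=5e-3)


def gw_conditional_gradient(
    D1: np.ndarray,
    D2: np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    loss: Loss = "abs",
    max_iter: int = 100,
    tol: float = 1e-9,
    init: str = "multi",
) -> tuple[float, np.ndarray]:
    """Frank–Wolfe GW with exact line search on the quadratic energy.

    The problem is non-convex; we warm-start from the product coupling and
    (for equal sizes) the diagonal coupling, iterate from the better one,
    and return the lowest-energy solution seen. A warm start that already
    attains (near-)zero energy — e.g. identical distance matrices from a
    rigidly transformed contour — short-circuits the iteration.
    """
    n, m = len(D1), len(D2)
    a = np.full(n, 1.0 / n) if a is None else np.asarray(a, float)
    b = np.full(m, 1.0 / m) if b is None else np.asarray(b, float)

    scale = 0.5 * float(D1.mean() + D2.mean()) or 1.0
    e_scale = scale if loss == "abs" else scale**2

    cands = _initial_couplings(a, b, init, D1, D2, loss)
    E, T = cands[0]
    if E <= 1e-12 * e_scale:
        return E, T

    for _ in range(max_iter):
        G = _apply(D1, D2, T, loss)
        S = _lap_vertex(G, a, b)
        delta = S - T
        # E(T + t*delta) = E + b1*t + a2*t^2 exactly (quadratic form)
        b1 = float(np.sum(G * delta))
        a2 = 0.5 * float(np.sum(_apply(D1, D2, delta, loss) * delta))
        if a2 > 0:
            t_star = float(np.clip(-b1 / (2.0 * a2), 0.0, 1.0))
        else:
            t_star = 1.0 if (b1 + a2) < 0 else 0.0
        if t_star <= 0:
            break
        T = T + t_star * delta
        E_new = E + b1 * t_star + a2 * t_star**2
        if E - E_new <= tol * max(abs(E), e_scale * 1e-6):
            E = E_new
            break
        E = E_new
    # guard against drift of the incremental energy
    E = gw_energy(D1, D2, T, loss)
    return E, T


def gw_entropic(
    D1: np.ndarray,
    D2: np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    loss: Loss = "sq",
    eps: float = 5e-3,
    max_iter: int = 50,
    tol: float = 1e-7,
    init: str = "multi",
) -> tuple[float, np.ndarray]:
    """Entropic projected-gradient GW (Sinkhorn projections of the gradient).

    Returns the best iterate's unregularized energy and coupling; emits a
    warning instead of raising when the inner loop stops early.
    """
    n, m = len(D1), len(D2)
    a = np.full(n, 1.0 / n) if a is None else np.asarray(a, float)
    b = np.full(m, 1.0 / m) if b is None else np.asarray(b, float)

    scale = 0.5 * float(D1.mean() + D2.mean()) or 1.0
    e_scale = scale if loss == "abs" else scale**2
    cands = _initial_couplings(a, b, init, D1, D2, loss)
    E_prev, T = cands[0]
    if E_prev <= 1e-12 * e_scale:
        return E_prev, T

    # annealed projected gradient: start at a loose regularization (smooth,
    # near-convex landscape) and track the optimum down to the target eps
    eps_levels = list(np.geomspace(max(10 * eps, 0.05), eps, 4)) if eps < 0.05 else [eps]
    converged = False
    for lvl, e in enumerate(eps_levels):
        last_level = lvl == len(eps_levels) - 1
        for _ in range(max_iter if last_level else max(5, max_iter // 4)):
            G = _apply(D1, D2, T, loss)
            g_scale = max(G.max() - G.min(), 1e-30)
            try:
                T = sinkhorn(a, b, (G - G.min()) / g_scale, eps=e)
            except RuntimeError:
                warnings.warn("entropic GW inner Sinkhorn stalled; keeping last iterate")
                break
            E = gw_energy(D1, D2, T, loss)
            if abs(E_prev - E) <= tol * max(abs(E), e_scale * 1e-6):
                converged = last_level
                E_prev = E
                break
            E_prev = E
    if not converged:
        warnings.warn("entropic GW did not fully converge; returning last iterate")
    return gw_energy(D1, D2, T, loss), T
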