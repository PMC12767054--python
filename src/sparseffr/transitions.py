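"""Optimal-transport-informed block transition matrix and pseudotime.

Cells are partitioned into blocks by recording time. Diagonal blocks carry
within-time transition probabilities from the fuzzy kNN connectivity graph;
the first upper off-diagonal blocks carry entropic optimal-transport plans
between consecutive time points (balanced, uniform marginals — the imaged
populations show minimal proliferation). Row normalization yields a Markov
chain over all cells, from which a real-time-informed pseudotime is
computed by damped diffusion of the recording times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _ot
from .embedding import Embedding

__all__ = [
    "BlockTransition",
    "Pseudotime",
    "time_blocks",
    "intra_transition",
    "inter_transition_ot",
    "assemble_block_transition",
    "pseudotime",
    "build_block_transition",
]


@dataclass
class BlockTransition:
    """Row-stochastic Markov matrix with time-block structure."""

    T_hat: np.ndarray  # (N, N), rows sum to 1
    time_blocks: list[np.ndarray]  # index arrays, ordered by time
    block_times: np.ndarray  # representative time per block
    intra: list[np.ndarray] = field(default_factory=list)
    inter: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        rows = self.T_hat.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("T_hat rows must sum to 1 within 1e-10")
        if (self.T_hat < -1e-15).any():
            raise ValueError("T_hat entries must be nonnegative")


@dataclass
class Pseudotime:
    """Diffused, real-time-anchored ordering (days), min-shifted to 0."""

    tau: np.ndarray
    root_policy: str = "min-shift to earliest block"


def time_blocks(time_labels: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Ordered partition of cell indices by unique time label."""
    t = np.asarray(time_labels, float)
    uniq = np.unique(t)
    return [np.flatnonzero(t == u) for u in uniq], uniq


def intra_transition(connectivity: sp.spmatrix, block: np.ndarray) -> np.ndarray:
    """Row-normalized fuzzy edge weights within one time point.

    The fuzzy graph carries no self-edges; the diagonal is zeroed before
    normalization and isolated cells get a self-transition of 1.
    """
    W = np.asarray(connectivity.tocsr()[np.ix_(block, block)].todense(), float)
    np.fill_diagonal(W, 0.0)
    rows = W.sum(axis=1)
    isolated = rows <= 0
    P = np.zeros_like(W)
    P[~isolated] = W[~isolated] / rows[~isolated, None]
    P[isolated, np.flatnonzero(isolated)] = 1.0
    return P


def inter_transition_ot(
    coords_i: np.ndarray,
    coords_j: np.ndarray,
    eps: float = 0.05,
    cost: str = "sq_euclid_embedding",
    cost_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Entropic OT plan between two consecutive time blocks, row-normalized
    into conditional probabilities p(x_{t+1} | x_t).

    ``cost="gw_metric"`` uses ``cost_matrix`` (the restriction of the GW
    metric matrix) instead of squared Euclidean distance in the embedding.
    """
    ni, nj = len(coords_i), len(coords_j)
    if ni == 0 or nj == 0:
        raise ValueError("both time blocks must be nonempty")
    if cost == "sq_euclid_embedding":
        diff = coords_i[:, None, :] - coords_j[None, :, :]
        C = np.sum(diff**2, axis=-1)
    elif cost == "gw_metric":
        if cost_matrix is None:
            raise ValueError("cost='gw_metric' needs cost_matrix")
        C = np.asarray(cost_matrix, float)
    else:
        raise ValueError(f"unknown cost {cost!r}")
    scale = max(C.max(), 1e-300)
    a = np.full(ni, 1.0 / ni)
    b = np.full(nj, 1.0 / nj)
    try:
        plan = _ot.sinkhorn(a, b, C / scale, eps=eps)
    except RuntimeError as exc:
        raise RuntimeError(f"{exc}; consider increasing eps above {eps}") from exc
    return plan / plan.sum(axis=1, keepdims=True)


def assemble_block_transition(
    intra: list[np.ndarray],
    inter: list[np.ndarray],
    blocks: list[np.ndarray],
    block_times: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
) -> BlockTransition:
    """Assemble the global row-stochastic block matrix.

    Each row of a non-final block splits its mass ``w_intra`` : ``w_inter``
    between its diagonal block and its OT block, then rows are renormalized.
    The last block is intra-only. All other blocks are zero (first-order
    Markov structure in time).
    """
    w_intra, w_inter = weights
    N = sum(len(b) for b in blocks)
    if len(intra) != len(blocks) or len(inter) != len(blocks) - 1:
        raise ValueError("need one intra block per time and one inter plan per gap")
    T = np.zeros((N, N))
    for k, b in enumerate(blocks):
        if intra[k].shape != (len(b), len(b)):
            raise ValueError(f"intra block {k} has wrong shape")
        last = k == len(blocks) - 1
        wi = 1.0 if last or w_inter == 0 else w_intra
        T[np.ix_(b, b)] = wi * intra[k]
        if not last and w_inter > 0:
            nxt = blocks[k + 1]
            if inter[k].shape != (len(b), len(nxt)):
                raise ValueError(f"inter plan {k} has wrong shape")
            T[np.ix_(b, nxt)] = w_inter * inter[k]
    rows = T.sum(axis=1)
    zero = rows <= 0
    T[zero, np.flatnonzero(zero)] = 1.0
    rows = T.sum(axis=1)
    T /= rows[:, None]
    return BlockTransition(T, blocks, np.asarray(block_times, float), intra, inter)


def pseudotime(
    bt: BlockTransition,
    real_times: np.ndarray,
    n_steps: int = 50,
    damping: float = 0.5,
) -> Pseudotime:
    """Damped diffusion of recording times through the Markov chain.

    tau^(k+1) = (1 - damping) * real_times + damping * T_hat tau^(k),
    starting from the recording times, then shifted so the minimum is 0.
    """
    t = np.asarray(real_times, float)
    tau = t.copy()
    for _ in range(n_steps):
        tau = (1.0 - damping) * t + damping * (bt.T_hat @ tau)
    tau = tau - tau.min()
    return Pseudotime(tau)


def build_block_transition(
    emb: Embedding,
    eps: float = 0.05,
    weights: tuple[float, float] = (0.5, 0.5),
    cost: str = "sq_euclid_embedding",
    metric: np.ndarray | None = None,
) -> BlockTransition:
    """Full assembly from an Embedding carrying its connectivity graph."""
    if emb.connectivity is None:
        raise ValueError("embedding has no connectivity graph")
    blocks, uniq = time_blocks(emb.time_labels)
    blocks = [b for b in blocks if len(b) > 0]
    intra = [intra_transition(emb.connectivity, b) for b in blocks]
    inter = []
    for k in range(len(blocks) - 1):
        bi, bj = blocks[k], blocks[k + 1]
        cm = metric[np.ix_(bi, bj)] if (metric is not None and cost == "gw_metric") else None
        inter.append(
            inter_transition_ot(emb.coords[bi], emb.coords[bj], eps=eps, cost=cost, cost_matrix=cm)
        )
    return assemble_block_transition(intra, inter, blocks, uniq, weights)
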