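"""2D manifold embedding of the GW metric matrix.

UMAP with a precomputed metric provides both the low-dimensional
coordinates (the reduced morphological state space) and the fuzzy
topological connectivity graph reused by the transition-matrix stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gw import MetricMatrix

__all__ = ["Embedding", "embed", "connectivity_graph"]


@dataclass
class Embedding:
    """Per-cell 2D coordinates with time labels and the kNN fuzzy graph."""

    cell_ids: list[str]
    coords: np.ndarray  # (N, dim)
    time_labels: np.ndarray  # (N,)
    rng_seed: int
    connectivity: sp.csr_matrix | None = None  # symmetric fuzzy weights

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.time_labels = np.asarray(self.time_labels, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        if len(self.coords) != len(self.cell_ids) or len(self.time_labels) != len(self.cell_ids):
            raise ValueError("cell_ids, coords and time_labels must be index-aligned")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=[f"u{i+1}" for i in range(self.coords.shape[1])])
        df.insert(0, "time", self.time_labels)
        df.insert(0, "cell_id", self.cell_ids)
        return df


def embed(
    metric: MetricMatrix,
    time_labels: np.ndarray,
    n_neighbors: int = 30,
    min_dist: float = 0.5,
    dim: int = 2,
    seed: int = 0,
) -> Embedding:
    """UMAP embedding of a precomputed GW distance matrix.

    Deterministic given ``seed``; the learned fuzzy simplicial set is kept on
    the returned object so downstream stages share the same neighborhood
    topology.
    """
    import umap

    N = len(metric.cell_ids)
    if N <= n_neighbors:
        raise ValueError(f"need N > n_neighbors ({N} <= {n_neighbors})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_components=dim,
            metric="precomputed",
            random_state=seed,
        )
        coords = reducer.fit_transform(metric.M)
    graph = sp.csr_matrix(reducer.graph_)
    return Embedding(metric.cell_ids, coords, np.asarray(time_labels, float), seed, graph)


def connectivity_graph(
    coords_or_metric: np.ndarray, n_neighbors: int = 30, seed: int = 0,
    precomputed: bool = False,
) -> sp.csr_matrix:
    """Fuzzy kNN connectivity for raw 2D coordinates (mid-pipeline entry) or
    a precomputed distance matrix, matching the graph UMAP would build."""
    from umap.umap_ import fuzzy_simplicial_set

    X = np.asarray(coords_or_metric, float)
    graph, *_ = fuzzy_simplicial_set(
        X,
        n_neighbors=n_neighbors,
        random_state=np.random.RandomState(seed),
        metric="precomputed" if precomputed else "euclidean",
    )
    return sp.csr_matrix(graph)
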