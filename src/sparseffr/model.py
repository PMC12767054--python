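"""Model/results interface for sparse force-field reconstruction.

`SparseFFR` bundles the reconstruction pipeline behind a statsmodels-style
API: construct the model from data (snapshot coordinates with time labels,
or raw contours), call :meth:`fit`, and receive a :class:`SparseFFRResults`
carrying the fitted flow and score fields, the force field at the chosen
diffusion coefficient, per-stage diagnostics and a :meth:`summary` table.
Simulation, landscape reconstruction and thermodynamic scans are methods of
the results object, so one fit supports arbitrary diffusion coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from . import density, dynamics, thermo, transitions
from .contours import RawCell, process_cells
from .embedding import Embedding, connectivity_graph, embed
from .field import ForceField, SmoothField, vfc_fit
from .gw import MetricMatrix, metric_matrix

logger = logging.getLogger(__name__)

__all__ = ["SparseFFR", "SparseFFRResults"]


class SparseFFR:
    """Reconstruct the stochastic driving force of cell-state dynamics from
    time-stamped snapshots.

    Parameters
    ----------
    coords : (N, 2) array
        Low-dimensional cell-state coordinates (an embedding of the
        morphology metric, or any 2D state readout).
    times : (N,) array
        Recording time of each cell, in days.
    cell_ids : sequence of str, optional
    D : float
        Diffusion coefficient used for the returned force field
        F(x) = V(x) + D S(x) (any other value is available from the results
        without refitting).
    """

    def __init__(
        self,
        coords: np.ndarray,
        times: np.ndarray,
        cell_ids: Sequence[str] | None = None,
        D: float = 0.003,
        n_neighbors: int = 30,
        seed: int = 0,
    ) -> None:
        self.coords = np.asarray(coords, float)
        self.times = np.asarray(times, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (N, 2)")
        if len(self.coords) != len(self.times):
            raise ValueError("coords and times must be aligned")
        self.cell_ids = (
            list(cell_ids) if cell_ids is not None
            else [f"cell{i:05d}" for i in range(len(self.times))]
        )
        self.D = float(D)
        self.n_neighbors = int(n_neighbors)
        self.seed = int(seed)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_contours(
        cls,
        cells: list[RawCell],
        K: int = 150,
        gw_points: int | None = 32,
        n_neighbors: int = 30,
        min_dist: float = 0.5,
        D: float = 0.003,
        seed: int = 0,
        gw_kwargs: dict | None = None,
    ) -> "SparseFFR":
        """Full front end: resample/align contours, GW metric, UMAP embed."""
        contours = process_cells(cells, K=K)
        metric = metric_matrix(contours, n_points=gw_points, **(gw_kwargs or {}))
        emb = embed(
            metric,
            np.array([c.time_label for c in contours]),
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            seed=seed,
        )
        model = cls(emb.coords, emb.time_labels, emb.cell_ids, D=D,
                    n_neighbors=n_neighbors, seed=seed)
        model._embedding = emb
        model._metric = metric
        model._contours = contours
        return model

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, coord_cols=("u1", "u2"), time_col="time", **kwargs
    ) -> "SparseFFR":
        ids = df["cell_id"].astype(str).tolist() if "cell_id" in df.columns else None
        return cls(df[list(coord_cols)].to_numpy(float), df[time_col].to_numpy(float),
                   cell_ids=ids, **kwargs)

    _embedding: Embedding | None = None
    _metric: MetricMatrix | None = None
    _contours: list | None = None

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        sigma: float | None = None,
        sigma_grid: np.ndarray | None = None,
        score_mode: str = "analytic",
        score_time: str = "pooled",
        k_neighbors: int | None = None,
        dtau_min: float = 0.05,
        ot_eps: float = 0.05,
        weights: tuple[float, float] = (0.5, 0.5),
        pseudotime_steps: int = 50,
        pseudotime_damping: float = 0.5,
        vfc_kwargs: dict | None = None,
    ) -> "SparseFFRResults":
        """Run the reconstruction: transition matrix, pseudotime, cell-wise
        flow and score, then the robust global field fits.

        ``score_mode="analytic"`` evaluates the score directly from the GMM
        (the default); ``"fitted"`` additionally smooths it through the same
        robust kernel regression used for the flow. ``score_time="pooled"``
        fits one density to all cells (steady-snapshot approximation);
        ``"per_time"`` scores each cell against its own time point's density
        (Scott-rule bandwidth per block) — the time-dependent reading of the
        score field — and always smooths the result into a fitted S field.
        """
        emb = self._embedding
        if emb is None:
            graph = connectivity_graph(self.coords, n_neighbors=self.n_neighbors,
                                       seed=self.seed)
            emb = Embedding(self.cell_ids, self.coords, self.times, self.seed, graph)
            self._embedding = emb

        bt = transitions.build_block_transition(emb, eps=ot_eps, weights=weights)
        tau = transitions.pseudotime(bt, self.times, n_steps=pseudotime_steps,
                                     damping=pseudotime_damping)
        flow = density.kramers_moyal_flow(
            emb, bt, tau,
            k_neighbors=k_neighbors or self.n_neighbors,
            dtau_min=dtau_min,
        )

        sigma_sel = None
        if score_time == "per_time":
            # time-dependent score: each cell against its own snapshot density
            S_samples = np.zeros_like(self.coords)
            sigmas = []
            for t in np.unique(self.times):
                msk = self.times == t
                sig_t = float(msk.sum() ** (-1.0 / 6.0)
                              * self.coords[msk].std(axis=0).mean())
                sigmas.append(sig_t)
                block_gmm = density.gmm_density(self.coords[msk], sig_t)
                S_samples[msk] = block_gmm.score(self.coords[msk])
            sigma = float(np.mean(sigmas)) if sigma is None else float(sigma)
            gmm = density.gmm_density(self.coords, sigma)
        elif score_time == "pooled":
            if sigma is None:
                # sigma grid is defined on unit-scale data; rescale by spread
                span = float(np.mean(self.coords.std(axis=0)))
                sigma_sel = density.select_sigma(self.coords / span, grid=sigma_grid)
                sigma = sigma_sel.sigma_opt * span
            gmm = density.gmm_density(self.coords, sigma)
            S_samples = gmm.score(self.coords)
        else:
            raise ValueError(f"unknown score_time {score_time!r}")

        vkw = dict(seed=self.seed)
        vkw.update(vfc_kwargs or {})
        # cells with no valid flow neighbors (e.g. the final time block)
        # carry no flow observation and are left out of the field fit
        ok = ~flow.no_neighbor_flag
        V_field = vfc_fit(self.coords[ok], flow.V[ok], **vkw)
        if score_mode == "fitted" or score_time == "per_time":
            S_field = vfc_fit(self.coords, S_samples, **vkw)
        elif score_mode == "analytic":
            S_field = gmm.score  # callable (n,2)->(n,2)
        else:
            raise ValueError(f"unknown score_mode {score_mode!r}")

        ff = ForceField(V_field, S_field, self.D)
        return SparseFFRResults(
            model=self,
            embedding=emb,
            block_transition=bt,
            pseudotime=tau,
            flow_samples=flow,
            gmm=gmm,
            sigma=float(sigma),
            sigma_selection=sigma_sel,
            score_samples=S_samples,
            V_field=V_field,
            S_field=S_field,
            force_field=ff,
        )


@dataclass
class SparseFFRResults:
    """Fitted flow/score fields plus every derived landscape quantity."""

    model: SparseFFR
    embedding: Embedding
    block_transition: transitions.BlockTransition
    pseudotime: transitions.Pseudotime
    flow_samples: density.FlowSamples
    gmm: density.DensityModel
    sigma: float
    sigma_selection: density.SigmaSelection | None
    score_samples: np.ndarray
    V_field: SmoothField
    S_field: object
    force_field: ForceField
    _cache: dict = dc_field(default_factory=dict)

    # -- accessors ----------------------------------------------------------

    def force(self, x: np.ndarray, D: float | None = None) -> np.ndarray:
        ff = self.force_field if D is None else self.force_field.with_D(D)
        return ff.force(x)

    def cellwise_force(self, D: float | None = None) -> np.ndarray:
        """Per-cell force V(x_i) + D S(x_i) from the raw (unsmoothed)
        Kramers–Moyal flow and score samples; rows are zero-flow where the
        flow estimator had no valid neighbors (see flow_samples flags)."""
        D = self.model.D if D is None else float(D)
        return self.flow_samples.V + D * self.score_samples

    def force_field_at(self, D: float) -> ForceField:
        return self.force_field.with_D(D)

    # -- downstream stages --------------------------------------------------

    def _domain_bounds(self, pad: float = 0.2) -> np.ndarray:
        X = self.model.coords
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.maximum(hi - lo, 1e-6)
        return np.stack([lo - pad * span, hi + pad * span], axis=1)

    def simulate(self, D: float | None = None, x0: np.ndarray | None = None,
                 **kwargs) -> dynamics.TrajectoryEnsemble:
        """Langevin ensemble from the earliest snapshot's empirical states
        (by default), reflected at a box padding the full embedding."""
        ff = self.force_field if D is None else self.force_field.with_D(D)
        if x0 is None:
            t0 = self.model.times.min()
            x0 = self.model.coords[self.model.times == t0]
        kwargs.setdefault("seed", self.model.seed)
        kwargs.setdefault("bounds", self._domain_bounds())
        return dynamics.simulate(ff, x0, **kwargs)

    def landscape(self, ens: dynamics.TrajectoryEnsemble | None = None,
                  **kwargs) -> dynamics.Landscape:
        if ens is None:
            ens = self.simulate()
        return dynamics.steady_state_landscape(ens, **kwargs)

    def basins(self, land: dynamics.Landscape, **kwargs) -> dynamics.BasinSet:
        return dynamics.find_basins(land, **kwargs)

    def shape_modes(self, basins: dynamics.BasinSet, sigma_mode: float | None = None):
        return dynamics.assign_shape_modes(self.model.coords, basins, sigma_mode)

    def flux(self, land: dynamics.Landscape, D: float | None = None) -> dynamics.FluxField:
        ff = self.force_field if D is None else self.force_field.with_D(D)
        return dynamics.flux_field(ff, land)

    def diffusion_scan(self, D_list, **kwargs):
        t0 = self.model.times.min()
        x0 = self.model.coords[self.model.times == t0]
        kwargs.setdefault("seed", self.model.seed)
        sim_kwargs = dict(kwargs.pop("sim_kwargs", {}) or {})
        sim_kwargs.setdefault("bounds", self._domain_bounds())
        return thermo.diffusion_scan(self.force_field, D_list, x0,
                                     sim_kwargs=sim_kwargs, **kwargs)

    # -- plotting -----------------------------------------------------------

    def plot_landscape(self, land, basins=None, flux=None, **kwargs):
        from .plotting import plot_landscape

        return plot_landscape(land, basins=basins, flux=flux, **kwargs)

    def plot_force_field(self, D: float | None = None, n: int = 24, ax=None):
        from .plotting import plot_force_field

        return plot_force_field(self.force_field, self._domain_bounds(),
                                n=n, ax=ax, D=D)

    def plot_embedding(self, color="time", ax=None):
        from .plotting import plot_embedding

        values = (self.pseudotime.tau if color == "tau"
                  else self.model.times)
        label = "pseudotime (d)" if color == "tau" else "time (d)"
        return plot_embedding(self.model.coords, values, label=label, ax=ax)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        from scipy.stats import spearmanr

        rho = spearmanr(self.pseudotime.tau, m.times).statistic
        Vn = np.linalg.norm(self.flow_samples.V, axis=1)
        lines = [
            "Sparse force-field reconstruction",
            "=" * 48,
            f"cells:                {len(m.times)}",
            f"time points:          {len(np.unique(m.times))}"
            f"  (span {m.times.min():g}..{m.times.max():g} d)",
            f"diffusion D:          {m.D:g} (embedding units^2/day)",
            f"GMM bandwidth sigma:  {self.sigma:.4g}",
            f"pseudotime ~ time:    Spearman rho = {rho:.3f}",
            f"mean |V| at cells:    {Vn.mean():.4g} units/day",
            f"VFC inlier fraction:  {self.V_field.gamma:.3f}",
            f"VFC residual sigma^2: {self.V_field.sigma2:.4g}",
            f"VFC EM iterations:    {len(self.V_field.energy_trace)}",
            f"score mode:           "
            + ("fitted" if isinstance(self.S_field, SmoothField) else "analytic (GMM)"),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-cell table: embedding, pseudotime, flow, score, force."""
        df = self.embedding.to_frame()
        df["tau"] = self.pseudotime.tau
        df[["v1", "v2"]] = self.flow_samples.V
        df[["s1", "s2"]] = self.score_samples
        df[["f1", "f2"]] = self.force(self.model.coords)
        return df
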