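# sparseffr

Reconstruction of the stochastic driving force of cell-state dynamics from
sparse, time-stamped single-cell snapshots — and the nonequilibrium
landscape that follows from it.

## The problem

Imaging experiments that follow a cell population through a state
transition (for example fibroblasts converting into neurons over eleven
days of daily fixation and imaging) produce *snapshots*: each cell is
segmented and measured once, at one time point, and then lost. No cell is
tracked. The question is whether the underlying dynamics — which shapes
are stable, how cells move between them, how high the barriers are and
how much the process dissipates — can be recovered from such destructive
sampling alone.

## The model

Cell shape is reduced to a 2D state space and modeled as an overdamped
Langevin system

    dx/dt = F(x) + sqrt(2 D) xi(t),

whose driving force decomposes exactly (for homogeneous diffusion) as

    F(x) = V(x) + D * grad log p(x)  =  V(x) + D S(x):

a deterministic flow field **V** plus the diffusion-scaled score field
**S**. Both pieces are estimable from snapshots:

1. **Shape metric.** Each segmented contour is resampled to 150
   equidistant boundary points; cells are compared by the
   Gromov–Wasserstein distance between their intra-contour distance
   matrices, which is invariant to position, rotation and reflection.
2. **Embedding.** UMAP on the precomputed metric gives the 2D state
   space and the fuzzy neighborhood graph.
3. **Flow.** An optimal-transport-informed block transition matrix
   (within-day kNN transitions + entropic OT plans between consecutive
   days) yields a real-time-anchored pseudotime and the first
   Kramers–Moyal coefficient V(x_i) = sum_j T_ij (x_j - x_i)/(tau_j - tau_i).
4. **Score.** A maximum-entropy Gaussian mixture (one kernel per cell,
   bandwidth selected by leave-one-out likelihood against a KDE
   smoothness reference) gives p(x) and S = grad log p.
5. **Global field.** Both components are fitted as smooth Gaussian-kernel
   fields by an outlier-robust EM (Gaussian inliers / uniform outliers),
   so F(x; D) = V(x) + D S(x) is available everywhere, for *any* D,
   without refitting.

Langevin simulation of the fitted field then gives the landscape
U = -log p_ss, its basins (archetypal shape modes), least-action
transition paths, barrier heights, mean first-passage times, the
steady-state curl flux J_ss/p_ss, the accumulated flux along the
transition path, and the entropy production rate (k_B T = D convention).

## Worked example

Recover a known force field from six snapshot ensembles of a rotational
Ornstein–Uhlenbeck process (300 cells per time point, exact sampling):

```python
import numpy as np
from sparseffr import SparseFFR
from sparseffr.synthetic import ou_benchmark

ds = ou_benchmark(seed=7)                  # F_true(x) = A x, D = 0.1
model = SparseFFR(ds.coords, ds.times, D=0.1, seed=7)
res = model.fit(score_time="per_time", ot_eps=0.005)
print(res.summary())

F_hat = res.cellwise_force()
ok = ~res.flow_samples.no_neighbor_flag
cos = np.sum(F_hat[ok] * ds.F_true[ok], axis=1) / (
    np.linalg.norm(F_hat[ok], axis=1) * np.linalg.norm(ds.F_true[ok], axis=1))
print(f"median cosine(F_hat, F_true) = {np.median(cos):.3f}")
```

```
Sparse force-field reconstruction
================================================
cells:                1800
time points:          6  (span 0..1 d)
diffusion D:          0.1 (embedding units^2/day)
GMM bandwidth sigma:  0.1174
pseudotime ~ time:    Spearman rho = 0.990
mean |V| at cells:    1.611 units/day
VFC inlier fraction:  0.976
VFC residual sigma^2: 0.06842
VFC EM iterations:    27
score mode:           fitted
median cosine(F_hat, F_true) = 0.987
```

The pseudotime tracks the recording times almost perfectly, and the
reconstructed per-cell force points within a few degrees of the true
drift at the median cell. A full contour pipeline looks the same but
starts from polygons:

```python
from sparseffr.synthetic import make_morphing_contours
ds = make_morphing_contours(n_per_day=50, days=11, noise=0.02, seed=3)
model = SparseFFR.from_contours(ds.cells, D=0.003, seed=0)
res = model.fit()
ens = res.simulate(dt=2e-3, n_steps=6000, n_traj=400, burn_in=1000)
land = res.landscape(ens)
basins = res.basins(land, max_depth_merge=0.5)   # archetypal shape modes
```

## Command line

Every stage is also a cached CLI step over a YAML config:

```bash
sparseffr run-all --config examples/morphing.yaml --outdir runs/morphing
```

which writes `contours.csv`, `metric.csv`, `embedding.csv`,
`cellwise.csv` (pseudotime, flow, score, force per cell),
`landscape.csv`, `basins.json` and `thermo.csv` (one row per diffusion
coefficient: barrier, MFPT, accumulated flux, EPR).

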