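# Methods

This note records the model, the estimators, the numerical choices and the
known limitations of the package, in the order the pipeline runs them.

## Model

Cell-state (morphological) dynamics are modeled as an overdamped Langevin
system in a reduced 2D state space,

    dx/dt = F(x) + sqrt(2 D) xi(t),      <xi(t) xi(t')> = delta(t - t'),

with homogeneous, isotropic diffusion D. Writing p(x, t) for the state
density, the force decomposes as

    F(x) = V(x) + D S(x),        S(x) = grad log p(x),

where V is the deterministic (Liouville) flow that transports the same
density as the Fokker–Planck equation and S is the score field. The two
components are estimated independently from time-stamped snapshots, so the
force is available for *any* diffusion coefficient without refitting. At
steady state the landscape is U = -log p_ss, the probability flux is
J_ss = F p_ss - D grad p_ss, and the normalized curl flux V_ss = J_ss/p_ss
quantifies irreversible circulation (zero iff detailed balance holds).

Assumptions: Markovian dynamics, homogeneous diffusion, and snapshot
sampling dense enough in time that consecutive populations overlap in state
space after optimal-transport matching. Where these fail the reconstruction
degrades gracefully (the robust field fit down-weights inconsistent
samples) but is not guaranteed.

## Shape representation and metric

Segmentation polygons are resampled to K = 150 points equidistant in arc
length, oriented counter-clockwise, with the parameterization started at
the boundary point farthest from the polygon's *area* centroid (the area
centroid is invariant to boundary re-parameterization, which makes
resampling idempotent). Contours are centered and rotated so the principal
covariance axis lies along x; the 180-degree and reflection ambiguities are
fixed by making the third moments of x and then y nonnegative. Point sets
with no preferred axis (equal covariance eigenvalues) are centered only and
flagged. Contours are not rescaled by default — size is morphological
signal; `normalize_scale` divides by the root-mean-square radius when shape
alone should matter.

Cells are compared by the Gromov–Wasserstein (GW) distance between their
intra-contour Euclidean distance matrices with uniform weights,

    GW(D^i, D^j) = 1/2 min_T sum |D^i_ab - D^j_gd| T_ag T_bd,

which is invariant to rigid transformation and reflection by construction.
Solvers (in `_ot.py`, no external OT dependency):

* conditional gradient (Frank–Wolfe) with an exact line search — the GW
  energy is a quadratic form in the coupling for any fixed loss, so the
  optimal step is closed-form;
* entropic projected gradient with epsilon-annealing, used as the
  alternative for large point sets.

Both losses are supported: the absolute difference (the defining form) and
the squared difference, whose gradient factorizes to O(K^2 m) and is the
default for all-pairs work. GW is non-convex; warm starts are the product
coupling (closed-form energy), the best cyclic-shift/reversed-cyclic
correspondence (the natural candidate family for equidistantly sampled
closed contours, scanned by FFT cross-correlation for the squared loss),
and — for tiny instances, n <= 6 — the exact best permutation by
enumeration. A warm start with (near-)zero energy short-circuits the
iteration, which makes rigid-copy pairs exact and fast.

At desk scale the all-pairs stage subsamples each contour to
`n_points = 32` boundary points (uniform stride of the 150) before the GW
solve; with ~550 cells this keeps the metric matrix under two minutes on
one core. This is a resolution choice of the package, exposed in the API
and config.

## Embedding and transitions

UMAP with `metric="precomputed"`, `n_neighbors = 30`, `min_dist = 0.5` and
a mandatory seed embeds the metric matrix in 2D; the learned fuzzy
simplicial set is kept and reused as the connectivity graph. Data already
in 2D (mid-pipeline entry) get the same fuzzy kNN graph built directly.

The global transition matrix is block-structured by recording time:
diagonal blocks are the row-normalized fuzzy edge weights within a time
point (no self-edges; isolated cells get a self-transition), and the first
upper off-diagonal blocks are entropic optimal-transport plans between
consecutive time points (balanced, uniform marginals — the imaged
populations proliferate minimally). Each row of a non-final block splits
its mass 0.5/0.5 between its within-time block and its OT block before
renormalization; the weighting is a package choice exposed in config.

Pseudotime is a damped diffusion of the recording times through the chain:
tau <- (1-d) t + d T_hat tau, iterated 50 times with damping d = 0.5 from
tau = t, then min-shifted to zero. With the identity chain or zero damping
it reduces to the shifted recording times.

## Cell-wise flow and score

The flow at cell i is the first Kramers–Moyal coefficient

    V(x_i) = sum_{j in N(x_i)} T_hat_ij (x_j - x_i)/(tau_j - tau_i),

where N(x_i) is the support of row i of the transition matrix (its top-30
entries), neighbors with |tau_j - tau_i| < dtau_min = 0.05 d are excluded
(they would divide a within-cloud displacement by a vanishing time
difference), and the retained weights are renormalized. Using the
transition-row support rather than spatial k-nearest neighbors matters when
consecutive snapshot populations barely overlap in state space: the OT
plans then carry all of the forward correspondence. Cells with no valid
neighbor (the final time point) are flagged and excluded from the flow
field fit.

The state density is a maximum-entropy Gaussian mixture: one isotropic
kernel of equal weight per sample, covariance sigma^2 I. The bandwidth
trades off the leave-one-out log-likelihood of the data (C2) against the
KL divergence from a Scott's-rule KDE reference (C1, grid quadrature on a
128x128 lattice covering the data plus three reference bandwidths); both
curves are min-max normalized and sigma maximizes C2_hat - C1_hat, ties
toward smaller sigma. Leave-one-out (with exact duplicates also left out)
is essential: scoring a point by its own kernel diverges as sigma -> 0 and
would pin the selection to the grid edge. The score is evaluated from the
mixture responsibilities in log space, so density underflow far from the
data never produces a non-finite score.

Time dependence of the score: the default pools all cells (steady-snapshot
approximation). `score_time="per_time"` scores each cell against its own
snapshot's density with a per-block Scott bandwidth — the reading used for
the OU recovery benchmark, where the density genuinely moves.

## Robust global field fit

Both V and S are fitted (separately) as Gaussian-kernel expansions
f(x) = sum_m k_beta(x, z_m) c_m by EM on a Gaussian-inlier /
uniform-outlier mixture: inlier responsibilities p_n, a regularized
weighted least-squares coefficient solve minimizing

    E = 1/(2 sigma^2) sum p_n ||y_n - f(x_n)||^2 + lambda/2 ||f||_H^2,

then responsibility-weighted updates sigma^2 = sum p_n r_n^2 / (2 sum p_n)
and gamma = sum p_n / N. Defaults: gamma0 = 0.9, outlier volume a = 5,
lambda = 3, bandwidth beta = 2 / <mean squared distance to the N/5 nearest
neighbors>, at most 1000 anchor points (all points when N < 500). Targets
are normalized to unit RMS internally so the fixed outlier density stays
balanced against the adaptive Gaussian for any field scale; coefficients
are rescaled on output. The coefficient solve runs in the whitened
Nystrom eigenbasis (eigenvalues of K_MM below 1e-12 of the maximum
dropped), where the RKHS penalty is an identity ridge — the same
minimizer as the raw anchor system, but conditioned well enough that the
per-iteration energy descent is numerically exact; both the pre- and
post-solve energies are recorded so the monotonicity is checkable. The
residual variance floor is 1e-12 (on the normalized scale); with
full-anchor interpolation capacity and low noise sigma^2 can reach it —
the fitted field is then an interpolant, which is the intended limit.

## Landscape, basins, flux

Euler–Maruyama with fixed dt (default 1e-3 d) integrates the fitted field
inside a reflecting box padding the data extent by 20% (the box always
covers the *full* embedding, not just the initial states). p_ss is a
Gaussian-smoothed (1 grid cell), floored (1e-12) histogram on a 128x128
default grid, and U = -log p_ss. Basins are strict 8-neighbor minima of
the smoothed U restricted to cells with p_ss above 1e-3 of the density
peak (suppressing shot-noise minima in near-empty cells), merged when
closer than `min_separation` or separated by a ridge shallower than
`max_depth_merge` (watershed labels; deeper minimum kept). Shape modes
freeze basin minima as centroids: cells get nearest-centroid labels plus
isotropic-GMM membership posteriors, with max-posterior <= 0.5 marked
"boundary". The archetypal contour of a mode is the classical-MDS
embedding of the members' averaged intra-distance matrix. Flux fields use
central differences of p_ss on the grid.

Landscapes of directed processes are quasi-steady: simulations start from
the earliest snapshot's empirical states and run for a horizon comparable
to the observation window, which is what keeps transient (metastable)
basins visible. For metastable benchmark systems the scan instead uses
stratified both-well initialization with a horizon short against the
barrier-crossing time, pinning the inter-well occupancy at its
symmetric-equilibrium value — the slowest-converging statistic — while the
well interiors equilibrate locally.

## Paths, barriers, MFPT, EPR

The least-action path minimizes the discretized functional
S = pre * sum ||dx/dt - F||^2 dt with pre = 1/(2D) by default
("half") or 1/(4D) ("fw", the Freidlin–Wentzell rate functional) — the two
differ by a constant factor and share the same minimizer. Optimization is
two-stage: L-BFGS over interior nodes with the analytic gradient (field
Jacobians are analytic for kernel fields, finite-difference otherwise) at
uniform time steps for each candidate transition time on a log grid, with
arc-length re-spacing between rounds; then the time steps are re-matched
to the local deterministic speed |dx/dt| = ||F|| and the geometry
re-optimized. Speed matching removes the uniform-step bias near fixed
points (where the passage time diverges) and brings the gradient-system
quasi-potential within ~1% of its closed form. Because the functional
scales as 1/D for a fixed field, `diffusion_scan` optimizes the path once
and reuses it across D, removing optimizer jitter from cross-D
comparisons.

Barriers interpolate U bilinearly along the path (forward = max U minus
U at the start). MFPT is direct simulation with capture at a ball around
the target; censored trajectories contribute t_max, making the estimate a
lower bound, and > 50% censoring flags the result unreliable. The
accumulated flux is the midpoint-rule line integral of F p_ss along the
path minus D times the endpoint log-density difference.

EPR (with k_B T = D) has two estimators: the gridded form
sum (F + D grad U) . J_ss dA over cells with p_ss > 1e-6, and the
trajectory (Stratonovich heat) form <F o dx>/dt time-averaged over a
fresh ensemble. The trajectory form telescopes to a boundary term for
gradient fields and is therefore near-exactly zero under detailed balance,
whereas the gridded form carries histogram shot noise quadratically; the
trajectory estimator is used wherever small EPRs must be resolved.

## Synthetic benchmarks

* **OU snapshots** are drawn from the closed-form Gaussian marginals
  (matrix exponential + Lyapunov covariance), so there is no
  discretization error and V, S, F are attached exactly. The standard
  drift-recovery configuration (`ou_benchmark`) is a damped rotation
  A = [[-1, 1], [-1, -1]], D = 0.1, six snapshots 0.2 d apart, mean (2, 0)
  and isotropic spread 0.3 at start: the ensemble relaxes in a spiral,
  giving strong flow signal, a moving density, and snapshot spacing small
  against the relaxation time (the finite-difference bias of the
  Kramers–Moyal estimator is O(dt ||A||/2) ~ 14%).
* **Double well with curl**: Phi = b (x^2-1)^2 + y^2/2 with a rotational
  term. The default orthogonal-curl mode keeps exp(-Phi/D) exactly
  stationary, anchoring the Boltzmann-limit and detailed-balance
  benchmarks analytically. The rigid-curl mode (rotation about an
  off-center point) keeps the rotational force finite at the saddle, so
  the transition-path flux inherits the saddle density's strong growth
  with D — the configuration used for the noise-scan trend suite. The
  orthogonal construction provably cannot show that trend measurably: its
  path flux is dominated by well-flank terms with D-elasticity ~0.5.
* **Morphing contours** are star-shaped polygons whose radial Fourier
  profile interpolates a spindle archetype (dominant 2nd + 4th harmonics,
  aspect ratio > 3 after a 0.75 transverse squash) into a branched
  archetype (5th/7th harmonics) along a latent progress variable. The
  day-to-progress map is sigmoidal (steepness 10), emulating two
  metastable phases with a rapid mid-course conversion rather than uniform
  drift; per-cell jitter (SD 0.08) makes day and morphology correlated but
  not deterministic. Cells are placed with random rigid motions, boundary
  noise is multiplicative on the radius, and self-intersecting draws are
  rejected. What this does *not* emulate: segmentation errors, touching
  cells, size growth, imaging artifacts, or non-star-shaped (strongly
  concave) outlines — passing tests demonstrate the machinery, not
  robustness to real microscopy pathologies.

## Problem sizes

Default test/validation sizes: 11 days x 50 cells (pipeline), 6 x 300
samples (drift recovery), ensembles of 300–600 trajectories of 4e4–1.2e5
steps (landscape/thermo), 32-point GW subsampling. These are the package's
validation scale; every routine accepts larger inputs.

## Known limitations

* The 2D reduction is load-bearing: thermodynamic quantities measured in
  the embedding are lower bounds on their high-dimensional counterparts,
  and no lift back to contour space is provided.
* Balanced OT ignores proliferation/death; datasets with strong growth
  need unbalanced transport, which is out of scope.
* The MFPT estimator is biased low under censoring (reported and flagged);
  rare-event samplers are out of scope.
* GW is non-convex; the solver guarantees only warm-started local optima
  (exact for rigid copies and tiny instances).
* Basin counts depend on grid resolution, smoothing and merge tolerances;
  all are exposed in config and should be treated as analysis choices.
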