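# End-to-end run on the synthetic morphing-contour dataset:
# 11 daily time points, spindle-like -> branched shapes.
#
#   sparseffr run-all --config examples/morphing.yaml --outdir runs/morphing

input:
  synthetic:
    kind: morphing
    n_per_day: 50
    days: 11
    noise: 0.02
    seed: 3

contours:
  K: 150

gw:
  loss: sq
  n_points: 32      # boundary points per contour for the all-pairs GW stage
  max_iter: 25

embedding:
  n_neighbors: 30
  min_dist: 0.5
  seed: 0

transitions:
  eps: 0.05
  w_intra: 0.5
  w_inter: 0.5

density:
  sigma: null        # select by the likelihood/KL criterion

simulation:
  D: 0.003
  dt: 0.002
  n_steps: 6000      # ~12 days: horizon comparable to the observation window
  n_traj: 400
  burn_in: 1000
  seed: 0
  grid: 96

thermo:
  D_list: [0.001, 0.003, 0.01]
  seed: 0
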