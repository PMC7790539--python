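# stericlv

Spatial Lotka–Volterra competition among steric pillars: a reaction–diffusion
simulator and analysis toolkit for studying how physical structure in an
environment stabilizes coexistence of mutually competing species.

## The scientific problem

Microbial communities in soils, guts, and biofilms routinely contain many
species competing within the same niche. Classical competitive-exclusion
theory — and simulations of Lotka–Volterra dynamics in featureless space —
predict that one dominant competitor should eventually take over. Yet natural
habitats are not featureless: they are full of impenetrable obstacles (sand
grains, tissue folds, fibers). This package simulates N competing species in
a 2D box studded with circular "pillars" and quantifies how the obstacles'
spacing, size, and disorder change long-term species coexistence.

The model is the non-dimensional N-species spatial Lotka–Volterra system

    ∂S_i/∂t = ∇²S_i + S_i · (1 − Σ_k S_k · (1 + (1 − δ_ik)/P_ik)),

where each field S_i ∈ [0, 1] is a local concentration in carrying-capacity
units, lengths are in natural units λ = √(D/r), and time is in doubling
times. The directed thresholds P_ik (the concentration of species k above
which k actively reduces species i) are sampled uniformly with mean ⟨P⟩ and
full width ΔP; every off-diagonal entry in (0, 1) means all-to-all (ATA)
active competition.

Key quantities the package computes:

- **Interface-curvature theory.** A pair of unbalanced competitors forms an
  interface that is stable only if it can curve at least
  κ ∝ |P_ik − P_ki| / (λ (P_ik + P_ki)); two pillars of radius R spaced Δx
  cap the achievable curvature at κ_struc = 1/(R√((Δx/2R)² − 1)). Equating
  the ensemble average of the first to the second yields a critical
  structural scale (Δx/R)_crit = 2√(1 + (2λ⟨P⟩/(RΔP))²) below which all
  species can coexist.
- **Point-pattern statistics.** Voronoi/Delaunay neighborhoods of the pillar
  pattern, nearest-neighbor and pairwise distance distributions, and the
  local structural scale of disordered arrangements.
- **Ensemble survival statistics.** Over replicate simulations, survivor
  counts follow a zero-truncated binomial
  p_n(N, α) = C(N,n) αⁿ(1−α)^{N−n} / (1 − (1−α)^N); the single-species
  survival probability α is fitted by maximum likelihood with 95%
  profile-likelihood confidence intervals.
- **Per-run observables.** Area fractions, the normalized standard deviation
  (NSD) of abundances across survivors, domain labeling, boundary
  segmentation, and the fraction of Voronoi-neighbor pillar pairs connected
  by an interspecies boundary ("connection density").

## Worked example

Simulate 8 balanced competitors on an ordered pillar lattice (Δx/R = 3.5,
R = 3) in a reduced box (L = 75), then summarize the outcome:

```python
import numpy as np
import stericlv as slv

env = slv.make_environment(L=75.0, dx=10.5, R=3.0, delta=0.0)
mat = slv.sample_matrix(N=8, mean_p=0.25, delta_p=0.0, seed=1)
cfg = slv.SimulationConfig(n_species=8)           # dt=0.01, tol=0.001, ...
traj = slv.run(cfg, env, mat.P, rng=np.random.default_rng(3))

thr = slv.extinction_threshold(env)
n, idx = slv.surviving_species(traj, thr)
print(traj.terminated_by, traj.final_state.time, n)
print(np.round(traj.mean_abundance[-1], 4))
```

prints

```
equilibrium 38.0 8
[0.3007 0.1084 0.0516 0.0198 0.1316 0.0871 0.1107 0.0359]
```

All 8 species equilibrate above the extinction threshold (4.8·10⁻⁴ here):
interfaces pin between pillars and arrest the coarsening that, in the same
box without pillars, ends with a single dominant species. The printed vector
is each species' share of the habitable area.

The same workflow is scriptable from the shell:

```bash
stericlv make-env --L 150 --dx 10.5 --R 3 --delta 0 --seed 1 --out env.h5
stericlv simulate --config run.yaml --out run.h5
stericlv analyze run.h5 --out summary.json
stericlv sweep --config sweep.yaml --replicates 30 --out sweep.csv
stericlv fit-alpha sweep.csv --N 8 --out alpha.json
```

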