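# Methods

## Model

`stericlv` integrates the non-dimensional N-species spatial Lotka–Volterra
system

    ∂S_i/∂t = ∇²S_i + S_i (1 − Σ_k S_k (1 + (1 − δ_ik)/P_ik))

on a 2D pixel grid. Each field S_i is a concentration in carrying-capacity
units (0 ≤ S_i ≤ 1), space is measured in natural lengths λ = √(D/r) (the
RMS dispersal distance per doubling time), and time in doubling times 1/r.
All species share the same growth rate, diffusivity, and carrying capacity;
they differ only through the directed competition thresholds P_ik — the
concentration of species k above which k actively reduces species i. The
diagonal is removed by the Kronecker delta and never read (it is stored as
NaN). With every off-diagonal P_ik ∈ (0, 1) ("all-to-all" competition) every
adjacent species pair forms an actively competing interface, the regime in
which isotropic space coarsens toward a single dominant competitor.

Assumptions worth keeping in mind: deterministic PDE dynamics (stochasticity
enters only through initial conditions, disorder, and matrix sampling),
purely diffusive motility, constant and spatially uniform resources, and
time-invariant pairwise interactions.

## Environments

Habitats are square boxes of side L containing impenetrable disks ("pillars")
of radius R placed on a triangular lattice of spacing Δx. Rows run parallel
to the x-axis, the first row at y = Δx/2, alternate rows offset by Δx/2 —
any fixed orientation is statistically equivalent; this one is the simplest.

Disorder displaces each center in a uniformly random direction by a
magnitude drawn from Uniform[0, w] with w = δ(Δx − R)/2, so
δ = 2w/(Δx − R): δ = 0 is the perfect lattice and δ ≈ 1 approaches a random
arrangement. Two genuinely open choices were fixed here: the displacement
magnitude is uniform on [0, w] (so δ interpolates continuously from order to
disorder), and centers displaced outside the box are clamped to its
boundary. Pillar disks may overlap each other or the box edge.

The grid has side n = round(L · ppl) with ppl = 5/1.29 pixels per λ, so that
pixels are smaller than λ and competitive interfaces span roughly ten
pixels. The grid tiles the box exactly, making the effective pixel scale n/L
(within 0.2% of the request); a pixel is uninhabitable iff its center lies
within R of a pillar center. The habitable area A is the valid-pixel count
times the pixel area.

Voronoi analysis (scipy.spatial) classifies a pillar as *interior* when its
cell is bounded with all vertices inside the box — edge pillars are excluded
from neighbor statistics, mirroring how edge objects are discarded in image
analysis. Interior pillars of a perfect lattice have exactly 6 neighbors;
disordered ones typically 5–7. The "local structural scale" statistic takes,
per interior pillar, the convex polygon through its Voronoi neighbors and
records the longest polygon edge; the fraction of polygons whose longest
edge is below Δx measures how often disorder creates prospective domains
tighter than the ordered lattice — these are rare (well under 1% per
realization at δ = 1) but nonzero in ensembles.

## Numerical scheme

Each step of length Δt = 0.01 applies diffusion, then a forward-Euler
reaction update:

- **Diffusion** is a Gaussian convolution with per-axis width σ = √(4DΔt)
  = 0.2 λ, truncated at ±4σ and normalized over the full stencil
  (scipy.ndimage.gaussian_filter). Masking implements reflecting boundaries:
  the blurred field is zeroed on invalid pixels and the kernel weight each
  source pixel would have sent into invalid territory is returned to that
  source ("self-return reflection"). The resulting pixel-to-pixel operator
  is symmetric with unit row sums, hence exactly conservative (to round-off)
  and with the uniform field as fixed point. The printed width σ = √(4DΔt)
  is kept for fidelity even though the 2D heat kernel would use √(2DΔt) per
  axis; `SimulationConfig.sigma` is a free parameter for sensitivity
  checks.
- **Reaction** applies the growth term with hard clamping of each field to
  [0, 1] as a stability guard. Clamp events are counted and reported; in the
  standard parameter regime they do not occur.
- Densities below 10⁻³⁰ are flushed to zero at every recording step. Dying
  species otherwise decay exponentially into subnormal-float range, which
  slows the convolution by roughly an order of magnitude; the flush is ~26
  orders of magnitude below any extinction threshold and has no effect on
  outcomes.

Initial conditions seed each species independently: every valid pixel
receives concentration 1/N with probability 0.002, so species establish
territory before meeting competitors. Contrived initial geometries
(half-planes, an enclosed disk, an N-wedge pinwheel) support interface
experiments.

Runs last at most 5000 doubling times. Mean abundances are recorded every
100 steps; at the same cadence the mean absolute change per pixel and
species between consecutive recorded snapshots is compared to the
equilibrium tolerance 0.001. Because sparse seeding makes the earliest
snapshots nearly static, the stop is *armed* only once the change has first
risen above tolerance and fires when it falls back below — "falling below"
taken literally. Comparing snapshots 100 steps apart (rather than adjacent
Δt steps) is the only reading under which the tolerance discriminates
growth and coarsening (changes ~10⁻²) from pinned equilibrium (≪10⁻³);
per-Δt changes never exceed 10⁻³ even during vigorous growth. A tolerance
of 0 disables early stopping for fixed-horizon experiments.

Extinction is classified only at termination (removing species mid-run
would alter the dynamics): a species survives if its final mean density is
at least ((2R)² − πR²)/4A — the density of a remnant population trapped
between a pillar and a box corner, far below the density of any
Delaunay-triangle-sized domain.

## Interface-curvature theory

A two-species interface with mismatched thresholds has a pair-critical
curvature κ ∝ |P_ik − P_ki|/(λ(P_ik + P_ki)): flatter interfaces advance
into the weaker competitor; more curved ones are stable. The expression is a
proportionality; the package's default prefactor is 3, chosen so that the
ensemble average over uniform sampling (E|P_ik − P_ki| = ΔP/3,
E[P_ik + P_ki] ≈ 2⟨P⟩) reproduces the closed-form ensemble curvature
ΔP/(2λ⟨P⟩). The prefactor is configurable since only the ensemble form is
pinned down by theory.

Two pillars of radius R at center spacing Δx cap the curvature of an
interface meeting both at right angles at κ_struc = 1/(R√((Δx/2R)² − 1)).
Setting the ensemble curvature equal to the cap gives the critical
structural scale

    (Δx/R)_crit = 2 √(1 + (2λ⟨P⟩/(R·ΔP))²),

the spacing below which all species of the ensemble can coexist. The
identity κ_struc(R·(Δx/R)_crit) = ΔP/(2λ⟨P⟩) holds exactly and is tested to
10⁻¹².

## Ensemble statistics

Replicate survivor counts condition on at least one survivor, giving the
zero-truncated binomial p_n(N, α) = C(N,n)αⁿ(1−α)^{N−n}/(1−(1−α)^N). The
MLE of α uses bounded scalar optimization of the log-likelihood; 95%
confidence bounds come from the profile likelihood at the χ²(1 df) cutoff
(a parametric bootstrap is available behind a flag). When every replicate
retains all N species the likelihood is maximized at the α → 1 boundary;
the fit is then reported with an open upper interval. NSD (the abundance-
variability statistic) is the *population* standard deviation of area
fractions across surviving species — the paper-adjacent choice of sample vs
population is not determined by theory; population SD keeps the two-
survivor case {1, 0} at exactly 0.5.

Sweeps derive per-replicate seed triplets (environment, matrix, initial
condition) from a base seed and the global row index via
`numpy.random.SeedSequence([base, row])`, so any row replays bit-exactly
regardless of execution order.

## Observables

Domain labels are the per-pixel arg-max species (ties to the lowest index);
a valid pixel is a boundary pixel if its peak density falls below 0.5 (the
depleted zone of active competition) or its label differs from a
4-neighbor's. The dual criterion is robust both to depleted boundary zones
and to sharp label flips. Boundary components are 8-connected; a component
contacts a pillar if any pixel lies within 2 px of the pillar disk, and
components touching the image border are excluded from pair counting.
Connection density is the fraction of interior Voronoi-neighbor pillar
pairs joined by some non-edge component; pairs joined across non-neighbor
pillars are reported separately and excluded from the numerator.

## Problem sizes and what the tests show

The full study behind the theory runs thousands of L = 150 simulations with
30–1000 replicates per condition. This package's test suite exercises the
same machinery at desk scale, a deliberate package choice: structured
coexistence at L = 75 (single run), isotropic coarsening at L = 15,
interface experiments in boxes of 20–32 λ, and sweeps over 2×2 parameter
grids with 3–12 replicates at L = 30–40. These sizes demonstrate the
qualitative phenomena — pinning, coarsening, the critical-scale separation,
decreasing survival probability with species number and with shrinking
system size — but estimate ensemble quantities (α, NSD distributions,
connection densities) with correspondingly wide uncertainty. Desk-scale
boxes also sit closer to the advisory minimum habitable area N·Δx², so
size-limited species loss mixes with curvature-driven loss at the largest
structural scales tested.

Two caveats found while validating:

- In small isotropic boxes, coarsening occasionally locks into a stripe
  whose straight boundaries span two parallel box edges; such states are
  neutrally stable and never resolve to a single species. This is an
  acknowledged edge case of the single-dominance claim, not a failure of
  coarsening; the isotropic tests use a box size and horizon at which the
  tested initial conditions do resolve.
- The synthetic-data generator (environments, matrices, seeding) emulates
  the study's stated conditions exactly but shares their idealizations:
  perfectly circular obstacles, spatially uniform carrying capacity, and
  deterministic dynamics. Passing tests therefore say nothing about
  demographic noise, non-diffusive dispersal, or obstacle-shape effects on
  real communities.

## Known limitations

- No intransitive (rock–paper–scissors) analysis: the matrix container
  accepts arbitrary values but no limit-cycle or stability cataloguing is
  provided.
- 2D only; no flow, chemotaxis, Allee effects, or secreted-toxin fields.
- Explicit forward-Euler time stepping only; the scheme is stable in the
  standard regime (clamp counter verifies this per run) but is not meant
  for stiff parameter choices.
- Boundary segmentation is threshold-based; the connection-density statistic
  can be sensitive to the segmentation rule near very depleted interfaces.
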