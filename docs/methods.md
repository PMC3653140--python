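# Methods

## Scope and model

`neuritemri` treats a neuron as a collection of impermeable cylinders and
asks how well a diffusion-tensor measurement of water inside those
cylinders reports their orientation distribution.  Only the intracellular
neurite compartment is modelled: the neurite volume fraction is fixed at
one, and somas, extracellular space, glia, membrane exchange and myelin
are outside scope.  Somas (SWC structure code 1) are treated as isotropic
and are excluded from both the orientation statistic and the signal;
structure codes 2, 3 and 4 (axon, basal and apical dendrite) are included
by default and the set is configurable.

## Morphometry: from SWC to the scatter matrix

1. **Parsing.** Strict 7-column SWC; `#` comments and blank lines are
   skipped; duplicate ids, non-positive radii, non-finite coordinates and
   forward/unknown parent references are rejected with line numbers.
   Units are μm throughout (the NeuroMorpho convention); no inference.
2. **Interpolation.** Every parent–child edge of length L is divided into
   ceil(L/step) equal sub-edges (default step 1 μm), with coordinates and
   radii interpolated linearly.  Total cable length, topology and termini
   are preserved exactly.
3. **Path decomposition.** Depth-first descent from each stem: at a
   branch point the current path continues into the lowest-id unused
   child, and each remaining child starts a new path from the branch
   coordinate.  Every non-soma edge lies in exactly one path and the path
   count equals the terminus count.  A stem whose parent is a soma starts
   at the soma coordinate; a flag selects the soma surface point instead
   (centroid is the default — the choice moves each stem's first ≤ r_soma
   of cable and is immaterial for trees of any size).
4. **Average lines.** Walking each path, consecutive points are
   accumulated until the cumulative polyline length reaches the line
   length l (default 10 μm, the conventional choice; the run closes with
   a 10⁻⁴ μm slack so that text round-tripped coordinates do not drop
   boundary runs).  An orthogonal-distance-regression line — the
   principal axis of the centered second-moment matrix — gives the
   segment direction; the segment radius is the unweighted mean of the
   node radii in the run.  Terminal leftovers shorter than l are
   discarded.  The ODR fit is unweighted; sign is fixed by nonnegative z
   (then y, then x) and a degenerate flag marks runs whose top two
   moments coincide.

The scatter matrix is T = Σ_k w_k û_k û_kᵀ with volume-fraction weights
w_k = r_k²/Σr_i² (the common length cancels), i.e. the matrix of rows
√w_k·û_kᵀ.  This form makes trace(T) = 1 and τ̄ = 1/3 hold by
construction, which is the defining property of the statistic.  FA is
computed identically for τ and for diffusion-tensor eigenvalues λ.

Neurons yielding fewer than 100 segments at a given l are flagged
excluded in the line-length sweep: an orientation statistic over so few
lines is dominated by sampling noise.

## Signal simulation

For a two-pulse Stejskal–Tanner sequence with pulse duration δ,
separation Δ and b = (Δ − δ/3)q², the cylinder-sum signal is

S(n̂, b) = Σ_k w_k · exp(−b·D_T,k) · exp(−(û_k·n̂)²(D_L − D_T,k)·b),

so S(0) = 1 exactly.  The transverse ADC D_T(r) comes from the
Gaussian-phase-distribution series for restricted diffusion in an
impermeable disc (Neumann eigenmodes; roots of J₁′), evaluated at the
sequence timings; because b ∝ (γgδ)², D_T is independent of gradient
strength.  The series uses up to 60 precomputed Bessel-derivative roots
with adaptive truncation at 10⁻⁸ relative change; it is validated against
a 10⁵-walker random-walk phase-accrual simulation in a disc (agreement
well within 2 % at r = 1 μm, δ = 10 ms, Δ = 20 ms) and reproduces both
limits (D_T → 0 as r → 0; D_T → D0 as δ, Δ → 0).

Defaults, all configurable and recorded in output manifests:
D_L = D0 = 1 μm²/ms (matching the dispersed-cylinder experiment's
diffusivity), δ = 10 ms, Δ = 20 ms, b-shells {0, 0.2, …, 1.0} ms/μm²,
63 gradient directions.  Directions are generated by deterministic
projected-gradient descent on the Coulomb energy of the antipodally
symmetrized point set, seeded; 63 directions end up ≥ 10° apart.

## Tensor and cumulant fits

Both models are fitted by trust-region nonlinear least squares on
linear-scale signals, initialized from the log-linear solution.  The
cumulant model absorbs the conventional kurtosis front factors into K̂
(ln S exactly quadratic in b_ij); the mapping to Jensen's W tensor is
K̂_ijkl = −(1/6)·D̄²·W_ijkl.  The kurtosis fit is initialized at the DTI
solution with K̂ = 0, so the monotone solver structurally guarantees the
nested-model property (explained variation of the cumulant fit never
below the DTI fit's).  Explained variation is 1 − SS_res/SS_tot over all
measurements including b = 0.  Fits with explained variation ≥ 0.95 are
classed "good", below it "poor" (threshold configurable).

The Gaussian-regime comparison pairs descending-sorted eigenvalues and
evaluates λᵢ − λ̄ = D_A(τᵢ − 1/3) and
FA_D·√(Σλ²) = D_A·FA_T·√(Στ²).  D_A is taken from the simulation's own
parameters (D_L minus the weight-averaged D_T) when known; otherwise it
is estimated as the regression slope of centralized λ on centralized τ.

## The dispersed-cylinder (Watson) experiment

Orientations are drawn from f(û) ∝ exp(κ(û·ẑ)²) by rejection sampling
with uniform-sphere proposals and envelope e^κ.  For each of 191 κ values
uniformly spanning [1, 20] (step 0.1), 10,000 infinitely narrow cylinders
with D = 1 μm²/ms produce equal-weight Gaussian signals
exp(−bD(n̂·û)²) on b-shells {0, b_max/2, b_max}.  Per κ a fresh seed is
derived from the master seed by counter and recorded.

τ₁ is the sample mean of (û·ẑ)², with τ₂ = τ₃ = (1 − τ₁)/2 imposed by
axial symmetry.  λ_∥ and λ_⊥ come from mono-exponential (log-linear)
fits of the signal along ẑ and perpendicular to it; the acquisition is
the 63-direction scheme augmented with ẑ and two exact perpendicular
directions, and the perpendicular signal is averaged over those two
directions per shell before the fit.  That azimuthal averaging is the
estimator dictated by the population's axial symmetry; it is unbiased
against a deterministic 1-D quadrature oracle at every κ and suppresses
the finite-sample azimuth noise that would otherwise inflate a
maximum taken over 191 sweep points.  A flag substitutes a full tensor
fit over all 63 directions for the axis construction.

The sweep records, per κ: τ eigenvalues, (λ_∥, λ_⊥), FA_T, observed FA_D,
the prediction D·FA_T·√(Στ²/Σλ²), and their difference; the summary is
the maximal |difference| and the FA_D where it occurs.  The difference is
one-sided (observed ≤ predicted) and grows with b_max.  Note the
difference-vs-FA curve is nearly flat around its maximum, so the FA
location of the maximum is ill-conditioned and wanders by a few
hundredths across seeds, while the maximum itself is stable to ~0.0005.

The choice of a log-linear (rather than linear-scale nonlinear)
mono-exponential ADC fit matters at these b-values because the decay is
not mono-exponential; the log-linear reading is the one consistent with
the quadrature-oracle characterization of the bias used in the tests.

## Synthetic morphology

`generate_neuron` grows a branching random walk: tips advance in 2 μm
steps with Gaussian heading jitter (σ = 0.35 rad), a pull of strength
`tropism_strength` toward a global axis, branching at 0.02 per μm with
mean branch angle 40°, and radius taper ×0.95 per branch point with a
0.2 μm floor (keeping the volume weights heterogeneous).  Growth stops
at a total cable budget (default 2,000 μm, a small-neuron scale chosen to
keep a single tree's morphometry around 10²–10³ segments).  Expected
FA_T increases monotonically with tropism strength, from ≈ 0 (isotropic
null at matched N) to > 0.9.  `generate_bundle` writes n straight,
equal-radius, Watson-oriented cables as a single SWC forest; the
morphometry pipeline recovers exactly one segment per cable, so its
scatter matrix equals the sample second moment of the drawn directions.
Coordinates are rounded to a 10⁻⁶ μm grid so SWC text round-trips are
exact and compact.

What the generators do **not** emulate: real reconstruction noise and
artifacts, curvature/tortuosity statistics of real dendrites, soma
geometry, type-specific arbor architecture, and database metadata.
Passing tests therefore demonstrate correctness of the computational
chain and its statistical behavior across the anisotropy range — not
that any particular biological population has a given FA.

## Problem sizes and determinism

The test suite and the results script run everything at the scales chosen
for the experiments they verify: the Watson sweeps at full scale (191 κ ×
10,000 cylinders per b-value), bundle closure and Gaussian-limit checks
at 2,000 cables, the random-walk ADC oracle at 10⁵ walkers (dt = 5 μs),
and the model-comparison population at 100 synthetic neurons of 1,500 μm
each.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence` counters), so every figure
and table regenerates bit-identically.

## Known limitations

- The Gaussian-limit tensor check is performed at b_max = 0.01 ms/μm²;
  at larger b the DTI fit's own cumulant bias (the effect under study)
  dominates the comparison.
- The GPD transverse ADC assumes a circular cross-section and the
  Gaussian phase approximation; at large r and strong gradients the GPD
  itself is an approximation, though excellent in the regime used here.
- Rejection sampling of the Watson distribution has acceptance ≈
  Z(κ)e^(−κ)/2 (≈ 2.5 % at κ = 20); fine for κ ≤ 200, inefficient far
  beyond.
- The kurtosis tensor is fitted unconstrained; no positivity or
  branch-cut constraints are imposed, matching the plain least-squares
  formulation.
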