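# neuritemri

Neurite orientation morphometry and diffusion-MRI signal simulation for
single-neuron reconstructions.

Diffusion MRI in gray matter is sensitive to the orientation distribution
of axons and dendrites. `neuritemri` implements the full chain from an SWC
neuron reconstruction to a predicted diffusion measurement, for anyone who
wants to test how faithfully a diffusion-tensor readout reports neurite
architecture when ground truth is known:

1. **Morphometry.** An SWC tree is interpolated at 1 μm, decomposed into
   unbranched paths, and reduced to N straight "average line" segments of
   common length l (default 10 μm) by orthogonal distance regression.
   Segment k has unit direction û_k, radius r_k, and volume-fraction
   weight w_k = r_k² / Σᵢ r_i².  The orientation **scatter matrix**

   T = Σ_k w_k û_k û_kᵀ,  trace(T) = 1,

   has eigenvalues τ₁ ≥ τ₂ ≥ τ₃ (mean 1/3), summarized by the fractional
   anisotropy FA_T = √(3/2 · Σ(τᵢ − τ̄)² / Στᵢ²).

2. **Signal simulation.** Each segment is an impermeable cylinder with
   longitudinal diffusivity D_L and a restricted transverse apparent
   diffusivity D_T(r) from the Gaussian-phase-distribution eigenmode
   series for a disc.  For a Stejskal–Tanner sequence (δ, Δ, b-values,
   63 gradient directions by electrostatic repulsion):

   S(n̂, b) = Σ_k w_k · e^(−b·D_T,k) · e^(−(û_k·n̂)² (D_L − D_T,k) b).

3. **Tensor fits.** Nonlinear least squares of the diffusion-tensor model
   S₀·e^(−b_ij D_ij) and the fourth-order cumulant (kurtosis) model
   S₀·e^(−b_ij D_ij − b_ij b_kl K̂_ijkl), with the explained variation
   1 − SS_res/SS_tot as goodness of fit.

4. **The Gaussian-regime prediction.** In the mono-exponential limit the
   diffusion and scatter eigenvalues are linearly related,
   λᵢ − λ̄ = D_A (τᵢ − τ̄) with D_A = D_L − D_T, equivalently
   FA_D·√(Σλᵢ²) = D_A·FA_T·√(Στᵢ²).  The package quantifies how restricted,
   non-Gaussian diffusion biases the measured FA_D **below** this
   prediction — including the headline experiment: 10,000 narrow cylinders
   with Watson-distributed axes, f(û) ∝ exp(κ(û·ẑ)²), swept over 191
   concentrations κ ∈ [1, 20] at several diffusion weightings.

A synthetic-morphology module (branching random-walk neurons with tunable
tropism; straight-cable Watson bundles) makes every stage testable without
downloading any reconstruction database.

## Worked example

```sh
python examples/watson_bias_sweep.py
```

prints (reduced sweep: 39 κ values, 2,000 cylinders):

```
b_max = 0.5 ms/um^2:  max |FA_D difference| = 0.0172  at observed FA_D = 0.632
b_max = 1.0 ms/um^2:  max |FA_D difference| = 0.0398  at observed FA_D = 0.639
b_max = 2.5 ms/um^2:  max |FA_D difference| = 0.1387  at observed FA_D = 0.648
```

Each line is the worst-case shortfall of the diffusion-tensor FA relative
to the scatter-matrix prediction over the κ sweep at that diffusion
weighting: at b = 0.5 ms/μm² the Gaussian approximation is accurate to
~0.02 FA units, while at b = 2.5 the tensor readout can understate
orientation anisotropy by ~0.14.  The other example scripts walk through
single-neuron morphometry (`scatter_from_reconstruction.py`), signal
simulation and both tensor fits (`simulate_and_fit.py`), the restricted
transverse ADC (`restricted_adc_table.py`), and the line-length
sensitivity check (`line_length_dependence.py`).

The same operations are available from a shell:

```sh
neuritemri synth --kind neuron --tropism 1.0 --out run
neuritemri scatter run/neuron.swc --out run
neuritemri watson-sweep --b-max 1.0 --out run
```

Every command writes CSV artifacts plus a `manifest.json` (configuration,
seed, version) from which the run can be reproduced bit-identically.

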