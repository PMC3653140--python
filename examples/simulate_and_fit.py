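"""Simulate a restricted-cylinder diffusion signal and fit both tensor models.

Builds a dispersed bundle of 10 μm cylinders (Watson κ = 5), synthesizes
the Stejskal–Tanner signal over 63 directions and b ∈ [0, 1] ms/μm², fits
the diffusion-tensor and cumulant (kurtosis) models, and compares both
against the eigenvalue prediction from the scatter matrix.
"""

import numpy as np

from neuritemri import (
    DiffusionParams,
    WatsonConfig,
    compare_scatter_diffusion,
    fit_dti,
    fit_kurtosis,
    generate_bundle,
    make_scheme,
    scatter_matrix,
    segments_from_tree,
    simulate_signal,
)
from neuritemri.dmri import transverse_adcs_for

bundle = generate_bundle(WatsonConfig(kappa=5.0, n_cylinders=2000, seed=4), radius=0.5)
segments = segments_from_tree(bundle, line_length=10.0)
scheme = make_scheme(n_dirs=63, b_values=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0), seed=0)
params = DiffusionParams(D_L=1.0, D0=1.0)

signal = simulate_signal(segments, scheme, params)
sm = scatter_matrix(segments)
d_a = params.D_L - float(np.sum(segments.weights * transverse_adcs_for(segments.radii, params, scheme)))

for label, fit in (("DTI", fit_dti(signal, scheme)), ("kurtosis", fit_kurtosis(signal, scheme))):
    res = compare_scatter_diffusion(sm, fit, D_A=d_a)
    print(
        f"{label:9s} lambda = {np.round(fit.eigenvalues, 4)}  "
        f"FA_D = {res.fa_d:.4f}  predicted = {res.fa_d_predicted:.4f}  "
        f"explained variation = {fit.explained_variation:.6f} ({res.fit_quality_class})"
    )
print()
print("The mono-exponential DTI model underestimates FA relative to the")
print("Gaussian-regime prediction D_A * FA_T * sqrt(sum tau^2 / sum lambda^2);")
print("the extra cumulant term absorbs the non-Gaussian decay and moves")
print("FA_D back toward the prediction.")
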