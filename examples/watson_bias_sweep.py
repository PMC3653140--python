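"""Quantify the Gaussian-approximation FA bias for dispersed cylinders.

Runs a reduced Watson concentration sweep (39 values of κ in [1, 20],
2,000 narrow cylinders each — the full-scale experiment uses 191 and
10,000) at three diffusion weightings and prints how far the observed
diffusion FA falls below the scatter-matrix prediction.
"""

from neuritemri import kappa_sweep

for b_max in (0.5, 1.0, 2.5):
    res = kappa_sweep(b_max=b_max, n_kappa=39, n_cylinders=2000, seed=0)
    print(
        f"b_max = {b_max:>3} ms/um^2:  max |FA_D difference| = "
        f"{res.max_abs_difference:.4f}  at observed FA_D = {res.fa_d_at_max:.3f}"
    )
print()
print("The bias is one-sided (observed FA_D <= predicted) and grows with b:")
print("stronger diffusion weighting exposes the non-mono-exponential decay")
print("of the dispersed-cylinder signal that the tensor model cannot follow.")
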