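"""Transverse apparent diffusivity of impermeable cylinders vs radius.

Evaluates the Gaussian-phase-distribution eigenmode series for restricted
diffusion in a circular cross-section at the default pulse timings
(δ = 10 ms, Δ = 20 ms, intrinsic D0 = 1 μm²/ms).
"""

from neuritemri import transverse_adc

print("radius (um)   D_T (um^2/ms)   D_T / D0")
for r in (0.1, 0.25, 0.5, 1.0, 2.0, 5.0):
    d_t = transverse_adc(r, D0=1.0, delta=10.0, Delta=20.0)
    print(f"{r:8.2f}   {d_t:12.6f}   {d_t:8.4f}")
print()
print("Thin neurites (r < 1 um) are nearly fully restricted across a 30 ms")
print("measurement: D_T is orders of magnitude below D0, which is why")
print("intra-neurite diffusion is so anisotropic. D_T grows toward D0 as the")
print("cross-section becomes large compared with the diffusion length.")
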