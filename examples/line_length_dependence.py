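"""Dependence of orientation anisotropy on the average-line length l.

Reduces one synthetic arbor to average lines at several l values and
tabulates the segment count and FA_T (plus the simulated-fit FA_D),
reproducing the weak-dependence check that justifies the default
l = 10 μm.
"""

from neuritemri import DiffusionParams, NeuronGenParams, generate_neuron, line_length_sweep, make_scheme

tree = generate_neuron(NeuronGenParams(tropism_strength=0.8, total_length=4000.0, seed=6))
scheme = make_scheme(n_dirs=63, b_values=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0), seed=0)
df = line_length_sweep(tree, lengths=[5, 10, 15, 20, 25], scheme=scheme, params=DiffusionParams())

print(df[["l", "n_segments", "fa_t", "fa_d", "excluded"]].to_string(index=False))
print()
print("FA_T and FA_D vary only weakly with l: longer average lines smooth")
print("out local wiggle (fewer, straighter segments, slightly higher FA).")
print("Trees yielding fewer than 100 segments at a given l are flagged")
print("'excluded' as too small for a reliable orientation statistic.")
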