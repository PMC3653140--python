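"""Regenerate the committed SWC fixtures and their golden morphometry values.

Run from the repository root:  python tests/data/regen_fixtures.py
All fixtures are synthetic (generated by neuritemri.synth / hand-written);
goldens freeze the pipeline's own output at line length 10 μm for
regression testing.
"""

import json
from pathlib import Path

import numpy as np

from neuritemri import (
    NeuronGenParams,
    WatsonConfig,
    decompose_paths,
    extract_segments,
    generate_bundle,
    generate_neuron,
    interpolate,
    parse_swc,
    scatter_matrix,
    write_swc,
)

HERE = Path(__file__).parent

# Hand-written toy with one bifurcation and one trifurcation (3 termini
# from the bifurcation side, 1 extra stem terminus): soma, two stems.
BRANCHED_TOY = """\
# synthetic toy arbor: soma, bifurcation, trifurcation
1 1 0 0 0 5 -1
2 3 0 0 6 1.2 1
3 3 0 0 14 1.0 2
4 3 5 0 20 0.8 3
5 3 -5 0 20 0.8 3
6 3 5 0 30 0.6 4
7 3 10 3 26 0.6 4
8 3 10 -3 26 0.6 4
9 4 0 7 0 1.0 1
10 4 0 15 0 0.9 9
"""

SINGLE_CABLE = """\
# synthetic single straight cable along z
1 3 0 0 0 0.8 -1
2 3 0 0 10 0.8 1
3 3 0 0 20 0.8 2
4 3 0 0 30 0.8 3
5 3 0 0 40 0.8 4
"""


def golden_for(tree, line_length=10.0):
    segs = extract_segments(decompose_paths(interpolate(tree, 1.0)), line_length)
    sm = scatter_matrix(segs)
    return {
        "n_segments": len(segs),
        "tau": [round(float(v), 12) for v in sm.eigenvalues],
        "fa_t": round(float(sm.fa), 12),
        "line_length": line_length,
    }


def main():
    (HERE / "single_cable.swc").write_text(SINGLE_CABLE)
    (HERE / "branched_toy.swc").write_text(BRANCHED_TOY)

    iso = generate_neuron(NeuronGenParams(tropism_strength=0.0, total_length=1000.0, seed=11))
    write_swc(iso, HERE / "isotropic_tree.swc", header="fixture: isotropic synthetic tree seed=11")

    aligned = generate_neuron(NeuronGenParams(tropism_strength=3.0, total_length=1000.0, seed=12))
    write_swc(aligned, HERE / "aligned_tree.swc", header="fixture: aligned synthetic tree seed=12")

    bundle = generate_bundle(WatsonConfig(kappa=5.0, n_cylinders=300, seed=13), cable_length=10.0, radius=0.5)
    write_swc(bundle, HERE / "bundle_k5.swc", header="fixture: synthetic watson bundle kappa=5 n=300 seed=13")

    goldens = {}
    for name in ("single_cable", "branched_toy", "isotropic_tree", "aligned_tree", "bundle_k5"):
        tree = parse_swc((HERE / f"{name}.swc").read_text(), name=name)
        goldens[name] = golden_for(tree)
    (HERE / "golden_morphometry.json").write_text(json.dumps(goldens, indent=1) + "\n")
    print("fixtures regenerated:", ", ".join(goldens))


if __name__ == "__main__":
    main()
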