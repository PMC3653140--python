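import json
from pathlib import Path

import numpy as np
import pytest

from neuritemri import (
    NeuronGenParams,
    decompose_paths,
    extract_segments,
    generate_neuron,
    interpolate,
    make_scheme,
    parse_swc,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def goldens() -> dict:
    return json.loads((DATA / "golden_morphometry.json").read_text())


@pytest.fixture(scope="session")
def fixture_trees(data_dir):
    return {
        name: parse_swc((data_dir / f"{name}.swc").read_text(), name=name)
        for name in ("single_cable", "branched_toy", "isotropic_tree", "aligned_tree", "bundle_k5")
    }


@pytest.fixture(scope="session")
def branched_toy(fixture_trees):
    return fixture_trees["branched_toy"]


@pytest.fixture(scope="session")
def small_scheme():
    """6-direction, 3-shell scheme: cheap but full-rank for tensor fits."""
    return make_scheme(n_dirs=6, b_values=(0.0, 0.5, 1.0), seed=7)


@pytest.fixture(scope="session")
def default_scheme():
    """The standard 63-direction, b ∈ [0, 1] ms/μm² acquisition."""
    return make_scheme(seed=0)


def segments_at(tree, l=10.0):
    return extract_segments(decompose_paths(interpolate(tree, 1.0)), l)


@pytest.fixture(scope="session")
def random_tree():
    return generate_neuron(NeuronGenParams(tropism_strength=0.5, total_length=800.0, seed=42))


def random_rotation(seed: int) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
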