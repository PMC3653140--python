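"""Synthetic neuron trees and cylinder bundles.

Stochastic stand-ins for curated reconstruction databases: a branching
random walk with a tunable directional bias ("tropism") generates
SWC-writable trees spanning the full anisotropy range, and straight-cable
bundles with Watson-drawn orientations mirror the dispersed-cylinder
experiment as an SWC fixture.  Both are deterministic per seed, and the
generator parameters are recorded in the SWC header for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .swc import APICAL_DENDRITE, BASAL_DENDRITE, SOMA, NeuronTree
from .watson import WatsonConfig, sample_watson

__all__ = ["NeuronGenParams", "generate_neuron", "generate_bundle"]


@dataclass
class NeuronGenParams:
    """Controls for the branching-random-walk neuron generator.

    tropism_strength biases every growth step toward ``tropism_axis``;
    0 gives an isotropic arbor and large values give near-straight cables,
    so expected FA_T increases monotonically with it.  Radii taper by
    ×0.95 at each branch point with a 0.2 μm floor, keeping the
    volume-fraction weights heterogeneous.
    """

    n_stems: int = 4
    branch_probability: float = 0.02  # per μm of grown cable
    segment_step: float = 2.0  # μm per growth step
    mean_branch_angle: float = 40.0  # deg
    tropism_strength: float = 0.0
    tropism_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    stem_radius: float = 1.0  # μm
    radius_taper: float = 0.95  # per branch point
    min_radius: float = 0.2  # μm
    wiggle: float = 0.35  # direction jitter per step (radians, sd)
    total_length: float = 2000.0  # μm cable budget
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.branch_probability <= 1):
            raise ValueError("branch_probability must be in [0, 1]")
        if self.segment_step <= 0 or self.total_length <= 0:
            raise ValueError("lengths must be positive")
        if self.n_stems < 1:
            raise ValueError("need at least one stem")
        self.tropism_axis = np.asarray(self.tropism_axis, float)
        self.tropism_axis = self.tropism_axis / np.linalg.norm(self.tropism_axis)


def _unit(v):
    return v / np.linalg.norm(v)


def _random_perp(rng, u):
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, u) * u
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def generate_neuron(params: NeuronGenParams) -> NeuronTree:
    """Grow a branching random-walk tree around a soma at the origin.

    Tips advance in steps of ``segment_step``; each step jitters the
    heading, pulls it toward the tropism axis, and may split the tip in
    two at ``branch_probability`` per μm.  Growth stops when the total
    cable budget is spent.
    """
    rng = np.random.default_rng(params.seed)
    soma_radius = 5.0
    ids = [1]
    types = [SOMA]
    xyz = [np.zeros(3)]
    radii = [soma_radius]
    parents = [-1]
    next_id = 2
    total = 0.0

    # active tips: (parent_id, position, direction, radius, type_code)
    tips = []
    for s in range(params.n_stems):
        d = _unit(rng.standard_normal(3))
        tcode = APICAL_DENDRITE if s == 0 else BASAL_DENDRITE
        tips.append((1, np.zeros(3) + d * soma_radius * 0.0, d, params.stem_radius, tcode))

    step = params.segment_step
    p_branch = min(1.0, params.branch_probability * step)
    while tips and total < params.total_length:
        # round-robin over tips keeps arbors balanced
        parent, pos, d, r, tcode = tips.pop(0)
        # jitter + tropism
        d = _unit(d + params.wiggle * rng.standard_normal(3) + params.tropism_strength * params.tropism_axis)
        pos = pos + d * step
        ids.append(next_id)
        types.append(tcode)
        xyz.append(pos)
        radii.append(r)
        parents.append(parent)
        node = next_id
        next_id += 1
        total += step
        if rng.random() < p_branch:
            # split: two children rotated away from the heading
            ang = np.deg2rad(params.mean_branch_angle) * (0.5 + rng.random())
            axis = _random_perp(rng, d)
            child_r = max(params.min_radius, r * params.radius_taper)
            for sign in (1.0, -1.0):
                dd = _unit(np.cos(ang / 2) * d + sign * np.sin(ang / 2) * axis)
                tips.append((node, pos, dd, child_r, tcode))
        else:
            tips.append((node, pos, d, r, tcode))

    return NeuronTree(
        ids=np.array(ids),
        type_codes=np.array(types),
        # 1e-6 μm grid keeps SWC text compact and round-trip exact
        xyz=np.round(np.array(xyz), 6),
        radii=np.round(np.array(radii), 6),
        parent_ids=np.array(parents),
        name=f"synthetic tropism={params.tropism_strength} seed={params.seed}",
    )


def generate_bundle(
    cfg: WatsonConfig, cable_length: float = 10.0, radius: float = 0.5
) -> NeuronTree:
    """n straight, unbranched, equal-radius cables with Watson orientations.

    Cable k runs from the lattice offset o_k to o_k + L·û_k (offsets only
    displace the cables; orientation statistics depend solely on û).  The
    morphometry pipeline applied at l = ``cable_length`` recovers exactly
    one segment per cable, so the scatter matrix equals the sample
    second-moment matrix of the drawn directions.
    """
    if cable_length <= 0 or radius <= 0:
        raise ValueError("cable_length and radius must be positive")
    u = sample_watson(cfg)
    n = len(u)
    spacing = 4.0 * max(radius, 1.0) + cable_length
    side = int(np.ceil(n ** (1 / 3)))
    ids, types, xyz, radii, parents = [], [], [], [], []
    nid = 1
    for k in range(n):
        ix, iy, iz = k % side, (k // side) % side, k // (side * side)
        origin = np.array([ix, iy, iz], float) * spacing
        ids += [nid, nid + 1]
        types += [BASAL_DENDRITE, BASAL_DENDRITE]
        xyz += [origin, origin + cable_length * u[k]]
        radii += [radius, radius]
        parents += [-1, nid]
        nid += 2
    return NeuronTree(
        ids=np.array(ids),
        type_codes=np.array(types),
        xyz=np.round(np.array(xyz), 6),
        radii=np.array(radii),
        parent_ids=np.array(parents),
        name=f"watson bundle kappa={cfg.kappa} n={n} seed={cfg.seed}",
    )
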