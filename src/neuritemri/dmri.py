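"""Stejskal–Tanner diffusion-MRI signal simulation for cylinder collections.

Each neurite segment is an equivalent impermeable cylinder with a
longitudinal diffusivity D_L along its axis and a restricted transverse
apparent diffusivity D_T(r) across it.  For a two-pulse gradient sequence
with pulse duration δ, separation Δ, and diffusion weighting
b = (Δ − δ/3) q², the intracellular signal is the volume-fraction-weighted
sum over the N cylinders

    S(n̂, b) = Σ_k w_k · exp(−b·D_T,k) · exp(−(û_k·n̂)² (D_L − D_T,k) b),

normalized so that S(b = 0) = 1.  D_T(r) follows the Gaussian-phase-
distribution (GPD) series for restricted 2-D self-diffusion in a circle
(Neumann eigenmodes of the disc; Bessel-derivative roots), evaluated at
the sequence timings.

Units: μm, ms, μm²/ms, b in ms/μm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import jnp_zeros

from .morphometry import LineSegmentSet

__all__ = [
    "AcquisitionScheme",
    "DiffusionParams",
    "SignalVector",
    "make_scheme",
    "generate_directions",
    "transverse_adc",
    "simulate_signal",
]

DEFAULT_B_VALUES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)  # ms/μm²
DEFAULT_N_DIRS = 63
DEFAULT_DELTA = 10.0  # pulse duration δ, ms
DEFAULT_DELTA_BIG = 20.0  # pulse separation Δ, ms


@dataclass
class AcquisitionScheme:
    """A flat table of diffusion measurements plus the pulse timings.

    ``bvals[i]`` and ``bvecs[i]`` describe measurement i; b = 0 rows carry
    a zero direction vector.  ``directions`` holds the unique nonzero-b
    gradient directions.
    """

    bvals: np.ndarray  # (M,) ms/μm²
    bvecs: np.ndarray  # (M, 3)
    delta: float  # δ, ms
    Delta: float  # Δ, ms
    directions: np.ndarray = field(default=None)

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, float)
        self.bvecs = np.asarray(self.bvecs, float).reshape(-1, 3)
        if self.delta <= 0 or self.Delta <= 0 or self.delta >= self.Delta:
            raise ValueError("require 0 < delta < Delta")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be nonnegative")
        if not np.any(self.bvals == 0):
            raise ValueError("scheme must include b = 0")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("nonzero-b directions must be unit vectors")
        if self.directions is None:
            self.directions = np.unique(np.round(self.bvecs[nz], 12), axis=0)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[self.bvals > 0])

    @property
    def diffusion_time(self) -> float:
        """Effective diffusion time Δ − δ/3 (ms), so q² = b / (Δ − δ/3)."""
        return self.Delta - self.delta / 3.0

    def to_text(self) -> str:
        """Gradient table: one 'nx ny nz b' row per measurement."""
        lines = [f"# delta={self.delta} Delta={self.Delta}", "# nx ny nz b"]
        for v, b in zip(self.bvecs, self.bvals):
            lines.append(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g} {b:.12g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AcquisitionScheme":
        delta, Delta = DEFAULT_DELTA, DEFAULT_DELTA_BIG
        vecs, bs = [], []
        for raw in text.splitlines():
            line = raw.strip()
            if line.startswith("#"):
                if "delta=" in line and "Delta=" in line:
                    parts = dict(p.split("=") for p in line[1:].split())
                    delta, Delta = float(parts["delta"]), float(parts["Delta"])
                continue
            if not line:
                continue
            x, y, z, b = (float(v) for v in line.split())
            vecs.append((x, y, z))
            bs.append(b)
        return cls(bvals=np.array(bs), bvecs=np.array(vecs), delta=delta, Delta=Delta)


@dataclass
class DiffusionParams:
    """Intracylinder diffusivities (μm²/ms).

    D_L acts along the cylinder axis; D0 is the intrinsic diffusivity
    governing the transverse restriction, so D_T(r) ≤ D0 and the
    anisotropic diffusivity is D_A = D_L − D_T.
    """

    D_L: float = 1.0
    D0: float = 1.0

    def __post_init__(self):
        if self.D_L <= 0 or self.D0 <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass
class SignalVector:
    """Simulated signal values aligned with an AcquisitionScheme's rows."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values <= 0):
            raise ValueError("signals must be positive")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Gradient directions by electrostatic repulsion


def generate_directions(n_dirs: int, seed: int = 0, n_iter: int = 2000) -> np.ndarray:
    """Deterministic electrostatic-repulsion point set on the half-sphere.

    Minimizes the Coulomb energy of the antipodally symmetrized set
    (Σ 1/‖v_i−v_j‖ + 1/‖v_i+v_j‖) by projected gradient descent from a
    seeded random start.  Same seed → identical table.
    """
    if n_dirs < 1:
        raise ValueError("n_dirs must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_dirs, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.05
    energy = _coulomb_energy(v)
    for _ in range(n_iter):
        F = _coulomb_forces(v)
        # project onto tangent plane and take a step
        F -= np.sum(F * v, axis=1, keepdims=True) * v
        v_new = v + step * F
        v_new /= np.linalg.norm(v_new, axis=1, keepdims=True)
        e_new = _coulomb_energy(v_new)
        if e_new < energy:
            v, energy = v_new, e_new
            step *= 1.05
        else:
            step *= 0.5
            if step < 1e-12:
                break
    # canonical hemisphere (z >= 0) for reproducible output
    flip = v[:, 2] < 0
    v[flip] *= -1
    return v


def _pairdiffs(v):
    d = v[:, None, :] - v[None, :, :]
    s = v[:, None, :] + v[None, :, :]
    return d, s


def _coulomb_energy(v) -> float:
    d, s = _pairdiffs(v)
    dn = np.linalg.norm(d, axis=-1)
    sn = np.linalg.norm(s, axis=-1)
    iu = np.triu_indices(len(v), k=1)
    return float(np.sum(1.0 / dn[iu]) + np.sum(1.0 / sn[iu]))


def _coulomb_forces(v) -> np.ndarray:
    d, s = _pairdiffs(v)
    dn = np.linalg.norm(d, axis=-1)
    sn = np.linalg.norm(s, axis=-1)
    np.fill_diagonal(dn, np.inf)
    np.fill_diagonal(sn, np.inf)
    fd = d / dn[..., None] ** 3
    fs = s / sn[..., None] ** 3
    return fd.sum(axis=1) + fs.sum(axis=1)


def make_scheme(
    n_dirs: int = DEFAULT_N_DIRS,
    b_values=DEFAULT_B_VALUES,
    delta: float = DEFAULT_DELTA,
    Delta: float = DEFAULT_DELTA_BIG,
    seed: int = 0,
    extra_directions=None,
) -> AcquisitionScheme:
    """Build the default acquisition: repulsion directions × b-shells + b=0.

    ``extra_directions`` appends exact directions (e.g. the principal axis
    and a perpendicular) to every nonzero shell.
    """
    if n_dirs < 6:
        raise ValueError("need at least 6 directions for tensor estimation")
    b_values = np.asarray(b_values, float)
    dirs = generate_directions(n_dirs, seed=seed)
    if extra_directions is not None:
        extra = np.atleast_2d(np.asarray(extra_directions, float))
        extra = extra / np.linalg.norm(extra, axis=1, keepdims=True)
        dirs = np.vstack([dirs, extra])
    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for b in b_values:
        if b == 0:
            continue
        for u in dirs:
            bvals.append(b)
            bvecs.append(u)
    return AcquisitionScheme(
        bvals=np.array(bvals), bvecs=np.array(bvecs), delta=delta, Delta=Delta, directions=dirs
    )


# ---------------------------------------------------------------------------
# Restricted transverse ADC (GPD series for an impermeable disc)


@lru_cache(maxsize=1)
def _bessel_prime_roots(n: int = 60) -> np.ndarray:
    """First n positive roots α_m of J1'(α) = 0."""
    return jnp_zeros(1, n)


def transverse_adc(
    r: float,
    D0: float = 1.0,
    delta: float = DEFAULT_DELTA,
    Delta: float = DEFAULT_DELTA_BIG,
    rtol: float = 1e-8,
    max_terms: int = 60,
) -> float:
    """Apparent transverse diffusivity for a cylinder of radius ``r`` (μm).

    Gaussian-phase-distribution attenuation for restricted diffusion in an
    impermeable circular cross-section under a two-pulse sequence:

        −ln S_⊥ = 2 γ²g² Σ_m  [2 D a_m² δ − 2 + 2e^{−D a_m² δ}
                   + 2e^{−D a_m² Δ} − e^{−D a_m²(Δ−δ)} − e^{−D a_m²(Δ+δ)}]
                   / (D² a_m⁶ (a_m² r² − 1)),

    with a_m = α_m/r and α_m the m-th root of J1'.  Since b = (γgδ)²(Δ−δ/3),
    D_T = −ln S_⊥ / b is independent of the gradient strength.  The series
    is truncated adaptively once a term changes the sum by less than
    ``rtol`` relatively.  D_T → 0 as r → 0 (full restriction) and → D0 in
    the short-time limit.
    """
    if r < 0 or D0 <= 0 or delta <= 0 or Delta <= 0 or delta >= Delta:
        raise ValueError("invalid inputs: need r >= 0, D0 > 0, 0 < delta < Delta")
    if r == 0:
        return 0.0
    roots = _bessel_prime_roots(max_terms)
    total = 0.0
    for alpha in roots:
        a2 = (alpha / r) ** 2
        x = D0 * a2
        num = (
            2 * x * delta
            - 2
            + 2 * np.exp(-x * delta)
            + 2 * np.exp(-x * Delta)
            - np.exp(-x * (Delta - delta))
            - np.exp(-x * (Delta + delta))
        )
        term = num / (D0**2 * a2**3 * (a2 * r * r - 1.0))
        total += term
        if total > 0 and abs(term) < rtol * abs(total):
            break
    # -ln S = 2 (q/δ)² total;  D_T = -ln S / b  with b = q² (Δ - δ/3)
    return float(2.0 * total / (delta**2 * (Delta - delta / 3.0)))


# ---------------------------------------------------------------------------
# Signal synthesis


def transverse_adcs_for(radii: np.ndarray, params: DiffusionParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Per-segment D_T, caching on unique radii."""
    radii = np.asarray(radii, float)
    uniq, inv = np.unique(radii, return_inverse=True)
    vals = np.array([transverse_adc(r, params.D0, scheme.delta, scheme.Delta) for r in uniq])
    return vals[inv]


def simulate_signal(
    segments: LineSegmentSet,
    scheme: AcquisitionScheme,
    params: DiffusionParams = DiffusionParams(),
) -> SignalVector:
    """Weighted cylinder-sum signal for every measurement in the scheme.

    S(b=0) = Σ w_k = 1 exactly; each nonzero-b measurement decays by the
    transverse restriction and the squared projection onto the gradient.
    """
    if len(segments) == 0:
        raise ValueError("empty segment set")
    D_T = transverse_adcs_for(segments.radii, params, scheme)  # (N,)
    if np.any(D_T > params.D0 + 1e-12):
        raise ValueError("transverse ADC exceeds intrinsic diffusivity")
    proj2 = (segments.directions @ scheme.bvecs.T) ** 2  # (N, M)
    b = scheme.bvals[None, :]  # (1, M)
    ln_att = -b * D_T[:, None] - proj2 * (params.D_L - D_T)[:, None] * b
    S = segments.weights @ np.exp(ln_att)
    return SignalVector(values=S)
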