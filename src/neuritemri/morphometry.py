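"""Orientation morphometry: average lines, the scatter matrix T, and FA_T.

An interpolated arbor is reduced to N straight "average line" segments of a
common length l (default 10 μm) by orthogonal distance regression on
consecutive runs of path coordinates.  Segment k carries a unit direction
û_k and a cross-sectional radius r_k; its weight is the cylinder volume
fraction w_k = r_k²/Σ r_i² (the shared length cancels).  The scatter
matrix

    T = Σ_k w_k û_k û_kᵀ

is symmetric, positive semidefinite, and has unit trace, so its
eigenvalues τ_1 ≥ τ_2 ≥ τ_3 average to 1/3.  Fractional anisotropy of any
eigenvalue triple e is

    FA = sqrt(3/2 · Σ(e_i − ē)² / Σ e_i²),

applied identically to τ (FA_T) and to diffusion-tensor eigenvalues
(FA_D, Basser–Pierpaoli).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .swc import NeuronTree, UnbranchedPath, decompose_paths, interpolate

__all__ = [
    "LineFit",
    "LineSegmentSet",
    "ScatterMatrix",
    "fit_line_odr",
    "extract_segments",
    "scatter_matrix",
    "fa_from_eigenvalues",
    "segments_from_tree",
    "line_length_sweep",
]

DEFAULT_LINE_LENGTH = 10.0  # μm
DEFAULT_MIN_SEGMENTS = 100


class LineFit(NamedTuple):
    direction: np.ndarray  # unit 3-vector
    centroid: np.ndarray  # 3-vector
    degenerate: bool  # top two moments indistinguishable


@dataclass
class LineSegmentSet:
    """N oriented line segments of shared length with volume-fraction weights."""

    directions: np.ndarray  # (N, 3), unit rows
    radii: np.ndarray  # (N,)
    length: float  # shared l, μm
    weights: np.ndarray  # (N,), sums to 1

    def __post_init__(self):
        self.directions = np.atleast_2d(np.asarray(self.directions, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if len(self) == 0:
            return
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("directions must be unit vectors")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return self.directions.shape[0]

    @classmethod
    def from_radii(cls, directions, radii, length) -> "LineSegmentSet":
        radii = np.atleast_1d(np.asarray(radii, float))
        w = radii**2 / np.sum(radii**2)
        return cls(directions=directions, radii=radii, length=float(length), weights=w)


@dataclass
class ScatterMatrix:
    """Trace-1 orientation second-moment matrix with sorted eigenvalues."""

    matrix: np.ndarray  # (3, 3)
    eigenvalues: np.ndarray  # τ_1 ≥ τ_2 ≥ τ_3
    eigenvectors: np.ndarray  # columns matching eigenvalues

    @property
    def fa(self) -> float:
        return fa_from_eigenvalues(self.eigenvalues)

    @property
    def mean_eigenvalue(self) -> float:
        return float(self.eigenvalues.mean())


def fit_line_odr(points: Sequence) -> LineFit:
    """Orthogonal-distance-regression line through 3-D points.

    The best-fit direction minimizes the summed squared perpendicular
    distances, i.e. it is the principal axis of the centered second-moment
    matrix.  Sign convention: nonnegative z component, ties broken by
    nonnegative y then x.  If the two largest moments coincide (a planar-
    or point-symmetric configuration) the direction is not unique; the
    eigenvector returned by the symmetric solver is kept and the fit is
    flagged degenerate.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    c = pts.mean(axis=0)
    X = pts - c
    M = X.T @ X
    if np.allclose(M, 0.0):
        raise ValueError("all points coincident; direction undefined")
    evals, evecs = np.linalg.eigh(M)  # ascending
    direction = evecs[:, -1]
    scale = max(evals[-1], 1e-300)
    degenerate = (evals[-1] - evals[-2]) / scale < 1e-9
    direction = _canonical_sign(direction)
    return LineFit(direction=direction, centroid=c, degenerate=bool(degenerate))


def _canonical_sign(u: np.ndarray) -> np.ndarray:
    for comp in (2, 1, 0):
        if abs(u[comp]) > 1e-12:
            return u if u[comp] > 0 else -u
    return np.abs(u)


def extract_segments(
    paths: Sequence[UnbranchedPath],
    line_length: float = DEFAULT_LINE_LENGTH,
) -> LineSegmentSet:
    """Reduce unbranched paths to average line segments of length ``line_length``.

    Walking each path from its first coordinate, consecutive points are
    accumulated until the cumulative polyline length reaches l; an ODR line
    fitted to the run yields one segment whose radius is the mean node
    radius over the run.  The next run starts at the closing point.
    Terminal leftovers spanning less than l are discarded.  Paths shorter
    than l contribute nothing; an empty result is returned as an empty set.
    """
    if line_length <= 0:
        raise ValueError("line_length must be positive")
    dirs, rads = [], []
    tol = 1e-4  # μm; absorbs text-roundtrip rounding of path coordinates
    for path in paths:
        steps = np.linalg.norm(np.diff(path.coords, axis=0), axis=1)
        start = 0
        acc = 0.0
        for i, s in enumerate(steps):
            acc += s
            if acc >= line_length - tol:
                run = slice(start, i + 2)  # includes closing point i+1
                fit = fit_line_odr(path.coords[run])
                dirs.append(fit.direction)
                rads.append(float(np.mean(path.radii[run])))
                start = i + 1
                acc = 0.0
    if not dirs:
        return LineSegmentSet(
            directions=np.empty((0, 3)),
            radii=np.empty(0),
            length=float(line_length),
            weights=np.empty(0),
        )
    return LineSegmentSet.from_radii(np.array(dirs), np.array(rads), line_length)


def scatter_matrix(segments: LineSegmentSet) -> ScatterMatrix:
    """Volume-weighted orientation scatter matrix T = Σ w_k û_k û_kᵀ.

    Built from rows sqrt(w_k)·û_kᵀ so that trace(T) = Σ w_k = 1 and the
    eigenvalue mean is 1/3 by construction.
    """
    if len(segments) < 1:
        raise ValueError("need at least one segment")
    S = np.sqrt(segments.weights)[:, None] * segments.directions
    T = S.T @ S
    T = 0.5 * (T + T.T)
    evals, evecs = np.linalg.eigh(T)
    order = np.argsort(evals)[::-1]
    return ScatterMatrix(matrix=T, eigenvalues=evals[order], eigenvectors=evecs[:, order])


def fa_from_eigenvalues(e) -> float:
    """Fractional anisotropy sqrt(3/2 · Σ(e_i − ē)²/Σ e_i²) of a 3-triple."""
    e = np.asarray(e, float)
    if e.shape != (3,):
        raise ValueError("expected 3 eigenvalues")
    ss = float(np.sum(e * e))
    if ss == 0.0:
        raise ValueError("all-zero eigenvalues: FA undefined")
    return float(np.sqrt(1.5 * np.sum((e - e.mean()) ** 2) / ss))


def segments_from_tree(
    tree: NeuronTree,
    line_length: float = DEFAULT_LINE_LENGTH,
    interp_step: float = 1.0,
    neurite_types=None,
    soma_attachment: str = "centroid",
) -> LineSegmentSet:
    """Full preprocessing chain: interpolate → paths → average lines."""
    kwargs = {}
    if neurite_types is not None:
        kwargs["neurite_types"] = neurite_types
    paths = decompose_paths(interpolate(tree, interp_step), soma_attachment=soma_attachment, **kwargs)
    return extract_segments(paths, line_length)


def line_length_sweep(
    tree: NeuronTree,
    lengths: Sequence[float] = tuple(range(5, 26)),
    scheme=None,
    params=None,
    interp_step: float = 1.0,
    min_segments: int = DEFAULT_MIN_SEGMENTS,
) -> pd.DataFrame:
    """FA as a function of the average-line length l.

    For each l the tree is reduced to segments, the scatter matrix FA_T is
    computed, and — when an acquisition ``scheme`` and diffusion ``params``
    are supplied — a diffusion signal is simulated and fitted with the
    diffusion-tensor model to yield FA_D.  Trees yielding fewer than
    ``min_segments`` segments at a given l are flagged ``excluded``
    (too few lines for a reliable orientation statistic).
    """
    from .dmri import simulate_signal
    from .tensors import fit_dti

    interp = interpolate(tree, interp_step)
    paths = decompose_paths(interp)
    rows = []
    for l in lengths:
        segs = extract_segments(paths, l)
        n = len(segs)
        row = {"l": float(l), "n_segments": n, "excluded": n < min_segments}
        if n >= 1:
            sm = scatter_matrix(segs)
            row.update(
                tau1=sm.eigenvalues[0],
                tau2=sm.eigenvalues[1],
                tau3=sm.eigenvalues[2],
                fa_t=sm.fa,
            )
            if scheme is not None and params is not None:
                sig = simulate_signal(segs, scheme, params)
                fit = fit_dti(sig, scheme)
                row["fa_d"] = fit.fa
        rows.append(row)
    return pd.DataFrame(rows)
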