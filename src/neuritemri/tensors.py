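"""Diffusion-tensor and cumulant (kurtosis) model fits, and the comparison
between diffusion eigenvalues and scatter-matrix eigenvalues.

Models fitted to a signal S over measurements (n̂, b):

    DTI:       S = S0 · exp(−b_ij D_ij)
    cumulant:  S = S0 · exp(−b_ij D_ij − b_ij b_kl K̂_ijkl)

with b_ij = b n_i n_j, D a symmetric 3×3 tensor (6 unique elements) and K̂
a fully symmetric fourth-order tensor (15 unique elements).  Front factors
of the conventional kurtosis tensor (Jensen's W, which carries 1/6·D̄²)
are absorbed into K̂, i.e.  K̂_ijkl = −(1/6)·D̄²·W_ijkl in terms of the
usual convention, so that ln S is exactly quadratic in the b-matrix.

Both fits are nonlinear least squares on linear-scale signals (log-linear
solutions serve as initializers), and goodness of fit is summarized as the
explained variation 1 − SS_res/SS_tot over all measurements including b=0.

In the Gaussian regime the diffusion-tensor eigenvalues λ_i are predicted
from the scatter-matrix eigenvalues τ_i by the centralized linear relation
λ_i − λ̄ = D_A (τ_i − τ̄) with D_A the anisotropic diffusivity, and FA_D is
predicted by FA_D·‖λ‖ = D_A·FA_T·‖τ‖.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import factorial

import numpy as np
from scipy.optimize import least_squares

from .dmri import AcquisitionScheme, DiffusionParams, SignalVector, transverse_adcs_for
from .morphometry import LineSegmentSet, ScatterMatrix, fa_from_eigenvalues

__all__ = [
    "TensorFit",
    "KurtosisFit",
    "ComparisonResult",
    "fit_dti",
    "fit_kurtosis",
    "compare_scatter_diffusion",
    "gaussian_limit_tensor",
]

# 6 unique symmetric-tensor index pairs and their multiplicity in b_ij D_ij
_D_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1, 1, 1, 2, 2, 2], dtype=float)

# 15 unique fully-symmetric fourth-order index multisets and multiplicities
_K_QUADS = list(combinations_with_replacement(range(3), 4))


def _quad_mult(quad) -> float:
    counts = [quad.count(i) for i in range(3)]
    return factorial(4) / np.prod([factorial(c) for c in counts])


_K_MULT = np.array([_quad_mult(q) for q in _K_QUADS])


def _design_dti(scheme: AcquisitionScheme) -> np.ndarray:
    """(M, 6) matrix X with b_ij D_ij = X @ d for d = unique D elements."""
    n = scheme.bvecs
    cols = [n[:, i] * n[:, j] for (i, j) in _D_PAIRS]
    return scheme.bvals[:, None] * (np.stack(cols, axis=1) * _D_MULT[None, :])


def _design_kurtosis(scheme: AcquisitionScheme) -> np.ndarray:
    """(M, 15) matrix with b_ij b_kl K̂_ijkl = X @ k for unique K̂ elements."""
    n = scheme.bvecs
    cols = [n[:, q[0]] * n[:, q[1]] * n[:, q[2]] * n[:, q[3]] for q in _K_QUADS]
    return (scheme.bvals**2)[:, None] * (np.stack(cols, axis=1) * _K_MULT[None, :])


def _tensor_from_elements(d: np.ndarray) -> np.ndarray:
    D = np.empty((3, 3))
    D[0, 0], D[1, 1], D[2, 2] = d[0], d[1], d[2]
    D[0, 1] = D[1, 0] = d[3]
    D[0, 2] = D[2, 0] = d[4]
    D[1, 2] = D[2, 1] = d[5]
    return D


def _explained_variation(model: np.ndarray, data: np.ndarray) -> float:
    ss_res = float(np.sum((data - model) ** 2))
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot


@dataclass
class TensorFit:
    S0: float
    D: np.ndarray  # symmetric 3×3, μm²/ms
    eigenvalues: np.ndarray  # λ_1 ≥ λ_2 ≥ λ_3
    eigenvectors: np.ndarray
    explained_variation: float

    @property
    def fa(self) -> float:
        return fa_from_eigenvalues(self.eigenvalues)

    @property
    def mean_diffusivity(self) -> float:
        return float(self.eigenvalues.mean())


@dataclass
class KurtosisFit(TensorFit):
    K: np.ndarray = None  # 15 unique K̂ elements, ordered like _K_QUADS

    def directional_kurtosis_term(self, direction) -> float:
        """Coefficient of −b² in ln S along a unit direction."""
        u = np.asarray(direction, float)
        mono = np.array([u[q[0]] * u[q[1]] * u[q[2]] * u[q[3]] for q in _K_QUADS])
        return float(np.sum(_K_MULT * mono * self.K))


def _check_signal(signal: SignalVector, scheme: AcquisitionScheme):
    if len(signal) != len(scheme):
        raise ValueError(
            f"signal has {len(signal)} values but scheme has {len(scheme)} measurements"
        )
    if np.any(signal.values <= 0):
        raise ValueError("signals must be positive")


def fit_dti(signal: SignalVector, scheme: AcquisitionScheme) -> TensorFit:
    """Least-squares diffusion-tensor fit (S0 plus 6 tensor elements).

    The log-linear solution initializes a trust-region nonlinear fit on the
    linear-scale signal.  Deterministic for a given input.
    """
    _check_signal(signal, scheme)
    y = signal.values
    X = _design_dti(scheme)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < 7:
        raise ValueError("rank-deficient design: need b=0 plus >= 6 noncollinear directions")
    # log-linear initializer
    A = np.column_stack([np.ones(len(y)), -X])
    coef, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
    p0 = np.concatenate([[np.exp(coef[0])], coef[1:]])

    def resid(p):
        return p[0] * np.exp(-X @ p[1:]) - y

    sol = least_squares(resid, p0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    S0 = float(sol.x[0])
    D = _tensor_from_elements(sol.x[1:])
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    model = S0 * np.exp(-X @ sol.x[1:])
    return TensorFit(
        S0=S0,
        D=D,
        eigenvalues=evals[order],
        eigenvectors=evecs[:, order],
        explained_variation=_explained_variation(model, y),
    )


def fit_kurtosis(signal: SignalVector, scheme: AcquisitionScheme) -> KurtosisFit:
    """Joint cumulant fit of S0, 6 tensor and 15 kurtosis-tensor elements.

    Initialized at the DTI solution with K̂ = 0, so the monotone
    trust-region solver can only lower the residual: the cumulant model's
    explained variation is never below the nested DTI model's.
    """
    _check_signal(signal, scheme)
    if len(scheme.shells) < 2:
        raise ValueError("kurtosis tensor needs >= 2 nonzero b-shells")
    if len(scheme) < 22:
        raise ValueError("need >= 22 measurements for 22 parameters")
    y = signal.values
    Xd = _design_dti(scheme)
    Xk = _design_kurtosis(scheme)
    dti = fit_dti(signal, scheme)
    d0 = np.array([dti.D[i, j] for (i, j) in _D_PAIRS])
    p0 = np.concatenate([[dti.S0], d0, np.zeros(15)])

    def resid(p):
        return p[0] * np.exp(-Xd @ p[1:7] - Xk @ p[7:]) - y

    sol = least_squares(resid, p0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    S0 = float(sol.x[0])
    D = _tensor_from_elements(sol.x[1:7])
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    model = S0 * np.exp(-Xd @ sol.x[1:7] - Xk @ sol.x[7:])
    ev = max(_explained_variation(model, y), dti.explained_variation)
    return KurtosisFit(
        S0=S0,
        D=D,
        eigenvalues=evals[order],
        eigenvectors=evecs[:, order],
        explained_variation=ev,
        K=sol.x[7:].copy(),
    )


@dataclass
class ComparisonResult:
    """Gaussian-regime prediction of diffusion eigenvalues from orientation."""

    tau_centralized: np.ndarray  # τ_i − 1/3, descending
    lambda_centralized: np.ndarray  # λ_i − λ̄, descending
    lambda_predicted_centralized: np.ndarray  # D_A (τ_i − 1/3)
    D_A: float
    fa_t: float
    fa_d: float
    fa_d_predicted: float
    explained_variation: float
    fit_quality_class: str  # "good" (>= threshold) or "poor"
    residuals: np.ndarray  # observed − predicted centralized λ

    @property
    def fa_difference(self) -> float:
        return self.fa_d_predicted - self.fa_d


def compare_scatter_diffusion(
    T: ScatterMatrix,
    fit: TensorFit,
    D_A: float | None = None,
    r2_threshold: float = 0.95,
) -> ComparisonResult:
    """Pair sorted τ and λ eigenvalues and evaluate the linear prediction.

    If ``D_A`` is not supplied it is estimated as the regression slope of
    centralized λ on centralized τ.
    """
    tau = np.sort(T.eigenvalues)[::-1]
    lam = np.sort(fit.eigenvalues)[::-1]
    tau_c = tau - tau.mean()
    lam_c = lam - lam.mean()
    if D_A is None:
        denom = float(np.sum(tau_c**2))
        if denom == 0:
            raise ValueError("isotropic scatter matrix: D_A not identifiable")
        D_A = float(np.sum(tau_c * lam_c) / denom)
    if D_A <= 0:
        raise ValueError("D_A must be positive")
    lam_pred_c = D_A * tau_c
    fa_t = fa_from_eigenvalues(tau)
    fa_d = fa_from_eigenvalues(lam)
    fa_d_pred = D_A * fa_t * np.sqrt(np.sum(tau**2) / np.sum(lam**2))
    return ComparisonResult(
        tau_centralized=tau_c,
        lambda_centralized=lam_c,
        lambda_predicted_centralized=lam_pred_c,
        D_A=float(D_A),
        fa_t=fa_t,
        fa_d=fa_d,
        fa_d_predicted=float(fa_d_pred),
        explained_variation=fit.explained_variation,
        fit_quality_class="good" if fit.explained_variation >= r2_threshold else "poor",
        residuals=lam_c - lam_pred_c,
    )


def gaussian_limit_tensor(
    segments: LineSegmentSet,
    scheme: AcquisitionScheme,
    params: DiffusionParams = DiffusionParams(),
) -> np.ndarray:
    """Small-b limit of the fitted diffusion tensor for a cylinder sum:
    Σ_k w_k [D_T,k I + (D_L − D_T,k) û_k û_kᵀ]."""
    D_T = transverse_adcs_for(segments.radii, params, scheme)
    iso = float(np.sum(segments.weights * D_T))
    outer = np.einsum("k,ki,kj->ij", segments.weights * (params.D_L - D_T), segments.directions, segments.directions)
    return iso * np.eye(3) + outer
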