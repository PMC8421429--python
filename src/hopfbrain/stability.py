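"""Linear stability of the coupled network at the silent fixed point z = 0.

The cubic term contributes nothing to the linearization, so fluctuations
around z = 0 obey d(dz)/dt = A dz with the N x N complex Jacobian

    A = diag(a - g S + i omega) + g C.

All eigenvalues having negative real part means the fixed point is stable;
the most negative real parts ("deepest" modes) are the most stable
directions, and on core-periphery connectomes those modes load on the hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .exceptions import InvalidArgumentError
from .hopf import HopfModelSpec


def build_jacobian(spec: HopfModelSpec) -> np.ndarray:
    """Jacobian A = diag(a - g S + i omega) + g C of the fixed point z = 0.

    In effective mode ``spec.a`` already holds a_eff = a - g S, so the
    diagonal is a_eff + i omega directly.
    """
    if spec.effective_mode:
        diag = spec.a + 1j * spec.omega
    else:
        diag = spec.a - spec.g * spec.strengths + 1j * spec.omega
    return np.diag(diag) + spec.g * spec.C.astype(complex)


@dataclass
class StabilityResult:
    """Sorted eigen-decomposition of the Jacobian.

    ``eigenvalues`` ascend by real part; column k of
    ``eigenvector_magnitudes`` holds |components| of the k-th (unit-norm)
    eigenvector; ``stable`` is True iff every eigenvalue has negative real
    part.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    eigenvector_magnitudes: np.ndarray
    stable: bool


def eigendecompose_sorted(A: np.ndarray) -> StabilityResult:
    """Eigen-decompose, sort ascending by Real(lambda), fix vector phases.

    Each eigenvector is normalized to unit Euclidean norm with its
    largest-magnitude component rotated to be real-positive, making the
    reported vectors reproducible up to the decomposition's numerics.
    """
    A = np.asarray(A, dtype=complex)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidArgumentError("Jacobian must be square")
    eigvals, eigvecs = np.linalg.eig(A)
    order = np.argsort(eigvals.real, kind="stable")
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvecs = eigvecs / np.linalg.norm(eigvecs, axis=0, keepdims=True)
    # phase fix: largest-magnitude component real-positive
    lead = np.argmax(np.abs(eigvecs), axis=0)
    phases = eigvecs[lead, np.arange(eigvecs.shape[1])]
    eigvecs = eigvecs * np.exp(-1j * np.angle(phases))[None, :]
    return StabilityResult(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        eigenvector_magnitudes=np.abs(eigvecs),
        stable=bool(np.max(eigvals.real) < 0),
    )


@dataclass
class HubStabilitySummary:
    """How strongly node strength predicts loading on the most stable modes."""

    correlations: np.ndarray
    min_real_eigenvalue: float
    k_dominant: int


def hub_stability_summary(
    result: StabilityResult,
    strengths: np.ndarray,
    k_dominant: int = 5,
) -> HubStabilitySummary:
    """Pearson correlation of eigenvector magnitude with node strength.

    Computed for the ``k_dominant`` most stable eigenvectors (lowest real
    parts, i.e. the first columns of the sorted decomposition), together
    with the stability depth min Real(lambda).
    """
    strengths = np.asarray(strengths, dtype=float)
    n = result.eigenvalues.size
    if not 1 <= k_dominant <= n:
        raise InvalidArgumentError(f"k_dominant must be in [1, {n}]")
    if np.ptp(strengths) == 0:
        raise InvalidArgumentError("constant strengths: correlation undefined")
    corr = np.array(
        [
            pearsonr(result.eigenvector_magnitudes[:, k], strengths).statistic
            for k in range(k_dominant)
        ]
    )
    return HubStabilitySummary(
        correlations=corr,
        min_real_eigenvalue=float(result.eigenvalues.real.min()),
        k_dominant=k_dominant,
    )


def stability_of_spec(spec: HopfModelSpec) -> StabilityResult:
    """Convenience: Jacobian + sorted eigendecomposition in one call."""
    return eigendecompose_sorted(build_jacobian(spec))
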