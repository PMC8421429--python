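"""Structural-connectome graph analysis.

Strength, hub detection, weighted k-density (rich-club) curves, hub vs
non-hub link weights, and the symmetrization / normalization applied to raw
tractography count matrices. All functions operate on square, symmetric,
non-negative weight matrices with zero diagonal ("SC matrices").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGraphError, InvalidArgumentError

#: Default hub threshold on the node-strength scale of tractography-derived,
#: fibre-count-normalized connectomes. On other normalizations the threshold
#: must be chosen on that matrix's own strength scale.
HUB_STRENGTH_THRESHOLD = 4.5

#: Maximum link weight the whole-brain model expects after scaling; chosen so
#: the coupled oscillator network cannot fully synchronize.
MODEL_MAX_WEIGHT = 0.2


def validate_sc(C: np.ndarray, *, atol: float = 1e-9) -> np.ndarray:
    """Validate an SC matrix: square, symmetric, non-negative, zero diagonal.

    Returns the matrix as a float ndarray; raises InvalidArgumentError on any
    violation.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InvalidArgumentError(f"SC matrix must be square, got shape {C.shape}")
    if not np.all(np.isfinite(C)):
        raise InvalidArgumentError("SC matrix contains non-finite entries")
    if np.min(C) < -atol:
        raise InvalidArgumentError("SC matrix has negative weights")
    if not np.allclose(C, C.T, atol=atol):
        raise InvalidArgumentError("SC matrix is not symmetric")
    if np.max(np.abs(np.diag(C))) > atol:
        raise InvalidArgumentError("SC matrix must have a zero diagonal")
    return C


def node_strengths(C: np.ndarray) -> np.ndarray:
    """Node strength S_j: the sum of the connection weights of each node."""
    C = validate_sc(C)
    return C.sum(axis=1)


def detect_hubs(strengths: np.ndarray, threshold: float = HUB_STRENGTH_THRESHOLD) -> np.ndarray:
    """Indices of hub nodes: nodes with strength strictly above ``threshold``."""
    strengths = np.asarray(strengths, dtype=float)
    return np.flatnonzero(strengths > threshold)


@dataclass
class KDensityCurve:
    """Weighted rich-club curve rho(S') over a grid of strength thresholds.

    ``rho`` is NaN past the cutoff (fewer than two surviving nodes);
    ``cutoff`` is the first grid threshold at which the curve is undefined,
    or None if it is defined on the whole grid.
    """

    thresholds: np.ndarray
    rho: np.ndarray
    cutoff: float | None = None


def k_density(
    C: np.ndarray,
    s_max: float = 10.0,
    step: float = 0.2,
    *,
    include_zero_weights: bool = True,
) -> KDensityCurve:
    """Weighted k-density curve: mean link weight among nodes stronger than S'.

    For each threshold S' on the grid 0..s_max (step ``step``), restrict to
    nodes with strength S > S' (strengths computed once on the full matrix;
    at S' = 0 every node survives, so rho(0) is the global mean off-diagonal
    weight) and average the off-diagonal weights among the survivors. By
    default the average runs over all surviving pairs including zero-weight
    entries (a weighted density); with ``include_zero_weights=False`` only
    existing (non-zero) links are averaged.
    """
    if step <= 0:
        raise InvalidArgumentError(f"step must be positive, got {step}")
    C = validate_sc(C)
    S = C.sum(axis=1)
    grid = np.arange(0.0, s_max + 0.5 * step, step)
    rho = np.full(grid.shape, np.nan)
    cutoff = None
    for i, thr in enumerate(grid):
        keep = S > thr if thr > 0 else np.ones_like(S, dtype=bool)
        if keep.sum() < 2:
            if cutoff is None:
                cutoff = float(thr)
            continue
        sub = C[np.ix_(keep, keep)]
        off = sub[~np.eye(sub.shape[0], dtype=bool)]
        if not include_zero_weights:
            off = off[off > 0]
            if off.size == 0:
                if cutoff is None:
                    cutoff = float(thr)
                continue
        rho[i] = off.mean()
    return KDensityCurve(thresholds=grid, rho=rho, cutoff=cutoff)


def hub_vs_nonhub_weights(C: np.ndarray, hub_indices: np.ndarray) -> tuple[float, float]:
    """Mean off-diagonal weight within the hub set and within the non-hub set.

    A class with fewer than two members has no internal links; its mean is
    returned as NaN with a warning.
    """
    C = validate_sc(C)
    n = C.shape[0]
    hubs = np.asarray(hub_indices, dtype=int)
    nonhubs = np.setdiff1d(np.arange(n), hubs)

    def _class_mean(idx: np.ndarray, label: str) -> float:
        if idx.size < 2:
            warnings.warn(f"{label} class has < 2 members; mean weight undefined")
            return float("nan")
        sub = C[np.ix_(idx, idx)]
        return float(sub[~np.eye(idx.size, dtype=bool)].mean())

    return _class_mean(hubs, "hub"), _class_mean(nonhubs, "non-hub")


def scale_to_max(C: np.ndarray, max_weight: float = MODEL_MAX_WEIGHT) -> np.ndarray:
    """Linearly rescale so the maximum entry equals ``max_weight`` exactly."""
    C = np.asarray(C, dtype=float)
    peak = C.max()
    if peak <= 0:
        raise DegenerateGraphError("cannot scale an all-zero matrix")
    out = C * (max_weight / peak)
    # guarantee the exact maximum despite rounding
    out[out == out.max()] = max_weight
    return out


def symmetrize_and_normalize(C_raw: np.ndarray, *, model_scale: bool = False) -> np.ndarray:
    """Turn a raw (possibly asymmetric) non-negative count matrix into an SC.

    Steps: average with the transpose, zero the diagonal, divide by the total
    weight of the network, and — when ``model_scale`` — linearly rescale so
    the maximum entry is exactly ``MODEL_MAX_WEIGHT``.
    """
    C_raw = np.asarray(C_raw, dtype=float)
    if C_raw.ndim != 2 or C_raw.shape[0] != C_raw.shape[1]:
        raise InvalidArgumentError(f"matrix must be square, got shape {C_raw.shape}")
    if np.min(C_raw) < 0:
        raise InvalidArgumentError("matrix has negative entries")
    C = 0.5 * (C_raw + C_raw.T)
    np.fill_diagonal(C, 0.0)
    total = C.sum()
    if total <= 0:
        raise DegenerateGraphError("all-zero connectivity matrix")
    C = C / total
    if model_scale:
        C = scale_to_max(C)
    return C


@dataclass
class GraphSummary:
    """Descriptive structural-graph summary of one connectome."""

    strengths: np.ndarray
    hub_indices: np.ndarray
    k_density_curve: KDensityCurve
    hub_mean_weight: float
    nonhub_mean_weight: float
    hub_threshold: float = HUB_STRENGTH_THRESHOLD
    extras: dict = field(default_factory=dict)


def graph_summary(
    C: np.ndarray,
    *,
    hub_threshold: float = HUB_STRENGTH_THRESHOLD,
    s_max: float | None = None,
    k_step: float = 0.2,
) -> GraphSummary:
    """Compute the full structural summary (strengths, hubs, rich-club curve)."""
    C = validate_sc(C)
    S = C.sum(axis=1)
    hubs = detect_hubs(S, hub_threshold)
    if s_max is None:
        s_max = max(10.0, float(S.max()))
    curve = k_density(C, s_max=s_max, step=k_step)
    if hubs.size >= 2 and (C.shape[0] - hubs.size) >= 2:
        hub_w, nonhub_w = hub_vs_nonhub_weights(C, hubs)
    else:
        hub_w, nonhub_w = float("nan"), float("nan")
    return GraphSummary(
        strengths=S,
        hub_indices=hubs,
        k_density_curve=curve,
        hub_mean_weight=hub_w,
        nonhub_mean_weight=nonhub_w,
        hub_threshold=hub_threshold,
    )
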