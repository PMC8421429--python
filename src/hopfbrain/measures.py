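"""Global statistics of phase dynamics.

Integration (largest-component integral over binarization thresholds),
segregation (Louvain modularity of the significance-binarized mean
interaction matrix), functional connectivity dynamics (FCD: cosine
similarity between window-averaged synchronization patterns), its mean, and
the grand-average Fisher-z Pearson functional connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components

from .datatypes import Bold, FCDMatrix
from .exceptions import InvalidArgumentError, ShortSeriesError
from .phase import (
    DEFAULT_TRIM,
    NARROW_BAND,
    bias_correct_mean_interaction,
    extract_phases,
    mean_phase_interaction,
    surrogate_mean_interactions,
    synchrony_from_phases,
)

#: FCD sliding-window geometry: 30 TRs per window, shifted one TR at a time.
DEFAULT_WINDOW = 30
DEFAULT_STEP = 1

#: Significance level of the surrogate binarization behind segregation.
DEFAULT_ALPHA = 0.01

#: Threshold grid resolution of the integration scan.
DEFAULT_THRESHOLD_STEP = 0.01


def integration(mean_P: np.ndarray, threshold_step: float = DEFAULT_THRESHOLD_STEP) -> float:
    """Normalized integral of the largest connected component over thresholds.

    The (bias-corrected) time-averaged interaction matrix is binarized at
    every threshold on the grid 0..1 (strict inequality ``entry > thr``);
    at each threshold the relative size of the largest connected component
    is recorded, and the mean over thresholds is returned. 1 means the
    network stays whole at every threshold; 1/N means it is always fully
    fragmented.
    """
    mean_P = np.asarray(mean_P, dtype=float)
    if mean_P.ndim != 2 or mean_P.shape[0] != mean_P.shape[1]:
        raise InvalidArgumentError("integration needs a square matrix")
    if not np.allclose(mean_P, mean_P.T, atol=1e-9):
        raise InvalidArgumentError("integration needs a symmetric matrix")
    n = mean_P.shape[0]
    off = mean_P.copy()
    np.fill_diagonal(off, 0.0)
    thresholds = np.arange(0.0, 1.0, threshold_step)
    sizes = np.empty(thresholds.shape)
    for i, thr in enumerate(thresholds):
        adj = off > thr
        _, labels = connected_components(adj, directed=False)
        sizes[i] = np.bincount(labels).max() / n
    return float(sizes.mean())


def louvain_modularity(adj: np.ndarray, seed: int = 0, restarts: int = 10) -> float:
    """Newman modularity Q of the best Louvain partition of a binary graph.

    Louvain is stochastic; the best of ``restarts`` seeded runs is kept.
    A graph without edges has no meaningful partition and returns 0 with a
    warning.
    """
    adj = np.asarray(adj)
    G = nx.from_numpy_array(adj.astype(float))
    if G.number_of_edges() == 0:
        warnings.warn("binarized graph has no edges; modularity set to 0")
        return 0.0
    best = -np.inf
    for k in range(restarts):
        parts = nx.community.louvain_communities(G, seed=seed + k)
        q = nx.community.modularity(G, parts)
        best = max(best, q)
    return float(best)


def binarize_by_surrogates(
    mean_P: np.ndarray,
    bold: Bold,
    n_surrogates: int,
    alpha: float,
    seed: int,
    *,
    low: float = NARROW_BAND[0],
    high: float = NARROW_BAND[1],
    trim: int = DEFAULT_TRIM,
) -> np.ndarray:
    """Binary adjacency: pairs whose <P> exceeds the surrogate (1-alpha) quantile."""
    if n_surrogates < int(np.ceil(1.0 / alpha)):
        raise InvalidArgumentError(
            f"need >= {int(np.ceil(1.0 / alpha))} surrogates to resolve alpha={alpha}"
        )
    null = surrogate_mean_interactions(bold, n_surrogates, seed, low=low, high=high, trim=trim)
    q = np.quantile(null, 1.0 - alpha, axis=0)
    adj = np.asarray(mean_P) > q
    np.fill_diagonal(adj, False)
    return adj


def segregation(
    mean_P: np.ndarray,
    bold: Bold,
    n_surrogates: int = 100,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    *,
    low: float = NARROW_BAND[0],
    high: float = NARROW_BAND[1],
    trim: int = DEFAULT_TRIM,
    restarts: int = 10,
) -> float:
    """Segregation: modularity Q of the significance-binarized <P> matrix.

    Pairs with average phase interaction significantly (p < alpha) larger
    than expected under phase-randomized surrogates form the binary graph;
    Louvain community detection then yields Newman modularity Q.
    """
    adj = binarize_by_surrogates(
        mean_P, bold, n_surrogates, alpha, seed, low=low, high=high, trim=trim
    )
    return louvain_modularity(adj, seed=seed, restarts=restarts)


def fcd(
    series: np.ndarray,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> FCDMatrix:
    """FCD: cosine similarities between window-averaged interaction patterns.

    P(t) is averaged over sliding windows of ``window`` TRs shifted by
    ``step``; the strict upper triangles are vectorized and all pairwise
    cosine similarities fill the M x M matrix (unit diagonal).
    """
    series = np.asarray(series, dtype=float)
    T, n, _ = series.shape
    if T < window:
        raise ShortSeriesError(f"{T} samples < window of {window}")
    starts = np.arange(0, T - window + 1, step)
    iu = np.triu_indices(n, k=1)
    csum = np.cumsum(series[:, iu[0], iu[1]], axis=0)
    csum = np.vstack([np.zeros((1, iu[0].size)), csum])
    vecs = (csum[starts + window] - csum[starts]) / window
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vecs / norms
    sim = unit @ unit.T
    sim = 0.5 * (sim + sim.T)
    np.clip(sim, -1.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    return FCDMatrix(similarity=sim, window=window, step=step)


def mean_fcd(fcd_matrix: FCDMatrix, exclude_overlap: bool = False) -> float:
    """Mean of the strict-upper-triangle FCD entries.

    With ``exclude_overlap`` window pairs sharing samples (centre distance
    under one window length) are dropped.
    """
    sim = fcd_matrix.similarity
    m = sim.shape[0]
    i, j = np.triu_indices(m, k=1)
    if exclude_overlap:
        keep = (j - i) * fcd_matrix.step >= fcd_matrix.window
        i, j = i[keep], j[keep]
        if i.size == 0:
            raise InvalidArgumentError("no non-overlapping window pairs available")
    return float(sim[i, j].mean())


def pearson_fc(bold: Bold, *, max_r: float = 1.0 - 1e-7) -> np.ndarray:
    """Fisher z-transformed Pearson correlation matrix, diagonal masked (NaN).

    Correlations are clipped to ``max_r`` in magnitude before the arctanh
    transform so duplicated rows produce a large finite z instead of
    infinity. Zero-variance rows are flagged with a warning and returned as
    NaN rows.
    """
    x = bold.values
    sd = x.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"zero-variance rows {np.flatnonzero(flat).tolist()}: correlation undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.clip(r, -max_r, max_r)
    z = np.arctanh(r)
    z[flat, :] = np.nan
    z[:, flat] = np.nan
    np.fill_diagonal(z, np.nan)
    return z


@dataclass
class DynamicsSummary:
    """The four global statistics of one BOLD recording."""

    integration: float
    segregation_Q: float
    fluctuations_m: float
    mean_fcd: float


def dynamics_summary(
    bold: Bold,
    *,
    low: float = NARROW_BAND[0],
    high: float = NARROW_BAND[1],
    trim: int = DEFAULT_TRIM,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    n_surrogates: int = 100,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    exclude_overlap: bool = False,
) -> DynamicsSummary:
    """Full per-recording summary: integration, segregation, m, mean FCD.

    Integration uses the surrogate-bias-corrected <P>; segregation uses the
    raw <P> against the surrogate null; m and FCD come straight from the
    phase series.
    """
    from .phase import phase_interaction_series  # local import to avoid cycle noise

    phases = extract_phases(bold, low, high, trim=trim)
    mean_P = mean_phase_interaction(phases)
    corrected = bias_correct_mean_interaction(
        mean_P, bold, n_surrogates, seed, low=low, high=high, trim=trim
    )
    integ = integration(corrected)
    seg = segregation(
        mean_P, bold, n_surrogates=n_surrogates, alpha=alpha, seed=seed,
        low=low, high=high, trim=trim,
    )
    sync = synchrony_from_phases(phases)
    series = phase_interaction_series(phases)
    fluct = fcd(series, window=window, step=step)
    return DynamicsSummary(
        integration=integ,
        segregation_Q=seg,
        fluctuations_m=sync.m,
        mean_fcd=mean_fcd(fluct, exclude_overlap=exclude_overlap),
    )
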