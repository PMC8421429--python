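"""Shared lightweight containers.

The package works on plain numpy arrays wherever possible; the containers
here only bundle an array with the metadata that every downstream operation
needs (the repetition time for BOLD, window geometry for FCD matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError


@dataclass
class Bold:
    """A region x time BOLD-like signal matrix.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_volumes)
        One row per region, one column per fMRI volume.
    tr : float
        Repetition time in seconds (sampling interval of the columns).
    """

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError(
                f"BOLD matrix must be 2-D (regions x volumes), got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("BOLD matrix contains non-finite entries")
        if not self.tr > 0:
            raise InvalidArgumentError(f"tr must be positive, got {self.tr}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.tr

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr


@dataclass
class GlobalSynchrony:
    """Time-resolved global phase synchrony r(t) and its fluctuation m.

    ``r`` is the mean of the strict upper triangle of the phase-interaction
    matrix at each retained time point; ``m`` is the population standard
    deviation of ``r`` over time.
    """

    r: np.ndarray
    m: float = field(init=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.m = float(np.std(self.r))


@dataclass
class FCDMatrix:
    """Window x window cosine-similarity matrix of synchronization patterns."""

    similarity: np.ndarray
    window: int
    step: int

    @property
    def n_windows(self) -> int:
        return self.similarity.shape[0]
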