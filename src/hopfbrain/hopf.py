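"""Coupled Stuart-Landau (Hopf normal form) whole-brain simulator.

Each region j carries a complex state z_j obeying

    dz_j/dt = z_j [(a_j + i w_j) - |z_j|^2] + g sum_k C_jk (z_k - z_j) + beta mu_j(t)

where a_j is the local bifurcation parameter (damped noisy dynamics for
a_j < 0, a limit cycle of amplitude sqrt(a_j) for a_j > 0), w_j the intrinsic
angular frequency, g the global coupling scaling the structural matrix C
(max weight 0.2), and mu a complex Gaussian white noise of standard
deviation beta per component. BOLD is modelled as Real(z_j) sampled at the
repetition time.

In *effective mode* the growth term is parameterized directly by the
effective bifurcation parameter a_eff_j = a_j - g S_j (S_j the node
strength) and the coupling becomes the pure input term g sum_k C_jk z_k;
the two forms are algebraically identical trajectories for matching
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import welch

from .connectome import validate_sc
from .datatypes import Bold
from .exceptions import InstabilityError, InvalidArgumentError
from .phase import NARROW_BAND, bandpass_filter

#: Default noise standard deviation per real/imaginary component.
DEFAULT_BETA = 0.02

#: Default Euler-Maruyama step (seconds).
DEFAULT_DT = 0.1

#: Default transient discarded before sampling (seconds).
DEFAULT_TRANSIENT = 60.0

#: Wide band used for power-proportion fitting (Hz); upper edge is the
#: Nyquist frequency at TR = 2 s.
WIDE_BAND = (0.04, 0.25)

_DIVERGENCE_GUARD = 1e3


@dataclass
class HopfModelSpec:
    """Full parameterization of the coupled oscillator network."""

    a: np.ndarray
    omega: np.ndarray
    g: float
    C: np.ndarray
    beta: float = DEFAULT_BETA
    dt: float = DEFAULT_DT
    effective_mode: bool = False

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.C = validate_sc(self.C)
        n = self.C.shape[0]
        if self.a.shape != (n,) or self.omega.shape != (n,):
            raise InvalidArgumentError(
                f"a and omega must be length-{n} vectors matching C"
            )
        if self.g < 0:
            raise InvalidArgumentError(f"g must be non-negative, got {self.g}")
        if self.beta < 0:
            raise InvalidArgumentError(f"beta must be non-negative, got {self.beta}")
        if not self.dt > 0:
            raise InvalidArgumentError(f"dt must be positive, got {self.dt}")

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        return self.C.sum(axis=1)

    def with_params(self, **kwargs) -> "HopfModelSpec":
        """Copy of the spec with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SimulationResult:
    bold: Bold
    seed: int
    transient_discarded: float
    final_state: np.ndarray = field(repr=False, default=None)


def simulate(
    spec: HopfModelSpec,
    duration: float,
    tr: float,
    seed: int,
    *,
    transient: float = DEFAULT_TRANSIENT,
    z0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the network SDE and return Real(z) sampled at ``tr``.

    Stochastic Heun scheme with step ``spec.dt``: a predictor-corrector
    drift step (second order, so the rotation term does not bias the
    limit-cycle radius at dt = 0.1 s) with additive Gaussian increments of
    standard deviation beta*sqrt(dt) applied independently to the real and
    imaginary parts. The first ``transient`` seconds are discarded, then
    every (tr/dt)-th sample is kept, yielding floor(duration/tr) volumes.
    Identical (spec, duration, tr, seed) give bit-identical output.
    """
    dt = spec.dt
    stride = tr / dt
    if abs(stride - round(stride)) > 1e-9:
        raise InvalidArgumentError(f"tr ({tr}) must be an integer multiple of dt ({dt})")
    stride = int(round(stride))
    n_volumes = int(np.floor(duration / tr))
    if n_volumes < 1:
        raise InvalidArgumentError("duration shorter than one TR")

    n = spec.n
    rng = np.random.default_rng(seed)
    if z0 is None:
        z = 0.1 * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    else:
        z = np.asarray(z0, dtype=complex).copy()
        if z.shape != (n,):
            raise InvalidArgumentError(f"z0 must be a length-{n} vector")

    gC = spec.g * spec.C
    growth = spec.a + 1j * spec.omega
    if not spec.effective_mode:
        # diffusive coupling g sum C_jk (z_k - z_j) = g C z - g S z
        growth = growth - spec.g * spec.strengths
    sigma = spec.beta * np.sqrt(dt)

    n_transient = int(round(transient / dt))
    total_steps = n_transient + n_volumes * stride
    out = np.empty((n, n_volumes))
    vol = 0
    chunk = 4096
    step = 0
    while step < total_steps:
        m = min(chunk, total_steps - step)
        if spec.beta > 0:
            noise = sigma * (
                rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
            )
        else:
            noise = np.zeros((m, n), dtype=complex)
        with np.errstate(over="ignore", invalid="ignore"):
            for i in range(m):
                # Heun (predictor-corrector) drift step, additive noise:
                # second-order in dt, so the rotation term does not inflate
                # the limit-cycle radius the way plain Euler does
                f0 = (growth - np.abs(z) ** 2) * z + gC @ z
                zp = z + dt * f0 + noise[i]
                f1 = (growth - np.abs(zp) ** 2) * zp + gC @ zp
                z = z + 0.5 * dt * (f0 + f1) + noise[i]
                step += 1
                if step > n_transient and (step - n_transient) % stride == 0:
                    out[:, vol] = z.real
                    vol += 1
        amax = np.abs(z).max()
        if not np.isfinite(amax) or amax > _DIVERGENCE_GUARD:
            raise InstabilityError(
                f"simulation diverged (|z| > {_DIVERGENCE_GUARD:g}) at t = {step * dt:g} s; "
                f"step size dt = {dt} s may be too large for these parameters"
            )
    return SimulationResult(
        bold=Bold(out, tr), seed=seed, transient_discarded=transient, final_state=z
    )


class IntrinsicFrequencies(NamedTuple):
    """Per-node intrinsic frequencies in rad/s (omega) and Hz (hz) views."""

    omega: np.ndarray
    hz: np.ndarray


def estimate_intrinsic_frequencies(
    group_bold: Sequence[Bold],
    band: tuple[float, float] = NARROW_BAND,
) -> IntrinsicFrequencies:
    """Average per-node spectral peak frequency across subjects, within band.

    Each subject's signals are band-passed to ``band``; the Welch power
    spectrum peak is located within the band for every node, and peaks are
    averaged across subjects. A flat in-band spectrum falls back to the band
    centre with a warning.
    """
    import warnings

    if len(group_bold) == 0:
        raise InvalidArgumentError("need at least one subject")
    n = group_bold[0].n_regions
    peaks = np.zeros((len(group_bold), n))
    for s, bold in enumerate(group_bold):
        filtered = bandpass_filter(bold, band[0], band[1])
        nperseg = min(128, max(8, bold.n_volumes // 2))
        f, psd = welch(filtered.values, fs=bold.fs, nperseg=nperseg, axis=1)
        in_band = (f >= band[0]) & (f <= band[1])
        if not np.any(in_band):
            raise InvalidArgumentError("no spectral bins inside the requested band")
        fb, pb = f[in_band], psd[:, in_band]
        flat = pb.max(axis=1) <= 0
        if np.any(flat):
            warnings.warn("flat in-band spectrum; falling back to band centre")
        idx = pb.argmax(axis=1)
        peaks[s] = np.where(flat, 0.5 * (band[0] + band[1]), fb[idx])
    hz = peaks.mean(axis=0)
    return IntrinsicFrequencies(omega=2.0 * np.pi * hz, hz=hz)


def power_proportions(
    bold: Bold,
    *,
    narrow: tuple[float, float] = NARROW_BAND,
    wide: tuple[float, float] = WIDE_BAND,
) -> np.ndarray:
    """Per-node proportion of spectral power in ``narrow`` relative to ``wide``.

    p_j = int_{narrow} PS_j(f) df / int_{wide} PS_j(f) df, with the wide
    band clipped at the Nyquist frequency. Spectra are Welch-averaged
    periodograms (segment length min(128, T/4)); integrating the raw PSD
    over the two bands is used rather than band-pass filtering first, which
    avoids filter roll-off bias at the band edges.
    """
    T = bold.n_volumes
    hi = min(wide[1], bold.nyquist)
    if not narrow[0] >= wide[0] or not narrow[1] <= hi:
        raise InvalidArgumentError("narrow band must sit inside the wide band")
    nperseg = min(128, max(8, T // 4))
    f, psd = welch(
        bold.values - bold.values.mean(axis=1, keepdims=True),
        fs=bold.fs,
        nperseg=nperseg,
        axis=1,
    )
    df = f[1] - f[0]

    def _band_power(lo: float, up: float) -> np.ndarray:
        # integrate on a fine grid interpolated between the exact band edges,
        # so the result does not depend on how the Welch bins straddle them;
        # the same grid density for both bands keeps num <= den
        grid = np.linspace(lo, up, 20 * int(np.ceil((up - lo) / df)) + 1)
        interp = np.vstack([np.interp(grid, f, row) for row in psd])
        return np.trapezoid(interp, grid, axis=1)

    num = _band_power(narrow[0], narrow[1])
    den = _band_power(wide[0], hi)
    if np.any(den <= 0):
        raise InvalidArgumentError(
            "zero wide-band power; power proportion undefined for some node"
        )
    return np.clip(num / den, 0.0, 1.0)


def power_proportion(bold: Bold, node: int, **kwargs) -> float:
    """Power proportion p_j for a single node (see ``power_proportions``)."""
    return float(power_proportions(bold, **kwargs)[node])
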