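"""Synthetic ground-truth data generation.

Core-periphery structural connectomes with designated hubs, hub-degraded
variants emulating lesioned (DOC-like) connectomes, and ground-truth
BOLD generated from the Hopf network simulator itself — so every
downstream stage of the pipeline can be tested against known parameters
without any empirical data.

Conventions: the designated hubs of a generated connectome are nodes
0..n_hubs-1. Generated matrices are symmetric, zero-diagonal and max-scaled
to the model weight 0.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .connectome import scale_to_max, validate_sc
from .datatypes import Bold
from .exceptions import DegenerateGraphError, InvalidArgumentError
from .hopf import DEFAULT_BETA, DEFAULT_DT, HopfModelSpec, simulate
from .phase import NARROW_BAND


def generate_core_periphery_sc(
    n_nodes: int,
    n_hubs: int,
    hub_factor: float,
    density: float,
    seed: int,
    *,
    weight_sigma: float = 0.75,
) -> np.ndarray:
    """Weighted stochastic-block core-periphery connectome, max weight 0.2.

    Links exist independently with probability
    min(1, density * hub_factor**(number of hub endpoints)) and carry
    log-normal weights (sigma ``weight_sigma``) multiplied by the same
    hub_factor**(number of hub endpoints) boost. Hubs are therefore both
    higher-degree and more strongly weighted, as in tractography-derived
    connectomes, which makes their strength advantage robust: with
    hub_factor >= 2 the designated hubs (nodes 0..n_hubs-1) have strictly
    larger strengths than every peripheral node and the core forms a
    rich-club by construction; hub_factor = 1 removes the boost entirely.
    """
    if not 1 <= n_hubs < n_nodes:
        raise InvalidArgumentError(f"need 1 <= n_hubs < n_nodes, got {n_hubs}/{n_nodes}")
    if not 0 < density <= 1:
        if density == 0 and n_hubs > 0:
            raise DegenerateGraphError("density 0 produces an empty graph")
        raise InvalidArgumentError(f"density must be in (0, 1], got {density}")
    if hub_factor < 1:
        raise InvalidArgumentError(f"hub_factor must be >= 1, got {hub_factor}")
    rng = np.random.default_rng(seed)
    is_hub = np.zeros(n_nodes, dtype=bool)
    is_hub[:n_hubs] = True
    boost = hub_factor ** (is_hub[:, None].astype(int) + is_hub[None, :].astype(int))
    present = rng.random((n_nodes, n_nodes)) < np.minimum(1.0, density * boost)
    weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=(n_nodes, n_nodes))
    C = np.triu(present * weights * boost, k=1)
    C = C + C.T
    if C.max() <= 0:
        raise DegenerateGraphError("generated graph has no links; raise density")
    return scale_to_max(C)


def degrade_hubs(
    sc: np.ndarray,
    reduction: float,
    hub_threshold: float,
    seed: int = 0,
    *,
    rescale: bool = False,
) -> np.ndarray:
    """Attenuate all links incident to hub nodes by (1 - reduction).

    Hubs are the nodes with strength strictly above ``hub_threshold`` on the
    input matrix. Attenuation is multiplicative and node count is preserved,
    emulating lesion-induced hub suppression while keeping the parcellation
    comparable across groups. The operation is deterministic; ``seed`` is
    accepted for interface uniformity and ignored. The output is returned on
    the attenuated (raw) scale unless ``rescale``, which re-scales the
    maximum back to 0.2.
    """
    if not 0 <= reduction <= 1:
        raise InvalidArgumentError(f"reduction must be in [0, 1], got {reduction}")
    C = validate_sc(sc).copy()
    strengths = C.sum(axis=1)
    hubs = strengths > hub_threshold
    mask = hubs[:, None] | hubs[None, :]
    C[mask] *= 1.0 - reduction
    if rescale:
        C = scale_to_max(C)
    return C


@dataclass
class GroundTruth:
    """The parameters a synthetic dataset was generated with."""

    g_true: float
    a_true: np.ndarray
    omega_true: np.ndarray  # rad/s
    hub_indices: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        record = asdict(self)
        record["a_true"] = np.asarray(self.a_true).tolist()
        record["omega_true"] = np.asarray(self.omega_true).tolist()
        record["hub_indices"] = np.asarray(self.hub_indices).astype(int).tolist()
        Path(path).write_text(json.dumps(record, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        record = json.loads(Path(path).read_text())
        return cls(
            g_true=record["g_true"],
            a_true=np.asarray(record["a_true"], dtype=float),
            omega_true=np.asarray(record["omega_true"], dtype=float),
            hub_indices=np.asarray(record["hub_indices"], dtype=int),
            seed=record["seed"],
        )


def make_ground_truth_dataset(
    sc: np.ndarray,
    g: float,
    a_spec: dict,
    band: tuple[float, float] = NARROW_BAND,
    n_volumes: int = 300,
    tr: float = 2.0,
    seed: int = 0,
    *,
    beta: float = DEFAULT_BETA,
    dt: float = DEFAULT_DT,
    hub_indices: np.ndarray | None = None,
) -> tuple[GroundTruth, Bold]:
    """Generate ground-truth BOLD from the Hopf model on a given connectome.

    ``a_spec`` is either {"homogeneous": value} or
    {"heterogeneous": (low, high)} (node parameters drawn uniformly).
    Intrinsic frequencies are drawn uniformly inside ``band`` (stored in
    rad/s). Identical (inputs, seed) give bit-identical output.
    """
    sc = validate_sc(sc)
    n = sc.shape[0]
    nyq = 0.5 / tr
    if not 0 < band[0] < band[1] < nyq:
        raise InvalidArgumentError(
            f"band {band} must sit inside (0, Nyquist = {nyq:g} Hz)"
        )
    rng = np.random.default_rng(seed)
    if "homogeneous" in a_spec:
        a = np.full(n, float(a_spec["homogeneous"]))
    elif "heterogeneous" in a_spec:
        lo, hi = a_spec["heterogeneous"]
        a = rng.uniform(lo, hi, size=n)
    else:
        raise InvalidArgumentError(
            "a_spec must contain 'homogeneous': value or 'heterogeneous': (low, high)"
        )
    omega = 2.0 * np.pi * rng.uniform(band[0], band[1], size=n)
    spec = HopfModelSpec(a=a, omega=omega, g=g, C=sc, beta=beta, dt=dt)
    result = simulate(spec, duration=n_volumes * tr, tr=tr, seed=seed)
    truth = GroundTruth(
        g_true=float(g),
        a_true=a,
        omega_true=omega,
        hub_indices=(
            np.asarray(hub_indices, dtype=int) if hub_indices is not None else np.array([], dtype=int)
        ),
        seed=seed,
    )
    return truth, result.bold
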