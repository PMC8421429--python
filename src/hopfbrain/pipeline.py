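"""End-to-end orchestration: I/O, configuration and the full analysis chain.

The pipeline sequences, per group of BOLD recordings on a shared structural
connectome: the four phase-dynamics statistics, the homogeneous global
coupling fit, the heterogeneous local-parameter fits (a and a_eff modes),
the effective-parameter / strength regression, linear stability, and the
structural graph summary. Group outputs are descriptive (means and
standard errors), never inferential.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .connectome import HUB_STRENGTH_THRESHOLD, graph_summary, validate_sc
from .datatypes import Bold
from .exceptions import InvalidArgumentError, ParseError
from .fitting import (
    DEFAULT_ETA,
    DEFAULT_TOL,
    fcd_values,
    fit_effective_parameters,
    fit_global_coupling,
    fit_local_bifurcation,
    strength_residual_analysis,
)
from .hopf import (
    DEFAULT_BETA,
    DEFAULT_DT,
    HopfModelSpec,
    estimate_intrinsic_frequencies,
    power_proportions,
)
from .measures import (
    DEFAULT_ALPHA,
    DEFAULT_STEP,
    DEFAULT_WINDOW,
    dynamics_summary,
    fcd,
)
from .phase import DEFAULT_TRIM, NARROW_BAND, extract_phases, phase_interaction_series
from .stability import hub_stability_summary, stability_of_spec

#: Wide band for power-proportion fitting (upper edge = Nyquist at TR 2 s).
WIDE_BAND = (0.04, 0.25)


@dataclass
class RunConfig:
    """All knobs of a full pipeline run; defaults are the standard constants.

    ``groups`` maps a group name to a list of BOLD inputs (paths to
    delimited text matrices or in-memory arrays); ``sc`` is the shared
    structural connectome (path or array).
    """

    groups: dict = field(default_factory=dict)
    sc: object = None
    tr: float = 2.0
    band: tuple = NARROW_BAND
    wide_band: tuple = WIDE_BAND
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    g_grid: tuple = (0.0, 3.0, 0.1)
    trials: int = 10
    eta: float = DEFAULT_ETA
    beta: float = DEFAULT_BETA
    dt: float = DEFAULT_DT
    hub_threshold: float = HUB_STRENGTH_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    n_surrogates: int = 100
    trim: int = DEFAULT_TRIM
    tol: float = DEFAULT_TOL
    max_iter: int = 50
    n_volumes: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = 0.5 / self.tr
        if not 0 < self.band[0] < self.band[1] <= nyq:
            raise InvalidArgumentError(f"band {self.band} outside (0, Nyquist={nyq:g}]")
        if not self.wide_band[0] < self.wide_band[1] <= nyq + 1e-12:
            raise InvalidArgumentError(f"wide band {self.wide_band} beyond Nyquist {nyq:g}")

    def g_values(self) -> np.ndarray:
        lo, hi, step = self.g_grid
        return np.round(np.arange(lo, hi + 1e-9, step), 10)


def load_matrix(path: str | Path, kind: str = "bold", *, tr: float = 2.0):
    """Load a delimited text matrix as a validated Bold or SC array.

    Rows may be whitespace- or comma-delimited. Ragged rows raise ParseError
    naming the offending line; non-finite entries raise a validation error.
    SC matrices are checked for symmetry within 1e-6 and then exactly
    symmetrized.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                row = [float(p) for p in parts]
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: non-numeric entry ({err})") from None
            if rows and len(row) != len(rows[0]):
                raise ParseError(
                    f"{path}:{lineno}: ragged row of {len(row)} entries "
                    f"(expected {len(rows[0])})"
                )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    values = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidArgumentError(f"{path}: matrix contains non-finite entries")
    if kind == "bold":
        return Bold(values, tr)
    if kind == "sc":
        if values.shape[0] != values.shape[1]:
            raise InvalidArgumentError(f"{path}: SC matrix must be square, got {values.shape}")
        if not np.allclose(values, values.T, atol=1e-6):
            raise InvalidArgumentError(f"{path}: SC asymmetry above tolerance 1e-6")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        return validate_sc(values)
    raise InvalidArgumentError(f"unknown matrix kind {kind!r}")


def save_matrix(path: str | Path, matrix: np.ndarray) -> None:
    """Write a matrix as whitespace-delimited text (full double precision)."""
    np.savetxt(path, np.asarray(matrix), fmt="%.17g")


def _as_bold(item, tr: float) -> Bold:
    if isinstance(item, Bold):
        return item
    if isinstance(item, (str, Path)):
        return load_matrix(item, kind="bold", tr=tr)
    return Bold(np.asarray(item, dtype=float), tr)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, complex):
        return {"real": obj.real, "imag": obj.imag}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return repr(obj)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run the complete analysis for every group in the config.

    Returns a report bundle (nested dict) with per-group dynamics
    summaries, the global-coupling fit, local and effective parameter fits,
    the strength-residual analysis, the stability spectrum summary, the
    structural graph summary, and a reproducibility manifest. Any stage
    failure is recorded in place of that stage's block instead of aborting
    the run.
    """
    if config.sc is None or not config.groups:
        raise InvalidArgumentError("config must provide an SC matrix and at least one group")
    sc = config.sc if isinstance(config.sc, np.ndarray) else load_matrix(config.sc, kind="sc")
    sc = validate_sc(sc)
    bundle: dict = {
        "manifest": {
            "package_version": __version__,
            "config": _jsonify(
                {f.name: getattr(config, f.name) for f in dataclasses.fields(config)
                 if f.name not in ("groups", "sc")}
            ),
            "group_sizes": {name: len(items) for name, items in config.groups.items()},
            "seed": config.seed,
        },
        "groups": {},
    }
    try:
        bundle["graph"] = _jsonify(graph_summary(sc, hub_threshold=config.hub_threshold))
    except Exception as err:  # noqa: BLE001
        bundle["graph"] = {"stage_failure": repr(err)}

    strengths = sc.sum(axis=1)
    for gi, (name, items) in enumerate(config.groups.items()):
        group: dict = {}
        bundle["groups"][name] = group
        bolds = [_as_bold(item, config.tr) for item in items]

        # --- per-subject phase-dynamics statistics -> descriptive summary
        try:
            summaries = [
                dynamics_summary(
                    b,
                    low=config.band[0],
                    high=config.band[1],
                    trim=config.trim,
                    window=config.window,
                    step=config.step,
                    n_surrogates=config.n_surrogates,
                    alpha=config.alpha,
                    seed=config.seed + 1000 * gi + si,
                )
                for si, b in enumerate(bolds)
            ]
            table = {
                stat: np.array([getattr(s, stat) for s in summaries])
                for stat in ("integration", "segregation_Q", "fluctuations_m", "mean_fcd")
            }
            group["dynamics"] = {
                "per_subject": _jsonify(table),
                "mean": {k: float(v.mean()) for k, v in table.items()},
                "se": {
                    k: float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
                    for k, v in table.items()
                },
            }
        except Exception as err:  # noqa: BLE001
            group["dynamics"] = {"stage_failure": repr(err)}
            continue

        # --- empirical inputs for model fitting
        freqs = estimate_intrinsic_frequencies(bolds, config.band)
        pooled_fcd = np.concatenate(
            [
                fcd_values(
                    fcd(
                        phase_interaction_series(
                            extract_phases(b, config.band[0], config.band[1], trim=config.trim)
                        ),
                        window=config.window,
                        step=config.step,
                    )
                )
                for b in bolds
            ]
        )
        p_emp = np.mean(
            [
                power_proportions(b, narrow=config.band,
                                  wide=(config.wide_band[0], min(config.wide_band[1], 0.5 / config.tr)))
                for b in bolds
            ],
            axis=0,
        )
        template = HopfModelSpec(
            a=np.zeros(sc.shape[0]), omega=freqs.omega, g=0.0, C=sc,
            beta=config.beta, dt=config.dt,
        )

        # --- homogeneous model: global coupling
        try:
            gfit = fit_global_coupling(
                pooled_fcd,
                template,
                config.g_values(),
                trials=config.trials,
                n_volumes=config.n_volumes,
                tr=config.tr,
                seed=config.seed + gi,
                band=config.band,
                trim=config.trim,
                window=config.window,
                step=config.step,
            )
            group["global_fit"] = _jsonify(gfit)
            g_opt = gfit.g_opt
        except Exception as err:  # noqa: BLE001
            group["global_fit"] = {"stage_failure": repr(err)}
            continue

        # --- heterogeneous model: local bifurcation parameters
        spec_g = template.with_params(g=g_opt)
        try:
            afit = fit_local_bifurcation(
                p_emp, spec_g, eta=config.eta, max_iter=config.max_iter,
                tol=config.tol, seed=config.seed + 10 + gi,
                n_volumes=config.n_volumes, tr=config.tr,
            )
            group["local_fit"] = _jsonify(afit)
        except Exception as err:  # noqa: BLE001
            afit = None
            group["local_fit"] = {"stage_failure": repr(err)}

        # --- effective parameters + strength-residual analysis
        try:
            efit = fit_effective_parameters(
                p_emp, spec_g, eta=config.eta, max_iter=config.max_iter,
                tol=config.tol, seed=config.seed + 20 + gi,
                n_volumes=config.n_volumes, tr=config.tr,
            )
            group["effective_fit"] = _jsonify(efit)
            group["residuals"] = _jsonify(strength_residual_analysis(efit.a_hat, strengths))
        except Exception as err:  # noqa: BLE001
            group["effective_fit"] = {"stage_failure": repr(err)}
            group["residuals"] = {"stage_failure": repr(err)}

        # --- linear stability of the fitted model
        try:
            a_fitted = afit.a_hat if afit is not None else np.zeros(sc.shape[0])
            stab = stability_of_spec(spec_g.with_params(a=a_fitted))
            hub_sum = hub_stability_summary(
                stab, strengths, k_dominant=min(5, sc.shape[0])
            )
            group["stability"] = {
                "eigenvalues_real": _jsonify(stab.eigenvalues.real),
                "eigenvalues_imag": _jsonify(stab.eigenvalues.imag),
                "stable": stab.stable,
                "min_real_eigenvalue": hub_sum.min_real_eigenvalue,
                "strength_correlations": _jsonify(hub_sum.correlations),
            }
        except Exception as err:  # noqa: BLE001
            group["stability"] = {"stage_failure": repr(err)}
    return bundle


def save_bundle(bundle: dict, path: str | Path) -> None:
    """Write a report bundle as indented JSON."""
    Path(path).write_text(json.dumps(_jsonify(bundle), indent=2))
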