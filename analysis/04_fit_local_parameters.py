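"""Heterogeneous-model recovery of the node bifurcation parameters a_j.

For three independent wakeful-like recordings (heterogeneous ground truth
a_j ~ U(-0.2, 0.1), g = 1.5), fits the per-node bifurcation parameters by
the parallel gradient rule a_j <- a_j + eta (p_emp_j - p_sim_j) on the
narrowband power proportions (eta = 0.1), then compares fitted against
true values.

Findings: the fit recovers the spatial arrangement of local excitability
(Spearman rank correlation ~= 0.7-0.9 between a_true and a_hat), and the
optimization trace of the power-proportion mismatch decreases to a noise
floor set by the finite recording length.

Writes: results/local_fit.csv, results/local_fit_summary.json
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import connectomes, N_VOLUMES, TR

from hopfbrain import (
    HopfModelSpec,
    fit_local_bifurcation,
    make_ground_truth_dataset,
    power_proportions,
)

OUT = Path(__file__).resolve().parents[1] / "results"
G_FIXED = 1.5


def main() -> None:
    OUT.mkdir(exist_ok=True)
    intact, _, _ = connectomes()
    rows, summary = [], {}
    for rep, seed in enumerate((201, 202, 203)):
        truth, bold = make_ground_truth_dataset(
            intact, g=G_FIXED, a_spec={"heterogeneous": (-0.2, 0.1)},
            n_volumes=N_VOLUMES, tr=TR, seed=seed,
        )
        spec = HopfModelSpec(
            a=np.zeros(intact.shape[0]), omega=truth.omega_true, g=G_FIXED, C=intact
        )
        fit = fit_local_bifurcation(
            power_proportions(bold), spec, eta=0.1, max_iter=60, seed=seed + 1000
        )
        rho = spearmanr(truth.a_true, fit.a_hat).statistic
        summary[f"repeat_{rep}"] = {
            "seed": seed,
            "spearman": float(rho),
            "iterations": fit.iterations,
            "initial_gap": float(fit.trace[0]),
            "final_gap": float(fit.trace[-1]),
        }
        for j in range(intact.shape[0]):
            rows.append(
                {"repeat": rep, "node": j, "a_true": truth.a_true[j], "a_hat": fit.a_hat[j]}
            )
        print(
            f"repeat {rep} (seed {seed}): Spearman(a_true, a_hat) = {rho:.3f}, "
            f"gap {fit.trace[0]:.3f} -> {fit.trace[-1]:.3f} in {fit.iterations} iterations"
        )
    summary["mean_spearman"] = float(
        np.mean([v["spearman"] for k, v in summary.items() if k.startswith("repeat")])
    )
    pd.DataFrame(rows).to_csv(OUT / "local_fit.csv", index=False)
    (OUT / "local_fit_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"mean Spearman over repeats: {summary['mean_spearman']:.3f}")


if __name__ == "__main__":
    main()
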