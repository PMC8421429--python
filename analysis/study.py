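"""Shared study conditions for the numbered analysis scripts.

Two synthetic conditions mirror the empirical contrast between conscious
wakefulness and low-level states of consciousness:

- "wakeful": intact connectome, strong global coupling (g = 2.0, the value
  fitted on awake subjects), heterogeneous local bifurcation parameters
  a_j ~ U(-0.2, 0.1);
- "reduced": hub-degraded connectome (50% attenuation of hub-incident
  links), weak coupling (g = 0.9, the sedation-level fit), homogeneous
  a_j = 0.

Three 10-minute recordings (300 volumes, TR = 2 s) per condition.
"""

import numpy as np

from hopfbrain import degrade_hubs, generate_core_periphery_sc, make_ground_truth_dataset, node_strengths

N, N_HUBS, HUB_FACTOR, DENSITY, SC_SEED = 40, 6, 3.0, 0.08, 12
N_SUBJECTS = 3
N_VOLUMES, TR = 300, 2.0


def connectomes():
    intact = generate_core_periphery_sc(N, N_HUBS, HUB_FACTOR, DENSITY, seed=SC_SEED)
    S = node_strengths(intact)
    hub_thr = 0.5 * (S[:N_HUBS].min() + S[N_HUBS:].max())
    degraded = degrade_hubs(intact, 0.5, hub_thr)
    return intact, degraded, hub_thr


def conditions():
    intact, degraded, _ = connectomes()
    return {
        "wakeful": dict(sc=intact, g=2.0, a_spec={"heterogeneous": (-0.2, 0.1)}),
        "reduced": dict(sc=degraded, g=0.9, a_spec={"homogeneous": 0.0}),
    }


def generate_group(cond: dict, base_seed: int = 500):
    """Ground truths and BOLD recordings for one condition."""
    truths, bolds = [], []
    for s in range(N_SUBJECTS):
        truth, bold = make_ground_truth_dataset(
            cond["sc"], g=cond["g"], a_spec=cond["a_spec"],
            n_volumes=N_VOLUMES, tr=TR, seed=base_seed + s,
            hub_indices=np.arange(N_HUBS),
        )
        truths.append(truth)
        bolds.append(bold)
    return truths, bolds
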