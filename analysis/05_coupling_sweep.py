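#!/usr/bin/env python
"""Parameter recovery: does the pipeline see coupling strength in the metrics?

Simulates single-network cohorts at K = 0 (independent oscillators),
K = K_mid (partially synchronized, near the critical coupling), and K = 50
(locked), 20 seed replicates each, and measures recovered Global sync and
metastability. Expected physics: sync increases monotonically with K while
metastability peaks in the partially synchronized regime — flexibility lives
between independence and rigidity. Writes results/coupling_sweep.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import syncmeta as sm
from syncmeta import presets

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
RC = sm.RunConfig(discard_initial=60.0, edge_trim=5, n_iterations=100)


def main() -> None:
    rows = []
    for coupling in (0.0, presets.K_MID, 50.0):
        for rep in range(20):
            cfg = presets.sweep_config(coupling, seed=SEED * 1000 + rep)
            ses = sm.simulate_kuramoto_sessions(cfg)[0]
            asg = sm.make_network_assignment(cfg.network_sizes, cfg.labels)
            m = sm.network_metrics(sm.session_phases(ses, asg, RC), asg)
            sync, meta = m["N0"]
            rows.append(
                {"K": coupling, "replicate": rep, "sync": sync, "metastability": meta}
            )
    frame = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    frame.to_csv(results / "coupling_sweep.tsv", sep="\t", index=False,
                 float_format="%.6g")

    summary = frame.groupby("K")[["sync", "metastability"]].agg(["mean", "std"])
    print(summary.round(3))
    means = frame.groupby("K").mean()
    ks = sorted(means.index)
    print(
        "\nsync strictly increasing in K:",
        bool(means.loc[ks[0], "sync"] < means.loc[ks[1], "sync"] < means.loc[ks[2], "sync"]),
    )
    print(
        "metastability peaks at moderate K:",
        bool(
            means.loc[ks[1], "metastability"] > means.loc[ks[0], "metastability"]
            and means.loc[ks[1], "metastability"] > means.loc[ks[2], "metastability"]
        ),
    )


if __name__ == "__main__":
    main()
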