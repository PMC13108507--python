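#!/usr/bin/env python
"""Departure from baseline under a simulated change of brain state.

Emulates a pharmacological state-change design: several baseline sessions
from one configured "subject", followed by sessions generated with strongly
reduced within-network coupling (desynchronization, as produced by a
psychedelic-like perturbation). For every session the combined
sync-metastability vector and the FC vector are compared with the first
baseline session via departure = 1 - Pearson r. A useful state marker shows
near-zero departure across baseline sessions and a clear excursion for the
perturbed ones. Writes results/state_departure.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

import syncmeta as sm
from syncmeta import presets

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
RC = sm.RunConfig(discard_initial=60.0, edge_trim=5, n_iterations=100)


def make_state_cohort(seed: int):
    base_cfg = presets.stationary_cohort_config(seed=seed)
    base_cfg = sm.SimulationConfig(**{**base_cfg.__dict__, "n_sessions": 5})
    baseline = sm.simulate_kuramoto_sessions(base_cfg)
    # perturbed state: within-network coupling collapsed to a fifth
    drug_cfg = sm.SimulationConfig(
        **{
            **base_cfg.__dict__,
            "n_sessions": 2,
            "coupling_per_network": tuple(
                k / 5.0 for k in base_cfg.coupling_per_network
            ),
            "seed": seed + 1,
        }
    )
    perturbed = sm.simulate_kuramoto_sessions(drug_cfg)
    sessions = list(baseline) + [
        sm.SessionSeries(
            data=s.data, tr=s.tr, session_id=f"drug-{i}", parcel_ids=s.parcel_ids
        )
        for i, s in enumerate(perturbed)
    ]
    asg = sm.make_network_assignment(base_cfg.network_sizes, base_cfg.labels)
    return sm.validate_cohort(sessions, asg)


def main() -> None:
    cohort = make_state_cohort(SEED)
    cache = sm.CohortCache(cohort, RC)
    rows = []
    for kind in ("combined", "fc"):
        vectors = [cache.vector((sid,), kind) for sid in cohort.session_ids]
        dep = sm.departure_from_baseline(vectors, reference_index=0)
        for sid, d in zip(cohort.session_ids, dep):
            rows.append({"session_id": sid, "metric": kind, "departure": d})
    frame = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    frame.to_csv(results / "state_departure.tsv", sep="\t", index=False,
                 float_format="%.6g")

    wide = frame.pivot(index="session_id", columns="metric", values="departure")
    print(wide.round(4))
    base = wide.loc[[s for s in wide.index if s.startswith("ses")], "combined"]
    drug = wide.loc[[s for s in wide.index if s.startswith("drug")], "combined"]
    print(
        f"\ncombined vector: baseline departures ≤ {base.max():.3f}, "
        f"perturbed ≥ {drug.min():.3f} "
        "-> the perturbation stands clear of within-subject variability"
    )


if __name__ == "__main__":
    main()
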