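# syncmeta

Phase synchrony and metastability of parcellated resting-state BOLD fMRI,
with split-half reliability profiling as a function of scan duration.

Metastability — the temporal variability of a brain network's instantaneous
phase synchrony — is widely used as a proxy of brain dynamics, but a
biomarker is only as good as its test-retest reliability. This package
implements the full analysis chain needed to quantify that reliability for
a single, highly sampled subject: EMD-based narrowband phase extraction,
Kuramoto order-parameter network metrics, a split-half resampling engine
that measures similarity-to-baseline at increasing acquisition durations,
phase-randomized surrogate nulls, and departure-from-baseline scoring for
state-change designs. A coupled-oscillator cohort generator with known
ground truth makes every stage testable without scanner data.

It is written for network-neuroscience researchers who have parcellated
session time series (plain TSV: header = parcel ids, one row per TR sample)
and a parcel→network table, and want to know how much data their sync /
metastability / FC estimates need before they stabilize.

## The quantities

For parcels p of network *n* with instantaneous phases θ_p(t):

    φ_n(t) = | ⟨ e^{iθ_p(t)} ⟩_{p∈n} |          Kuramoto order parameter
    sync_n = mean_t φ_n(t)
    meta_n = SD_t φ_n(t)                         (population SD)

θ_p(t) is the Hilbert phase of one intrinsic mode function (mode 0 ≈ the
0.04–0.07 Hz BOLD band) obtained by EMD sifting, with the first minute of
each session discarded and 5 samples trimmed from each end of the phase
series. The sync-metastability feature vector concatenates all networks'
sync values then all metastability values (14 networks incl. Global → 28
dimensions). Reliability of a metric is the Pearson correlation (scalars:
1 − |err|/baseline) between its value from k test sessions and a baseline
computed from a held-out half of the sessions, averaged over unique random
half-splits. See `docs/methods.md` for the full model and numerical choices.

## Worked example

```python
import syncmeta as sm
from syncmeta import presets

cfg = presets.stationary_cohort_config(seed=7)      # 24 sessions x 5 min,
sessions = sm.simulate_kuramoto_sessions(cfg)       # 20 parcels, 2 networks
assignment = sm.make_network_assignment(cfg.network_sizes, cfg.labels)
cohort = sm.validate_cohort(sessions, assignment)

rc = sm.RunConfig(discard_initial=60, edge_trim=5, n_iterations=100, seed=11)
cache = sm.CohortCache(cohort, rc)                  # EMD phases, cached once
plan = sm.build_split_plan(cohort.session_ids, rc.n_iterations, rc.seed)

for kind in ("fc", "combined"):
    prof = sm.convergence_profile(cache, plan, kind)
    print(f"{kind:9s} {prof.mean[0]:.3f} ± {prof.sd[0]:.3f} at "
          f"{prof.durations_min[0]:.1f} min")
```

prints

```
fc        0.839 ± 0.039 at 3.8 min
combined  0.985 ± 0.009 at 3.8 min
```

i.e. with a single short session, the combined sync-metastability vector
already correlates 0.985 with its 12-session baseline while static FC sits
at 0.839 — the combined vector's reliability advantage is largest exactly
where scan time is scarce. The same engine exposes per-network scalar
profiles, surrogate comparisons (`sm.surrogate_null_metrics`,
`sm.compare_empirical_null`) and departure-from-baseline scoring
(`sm.departure_from_baseline`).

The numbered scripts under `analysis/` run the complete study on synthetic
cohorts (generation, per-session metrics and redundancy, reliability
profiles, surrogate nulls, coupling-recovery sweep, simulated state change)
and write their tables under `results/`. A `syncmeta` CLI wraps the same
stages for TSV cohorts on disk (`syncmeta simulate|metrics|reliability|
surrogate|departure`).

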