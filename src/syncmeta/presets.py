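"""Standard synthetic study conditions.

These configurations define the cohorts on which the pipeline is validated;
they are fixed once and shared by the test suite, the analysis drivers, and
the acceptance script.

``K_MID`` is the moderate coupling of the parameter-recovery sweep. For
natural frequencies uniform on 2π·[0.03, 0.07] rad/s the mean-field Kuramoto
critical coupling is K_c = 4γ/π ≈ 0.16 (γ = half-width of the frequency
distribution); K = 0.1 sits in the partially synchronized regime just below
full locking, where fluctuations of the order parameter — metastability —
are maximal. K = 50 locks the network essentially instantly and K = 0 gives
independent oscillators, so the sweep spans independence → flexibility →
rigidity.
"""

from __future__ import annotations

from .synthdata import SimulationConfig

__all__ = [
    "K_MID",
    "SWEEP_BAND",
    "hsi_like_config",
    "stationary_cohort_config",
    "coupled_cohort_config",
    "sweep_config",
]

K_MID = 0.1
# frequency band used for coupling experiments; the narrower 0.03–0.07 Hz
# band keeps the critical coupling well separated from K = 50
SWEEP_BAND = (0.03, 0.07)


def hsi_like_config(seed: int = 0, n_parcels_per_network: int = 4) -> SimulationConfig:
    """A scaled-down highly-sampled-individual acquisition.

    84 sessions of ~10 min at TR 1.16 s (517 samples), 13 labeled networks
    plus Global, moderate within-network coupling. Parcel count is reduced
    from the full 333-parcel parcellation to keep desk-scale runs tractable;
    the session/duration structure matches the real acquisition.
    """
    n_networks = 13
    sizes = (n_parcels_per_network,) * n_networks
    return SimulationConfig(
        n_parcels=n_networks * n_parcels_per_network,
        network_sizes=sizes,
        n_sessions=84,
        session_duration=517 * 1.16,
        tr=1.16,
        intrinsic_freq_range=(0.01, 0.07),
        coupling_per_network=(K_MID,) * n_networks,
        seed=seed,
    )


def stationary_cohort_config(seed: int = 0) -> SimulationConfig:
    """Reliability-engine test cohort: 24 sessions × 5 min, 20 parcels, 2 networks.

    Moderate coupling in both networks keeps each session in the partially
    synchronized regime, so sync and metastability vary across sessions and
    the convergence profile is informative rather than degenerate.
    """
    return SimulationConfig(
        n_parcels=20,
        network_sizes=(10, 10),
        n_sessions=24,
        session_duration=300.0,
        tr=1.0,
        intrinsic_freq_range=SWEEP_BAND,
        coupling_per_network=(K_MID, K_MID),
        seed=seed,
    )


def coupled_cohort_config(seed: int = 0, coupling: float = 10.0) -> SimulationConfig:
    """Strongly coupled cohort for surrogate-destruction experiments.

    12 parcels in one network at K = 10 (far above critical): within-network
    sync is near 1, so independent phase randomization collapses it toward
    the finite-size floor 1/√N.
    """
    return SimulationConfig(
        n_parcels=12,
        network_sizes=(12,),
        n_sessions=20,
        session_duration=360.0,
        tr=1.0,
        intrinsic_freq_range=SWEEP_BAND,
        coupling_per_network=(coupling,),
        seed=seed,
    )


def sweep_config(coupling: float, seed: int = 0, n_parcels: int = 10) -> SimulationConfig:
    """Single-session, single-network config for the coupling-recovery sweep."""
    return SimulationConfig(
        n_parcels=n_parcels,
        network_sizes=(n_parcels,),
        n_sessions=1,
        session_duration=480.0,
        tr=1.0,
        intrinsic_freq_range=SWEEP_BAND,
        coupling_per_network=(coupling,),
        seed=seed,
    )
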