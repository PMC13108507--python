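"""Synthetic multi-session cohorts of coupled phase oscillators.

Generates parcellated "BOLD-like" session matrices with known ground truth so
the phase, metric, reliability, and surrogate stages can be tested end to end
without external data. Two generators are provided:

``simulate_kuramoto_sessions``
    Community-structured Kuramoto dynamics: each parcel is a phase oscillator
    with an intrinsic frequency in the slow BOLD band (0.01–0.07 Hz by
    default), coupled only to the other parcels of its assigned network with a
    per-network strength ``K_n``. The observed signal is ``cos(θ_p(t))`` plus
    Gaussian noise. Within-network synchrony is tunable from full independence
    (K = 0) to full phase locking (large K).

``simulate_linear_null``
    Independent band-limited Gaussian processes per parcel — the same
    amplitude spectrum occupancy with no interregional coupling, the
    linear-null counterpart of the coupled model.

Sessions of one configured "subject" share natural frequencies (drawn once
per config) but are re-initialized with random phases, emulating independent
scan runs of a single individual.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import (
    Cohort,
    NetworkAssignment,
    SessionSeries,
    ValidationError,
    validate_cohort,
    write_network_assignment,
    write_session,
)

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "make_network_assignment",
    "simulate_kuramoto_sessions",
    "simulate_linear_null",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Raised for an inconsistent SimulationConfig."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    Parameters
    ----------
    n_parcels : int
        Total number of parcels (columns).
    network_sizes : tuple of int
        Sizes of the contiguous network blocks; must partition ``n_parcels``.
    n_sessions : int
        Number of independent sessions ("scan runs") to generate.
    session_duration : float
        Duration of each session in seconds.
    tr : float
        Sampling interval in seconds; ``session_duration / tr`` must be a
        whole number of samples.
    intrinsic_freq_range : (float, float)
        Natural-frequency band in Hz; defaults to the slow BOLD band
        0.01–0.07 Hz and must stay below Nyquist (1 / (2·tr)).
    coupling_per_network : tuple of float
        Dimensionless within-network coupling strength K_n ≥ 0, one per
        network. K = 0 gives independent oscillators; K ≳ 10 with similar
        frequencies phase-locks the network.
    noise_sd : float
        SD of additive Gaussian observation noise, in signal units
        (oscillation amplitude is 1).
    noise_cutoff_hz : float or None
        Low-pass cutoff of the observation noise. Parcel-averaged,
        preprocessed BOLD carries negligible power above ~0.1 Hz, so the
        noise is colored accordingly by default; None gives white noise.
    phase_noise_sd : float
        Intensity of Brownian phase jitter (rad·s^-1/2) entering the Euler–
        Maruyama integration.
    seed : int
        Master seed; identical configs produce bit-identical cohorts.
    """

    n_parcels: int
    network_sizes: tuple[int, ...]
    n_sessions: int
    session_duration: float
    tr: float
    intrinsic_freq_range: tuple[float, float] = (0.01, 0.07)
    coupling_per_network: tuple[float, ...] = ()
    noise_sd: float = 0.1
    noise_cutoff_hz: float | None = 0.1
    phase_noise_sd: float = 0.05
    seed: int = 0
    network_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "network_sizes", tuple(int(s) for s in self.network_sizes))
        coupling = self.coupling_per_network or (0.0,) * len(self.network_sizes)
        object.__setattr__(self, "coupling_per_network", tuple(float(k) for k in coupling))
        object.__setattr__(
            self, "intrinsic_freq_range", tuple(float(f) for f in self.intrinsic_freq_range)
        )
        if sum(self.network_sizes) != self.n_parcels:
            raise ConfigurationError(
                f"network_sizes {self.network_sizes} sum to {sum(self.network_sizes)}, "
                f"not n_parcels = {self.n_parcels}"
            )
        if len(self.coupling_per_network) != len(self.network_sizes):
            raise ConfigurationError(
                "coupling_per_network must have one entry per network"
            )
        if any(k < 0 for k in self.coupling_per_network):
            raise ConfigurationError("coupling strengths must be >= 0")
        n_samples = self.session_duration / self.tr
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ConfigurationError(
                f"session_duration/tr = {n_samples} is not a whole number of samples"
            )
        lo, hi = self.intrinsic_freq_range
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0.0 < lo < hi):
            raise ConfigurationError("intrinsic_freq_range must satisfy 0 < lo < hi")
        if hi >= nyquist:
            raise ConfigurationError(
                f"intrinsic_freq_range upper bound {hi} Hz is at or above "
                f"Nyquist {nyquist} Hz for tr = {self.tr} s"
            )
        if self.network_labels is not None and len(self.network_labels) != len(
            self.network_sizes
        ):
            raise ConfigurationError("network_labels must match network_sizes")

    @property
    def n_samples(self) -> int:
        return int(round(self.session_duration / self.tr))

    @property
    def labels(self) -> tuple[str, ...]:
        if self.network_labels is not None:
            return tuple(self.network_labels)
        return tuple(f"N{i}" for i in range(len(self.network_sizes)))


def make_network_assignment(
    network_sizes: Sequence[int], labels: Sequence[str]
) -> NetworkAssignment:
    """Contiguous block assignment of parcels to labeled networks.

    Parcel ids are ``P000, P001, ...``; an all-parcel "Global" network is
    always appended after the labeled networks.
    """
    if len(labels) != len(network_sizes):
        raise ValidationError("labels and network_sizes must have equal length")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate network labels")
    n_total = int(sum(network_sizes))
    width = max(3, len(str(n_total - 1)))
    pairs = []
    parcel = 0
    for size, label in zip(network_sizes, labels):
        for _ in range(int(size)):
            pairs.append((f"P{parcel:0{width}d}", label))
            parcel += 1
    return NetworkAssignment.from_pairs(pairs)


def _parcel_ids(config: SimulationConfig) -> tuple[str, ...]:
    return make_network_assignment(config.network_sizes, config.labels).parcel_ids


def simulate_kuramoto_sessions(config: SimulationConfig) -> list[SessionSeries]:
    """Euler–Maruyama integration of community-coupled Kuramoto oscillators.

    dθ_p = ω_p dt + (K_n/|n|) Σ_{q∈n} sin(θ_q − θ_p) dt + σ_φ dW_p

    with the mean-field identity Σ_q sin(θ_q − θ_p) = |n| R_n sin(ψ_n − θ_p)
    used per network. Integration runs at an internal step of tr/10 and is
    subsampled to TR. Natural frequencies ω_p are drawn once per config
    (2π × uniform over ``intrinsic_freq_range``); each session starts from
    fresh uniform random phases. Observed signal: cos(θ_p(t)) + noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x4B]))
    lo, hi = config.intrinsic_freq_range
    omega = 2.0 * np.pi * rng.uniform(lo, hi, size=config.n_parcels)

    # internal step tr/10, refined when strong coupling would destabilize
    # explicit Euler (need K·dt ≲ 0.2)
    k_max = max(config.coupling_per_network, default=0.0)
    dt_max = config.tr / 10.0 if k_max <= 0 else min(config.tr / 10.0, 0.2 / k_max)
    n_sub = int(np.ceil(config.tr / dt_max))
    dt = config.tr / n_sub
    sqrt_dt = np.sqrt(dt)
    n_samples = config.n_samples

    # per-network slices (contiguous blocks)
    edges = np.concatenate([[0], np.cumsum(config.network_sizes)])
    blocks = [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    parcel_ids = _parcel_ids(config)
    sessions = []
    for s in range(config.n_sessions):
        theta = rng.uniform(-np.pi, np.pi, size=config.n_parcels)
        phases = np.empty((n_samples, config.n_parcels))
        for t in range(n_samples):
            phases[t] = theta
            for _ in range(n_sub):
                drift = omega.copy()
                for block, k in zip(blocks, config.coupling_per_network):
                    if k > 0.0:
                        z = np.exp(1j * theta[block]).mean()
                        drift[block] = drift[block] + k * np.abs(z) * np.sin(
                            np.angle(z) - theta[block]
                        )
                theta = theta + drift * dt
                if config.phase_noise_sd > 0.0:
                    theta = theta + config.phase_noise_sd * sqrt_dt * rng.standard_normal(
                        config.n_parcels
                    )
        data = np.cos(phases)
        if config.noise_sd > 0.0:
            data = data + _observation_noise(
                rng, data.shape, config.noise_sd, config.noise_cutoff_hz, config.tr
            )
        sessions.append(
            SessionSeries(
                data=data,
                tr=config.tr,
                session_id=f"ses-{s:03d}",
                parcel_ids=parcel_ids,
            )
        )
    return sessions


def _observation_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sd: float,
    cutoff_hz: float | None,
    tr: float,
) -> np.ndarray:
    """Gaussian observation noise, low-passed to ``cutoff_hz`` unless None."""
    noise = rng.standard_normal(shape)
    if cutoff_hz is None:
        return sd * noise
    freqs = np.fft.rfftfreq(shape[0], d=tr)
    spec = np.fft.rfft(noise, axis=0)
    spec[freqs > cutoff_hz, :] = 0.0
    noise = np.fft.irfft(spec, n=shape[0], axis=0)
    scale = noise.std(axis=0)
    scale[scale == 0.0] = 1.0
    return sd * noise / scale


def simulate_linear_null(config: SimulationConfig) -> list[SessionSeries]:
    """Independent band-limited Gaussian processes per parcel.

    Each parcel's series is white Gaussian noise spectrally masked to
    ``intrinsic_freq_range`` (hard brick-wall mask in the rFFT domain), scaled
    to unit variance, plus observation noise. No cross-parcel dependence by
    construction; parcels use independent child seeds, so permuting the parcel
    order commutes with generation.
    """
    n_samples = config.n_samples
    lo, hi = config.intrinsic_freq_range
    freqs = np.fft.rfftfreq(n_samples, d=config.tr)
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ConfigurationError(
            "session too short: no FFT bin falls inside intrinsic_freq_range"
        )
    parcel_ids = _parcel_ids(config)
    master = np.random.SeedSequence([config.seed, 0x11])
    session_seeds = master.spawn(config.n_sessions)
    sessions = []
    for s in range(config.n_sessions):
        parcel_seeds = session_seeds[s].spawn(config.n_parcels)
        data = np.empty((n_samples, config.n_parcels))
        for p in range(config.n_parcels):
            rng = np.random.default_rng(parcel_seeds[p])
            white = rng.standard_normal(n_samples)
            spec = np.fft.rfft(white)
            spec[~band] = 0.0
            x = np.fft.irfft(spec, n=n_samples)
            sd = x.std()
            if sd > 0:
                x = x / sd
            if config.noise_sd > 0.0:
                x = x + config.noise_sd * rng.standard_normal(n_samples)
            data[:, p] = x
        sessions.append(
            SessionSeries(
                data=data,
                tr=config.tr,
                session_id=f"ses-{s:03d}",
                parcel_ids=parcel_ids,
            )
        )
    return sessions


def write_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    kind: str = "kuramoto",
) -> Cohort:
    """Generate a cohort and write it as TSV sessions + assignment + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "kuramoto":
        sessions = simulate_kuramoto_sessions(config)
    elif kind == "linear-null":
        sessions = simulate_linear_null(config)
    else:
        raise ConfigurationError(f"unknown generator kind {kind!r}")
    assignment = make_network_assignment(config.network_sizes, config.labels)
    for session in sessions:
        write_session(session, out_dir / f"{session.session_id}.tsv")
    write_network_assignment(assignment, out_dir / "networks.tsv")
    manifest = {
        "kind": kind,
        "tr": config.tr,
        "sessions": [f"{s.session_id}.tsv" for s in sessions],
        "assignment": "networks.tsv",
        "config": asdict(config),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return validate_cohort(sessions, assignment)
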