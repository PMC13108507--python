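"""Empirical mode decomposition, instantaneous phase, and session trimming.

A parcel's BOLD signal is decomposed into intrinsic mode functions (IMFs) by
iterative sifting: locate local extrema, fit cubic-spline upper and lower
envelopes (with mirror-extended extrema to tame the end effect), subtract the
envelope mean, and repeat until a Cauchy-style stopping criterion is met; the
residual is then sifted recursively. Mode 0 is the fastest oscillatory
component; for slow BOLD fluctuations it typically occupies roughly
0.04–0.07 Hz, with mode 1 the 0.01–0.04 Hz band below it.

Instantaneous phase comes from the analytic signal (Hilbert transform):
θ(t) = arg[x(t) + i·H{x}(t)]. Because both sifting and the analytic signal
misbehave near the series ends, a configurable number of samples is trimmed
from each end of the *phase* series, after the transform; the first minute of
each session is additionally discarded before sifting to exclude scan-start
transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .dataio import NetworkAssignment, RunConfig, SessionSeries, ValidationError

__all__ = [
    "SiftConfig",
    "IMFDecomposition",
    "PhaseSeries",
    "sift_emd",
    "analytic_phase",
    "session_phases",
    "trimmed_raw",
]


@dataclass(frozen=True)
class SiftConfig:
    """Frozen sifting rules.

    ``sd_threshold``: Cauchy criterion — stop sifting a mode when
    Σ(h_prev − h)² / Σ h_prev² drops below this. ``max_sifts`` caps the inner
    loop; ``max_imfs`` caps the number of extracted modes (only modes 0 and 1
    are consumed downstream); ``n_mirror`` extrema are reflected past each end
    before envelope fitting.
    """

    sd_threshold: float = 0.2
    max_sifts: int = 100
    max_imfs: int = 4
    n_mirror: int = 2


@dataclass(frozen=True)
class IMFDecomposition:
    """Ordered IMFs (mode 0 = fastest) plus the final residual for one signal."""

    imfs: np.ndarray  # (n_imfs, n_time); may be empty (0, n_time)
    residual: np.ndarray
    degenerate: bool = False  # True when the input had < 4 extrema

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take the midpoint)."""
    dx = np.diff(x)
    # collapse exact plateaus so sign changes are detectable
    sign = np.sign(dx)
    nonzero = np.flatnonzero(sign)
    if nonzero.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    maxima, minima = [], []
    for a, b in zip(nonzero[:-1], nonzero[1:]):
        if sign[a] > 0 and sign[b] < 0:
            maxima.append((a + 1 + b) // 2)
        elif sign[a] < 0 and sign[b] > 0:
            minima.append((a + 1 + b) // 2)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirror_extend(
    idx: np.ndarray, val: np.ndarray, n_time: int, n_mirror: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to ``n_mirror`` extrema about each end of the time axis."""
    k = min(n_mirror, idx.size)
    left_t = (2 * 0 - idx[:k])[::-1]
    left_v = val[:k][::-1]
    right_t = (2 * (n_time - 1) - idx[-k:])[::-1]
    right_v = val[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([left_v, val, right_v])
    # reflection can produce duplicate abscissae when an extremum sits at an end
    t, keep = np.unique(t, return_index=True)
    return t, v[keep]


def _envelope_mean(x: np.ndarray, n_mirror: int) -> np.ndarray | None:
    """Mean of the cubic-spline extrema envelopes, or None if too few extrema."""
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    n = x.size
    grid = np.arange(n)
    t_max, v_max = _mirror_extend(maxima, x[maxima], n, n_mirror)
    t_min, v_min = _mirror_extend(minima, x[minima], n, n_mirror)
    upper = CubicSpline(t_max, v_max)(grid)
    lower = CubicSpline(t_min, v_min)(grid)
    return 0.5 * (upper + lower)


def sift_emd(
    signal: np.ndarray,
    max_imfs: int | None = None,
    sift_config: SiftConfig = SiftConfig(),
) -> IMFDecomposition:
    """Decompose one time series into IMFs + residual by EMD sifting.

    The decomposition is complete by construction: the sum of the IMFs and the
    residual equals the input to floating-point round-off. A signal with fewer
    than 4 local extrema cannot be sifted and is returned whole as the
    residual with ``degenerate=True``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValidationError("sift_emd expects a 1-D signal")
    if x.size < 16:
        raise ValidationError(f"signal too short to sift ({x.size} < 16 samples)")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in signal")

    if max_imfs is None:
        max_imfs = sift_config.max_imfs

    maxima, minima = _local_extrema(x)
    if maxima.size + minima.size < 4:
        return IMFDecomposition(
            imfs=np.empty((0, x.size)), residual=x.copy(), degenerate=True
        )

    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        h = residual.copy()
        for _ in range(sift_config.max_sifts):
            mean_env = _envelope_mean(h, sift_config.n_mirror)
            if mean_env is None:
                break
            h_new = h - mean_env
            denom = np.sum(h * h)
            if denom == 0.0:
                h = h_new
                break
            sd = np.sum((h - h_new) ** 2) / denom
            h = h_new
            if sd < sift_config.sd_threshold:
                break
        else:
            warnings.warn("sift cap reached before the stopping criterion", stacklevel=2)
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break  # h is not oscillatory; leave it in the residual
        imfs.append(h)
        residual = residual - h
        r_max, r_min = _local_extrema(residual)
        if r_max.size + r_min.size < 4:
            break
    return IMFDecomposition(
        imfs=np.asarray(imfs) if imfs else np.empty((0, x.size)),
        residual=residual,
    )


def analytic_phase(
    imf: np.ndarray, tr: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous phase, amplitude, and frequency of a narrowband signal.

    The analytic signal is built in the frequency domain (positive frequencies
    doubled, negative zeroed, DC/Nyquist kept). Phase is its argument in
    (−π, π]; amplitude its modulus; instantaneous frequency the derivative of
    the unwrapped phase over 2π·tr (centered differences, one-sided at the
    ends).
    """
    x = np.asarray(imf, dtype=float)
    if x.ndim != 1:
        raise ValidationError("analytic_phase expects a 1-D signal")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in signal")
    if not np.any(x):
        raise ValidationError("all-zero signal: phase undefined")
    analytic = hilbert(x)
    phase = np.angle(analytic)
    phase[phase == -np.pi] = np.pi  # keep the (−π, π] convention
    amplitude = np.abs(analytic)
    inst_freq = np.gradient(np.unwrap(phase)) / (2.0 * np.pi * tr)
    return phase, amplitude, inst_freq


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase θ_p(t), time × parcels, for one EMD mode.

    ``n_trimmed_start`` counts raw samples removed before the first retained
    phase sample (initial discard + edge trim); ``n_trimmed_end`` counts the
    edge-trim samples removed from the tail.
    """

    phases: np.ndarray
    tr: float
    parcel_ids: tuple[str, ...]
    mode_index: int
    n_trimmed_start: int
    n_trimmed_end: int
    session_id: str = ""

    @property
    def n_time(self) -> int:
        return self.phases.shape[0]

    @property
    def duration(self) -> float:
        """Retained duration in seconds."""
        return self.n_time * self.tr


def _trim_bounds(session: SessionSeries, config: RunConfig) -> tuple[int, int]:
    n_discard = int(np.floor(config.discard_initial / session.tr))
    start = n_discard + config.edge_trim
    stop = session.n_time - config.edge_trim
    min_needed = n_discard + 2 * config.edge_trim + 16
    if session.n_time < min_needed:
        raise ValidationError(
            f"session {session.session_id!r} too short: {session.n_time} samples, "
            f"need at least {min_needed} "
            f"({min_needed * session.tr:.1f} s at tr = {session.tr} s)"
        )
    return start, stop


def session_phases(
    session: SessionSeries,
    assignment: NetworkAssignment,
    config: RunConfig,
    sift_config: SiftConfig = SiftConfig(),
) -> PhaseSeries:
    """Full per-session phase extraction with the standard trimming protocol.

    Per parcel: drop the first ``⌊discard_initial/tr⌋`` raw samples, sift,
    select mode ``config.mode_index``, take the analytic-signal phase, then
    trim ``config.edge_trim`` samples from each end of the phase series. All
    parcels share the identical retained time grid.
    """
    start, stop = _trim_bounds(session, config)
    n_discard = start - config.edge_trim
    raw = session.data[n_discard:, :]
    n_keep = raw.shape[0] - 2 * config.edge_trim
    phases = np.empty((n_keep, session.n_parcels))
    for p in range(session.n_parcels):
        decomp = sift_emd(raw[:, p], sift_config=sift_config)
        if decomp.n_imfs <= config.mode_index:
            raise ValidationError(
                f"session {session.session_id!r}, parcel {session.parcel_ids[p]!r}: "
                f"only {decomp.n_imfs} IMFs, cannot select mode {config.mode_index}"
            )
        phase, _, _ = analytic_phase(decomp.imfs[config.mode_index], session.tr)
        if config.edge_trim:
            phase = phase[config.edge_trim : -config.edge_trim]
        phases[:, p] = phase
    return PhaseSeries(
        phases=phases,
        tr=session.tr,
        parcel_ids=session.parcel_ids,
        mode_index=config.mode_index,
        n_trimmed_start=start,
        n_trimmed_end=config.edge_trim,
        session_id=session.session_id,
    )


def trimmed_raw(session: SessionSeries, config: RunConfig) -> np.ndarray:
    """Raw data restricted to the same retained window as ``session_phases``.

    Used by the static-FC comparator so phase metrics and FC see identical
    session trimming.
    """
    start, stop = _trim_bounds(session, config)
    return session.data[start:stop, :]
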