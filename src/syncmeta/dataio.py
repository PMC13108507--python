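"""Read/write parcellated session time series, network assignments, and run configuration.

The on-disk interface is plain delimited text (TSV): a session file has a header
row of parcel ids and one row per TR sample; a network-assignment file has two
columns ``parcel_id`` and ``network``. Run configuration is YAML. CIFTI/BIDS
handling is deliberately out of scope — the analysis begins after parcellation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SessionSeries",
    "NetworkAssignment",
    "RunConfig",
    "Cohort",
    "ValidationError",
    "read_session",
    "write_session",
    "read_network_assignment",
    "write_network_assignment",
    "validate_cohort",
]

GLOBAL_NETWORK = "Global"


class ValidationError(ValueError):
    """Raised when an input file or cohort violates the format contract."""


@dataclass(frozen=True)
class SessionSeries:
    """One session's time × parcels matrix with its repetition time.

    Attributes
    ----------
    data : ndarray, shape (n_time, n_parcels)
        Parcel-averaged BOLD signal, one column per parcel.
    tr : float
        Repetition time (sampling interval) in seconds.
    session_id : str
        Unique session name.
    parcel_ids : tuple of str
        Column labels, aligned to ``data`` columns.
    """

    data: np.ndarray
    tr: float
    session_id: str
    parcel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "parcel_ids", tuple(self.parcel_ids))
        if data.ndim != 2:
            raise ValidationError(
                f"session {self.session_id!r}: data must be 2-D (time × parcels), "
                f"got shape {data.shape}"
            )
        if data.shape[0] < 2:
            raise ValidationError(
                f"session {self.session_id!r}: need at least 2 time points, "
                f"got {data.shape[0]}"
            )
        if len(self.parcel_ids) != data.shape[1]:
            raise ValidationError(
                f"session {self.session_id!r}: {len(self.parcel_ids)} parcel ids "
                f"for {data.shape[1]} columns"
            )
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValidationError(f"session {self.session_id!r}: duplicate parcel ids")
        if self.tr <= 0:
            raise ValidationError(f"session {self.session_id!r}: tr must be positive")
        bad = np.flatnonzero(~np.isfinite(data).all(axis=0))
        if bad.size:
            names = ", ".join(self.parcel_ids[i] for i in bad[:5])
            raise ValidationError(
                f"session {self.session_id!r}: non-finite values in parcel(s) {names}"
            )

    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Session duration in seconds (n_time × tr)."""
        return self.n_time * self.tr


@dataclass(frozen=True)
class NetworkAssignment:
    """Hard assignment of parcels to functional networks.

    The network order is fixed at construction (first appearance in the source,
    with the all-parcel "Global" network appended last) and is used for every
    feature vector in the analysis, so baseline and test vectors always align.
    """

    parcel_to_network: dict[str, str]
    networks: tuple[str, ...]

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "NetworkAssignment":
        mapping: dict[str, str] = {}
        order: list[str] = []
        for parcel, label in pairs:
            if not label:
                raise ValidationError(f"parcel {parcel!r} has an empty network label")
            if parcel in mapping:
                raise ValidationError(f"parcel {parcel!r} listed more than once")
            mapping[parcel] = label
            if label not in order:
                order.append(label)
        if GLOBAL_NETWORK in order:
            raise ValidationError(
                f"{GLOBAL_NETWORK!r} is reserved for the all-parcel network"
            )
        order.append(GLOBAL_NETWORK)
        return cls(parcel_to_network=mapping, networks=tuple(order))

    @property
    def parcel_ids(self) -> tuple[str, ...]:
        return tuple(self.parcel_to_network)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def members(self, network: str) -> tuple[str, ...]:
        """Parcel ids belonging to ``network`` (all parcels for Global)."""
        if network == GLOBAL_NETWORK:
            return self.parcel_ids
        if network not in self.networks:
            raise KeyError(f"unknown network {network!r}")
        return tuple(p for p, n in self.parcel_to_network.items() if n == network)

    def member_indices(self, network: str, parcel_ids: Sequence[str]) -> np.ndarray:
        """Column indices of ``network``'s parcels within ``parcel_ids``."""
        members = set(self.members(network))
        idx = np.array([i for i, p in enumerate(parcel_ids) if p in members], dtype=int)
        return idx


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings shared by the phase, metric, and reliability stages.

    Defaults follow the pipeline's standard protocol: discard the first minute
    of each session (scan-start transients), trim 5 samples from each end of
    each phase series (EMD edge artifacts), 1,000 resampling iterations, and
    the fastest intrinsic mode (mode 0).
    """

    mode_index: int = 0
    discard_initial: float = 60.0
    edge_trim: int = 5
    n_iterations: int = 1000
    duration_increment: float | None = None
    seed: int = 0
    similarity_kind: str = "vector-correlation"

    def __post_init__(self) -> None:
        if self.mode_index not in (0, 1):
            raise ValidationError(f"mode_index must be 0 or 1, got {self.mode_index}")
        if self.edge_trim < 0:
            raise ValidationError("edge_trim must be >= 0")
        if self.discard_initial < 0:
            raise ValidationError("discard_initial must be >= 0")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.similarity_kind not in ("vector-correlation", "scalar-similarity"):
            raise ValidationError(
                f"unknown similarity_kind {self.similarity_kind!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_session(path: str | Path, tr: float, session_id: str | None = None) -> SessionSeries:
    """Read one session from a TSV file (header = parcel ids, rows = samples)."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", header=0, dtype=float, float_precision="round_trip"
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: cannot parse session file: {exc}") from exc
    if frame.empty or frame.shape[1] == 0:
        raise ValidationError(f"{path}: empty session file")
    data = frame.to_numpy(dtype=float)
    nan_cols = np.flatnonzero(np.isnan(data).any(axis=0))
    if nan_cols.size:
        names = ", ".join(frame.columns[i] for i in nan_cols[:5])
        raise ValidationError(f"{path}: missing values in parcel(s) {names}")
    return SessionSeries(
        data=data,
        tr=tr,
        session_id=session_id if session_id is not None else path.stem,
        parcel_ids=tuple(str(c) for c in frame.columns),
    )


def write_session(session: SessionSeries, path: str | Path) -> None:
    """Write a session as TSV with 17 significant digits (exact round trip)."""
    frame = pd.DataFrame(session.data, columns=list(session.parcel_ids))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_network_assignment(path: str | Path) -> NetworkAssignment:
    """Read a parcel→network table (TSV columns ``parcel_id``, ``network``)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if not {"parcel_id", "network"} <= set(frame.columns):
        raise ValidationError(
            f"{path}: expected columns 'parcel_id' and 'network', got {list(frame.columns)}"
        )
    if frame["network"].isna().any() or frame["parcel_id"].isna().any():
        raise ValidationError(f"{path}: empty parcel id or network label")
    pairs = list(zip(frame["parcel_id"], frame["network"]))
    return NetworkAssignment.from_pairs(pairs)


def write_network_assignment(assignment: NetworkAssignment, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "parcel_id": list(assignment.parcel_to_network),
            "network": list(assignment.parcel_to_network.values()),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Cohort:
    """A validated set of sessions sharing TR, parcels, and a network assignment."""

    sessions: tuple[SessionSeries, ...]
    assignment: NetworkAssignment

    @property
    def tr(self) -> float:
        return self.sessions[0].tr

    @property
    def parcel_ids(self) -> tuple[str, ...]:
        return self.sessions[0].parcel_ids

    @property
    def session_ids(self) -> tuple[str, ...]:
        return tuple(s.session_id for s in self.sessions)

    def session(self, session_id: str) -> SessionSeries:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(f"unknown session {session_id!r}")


def validate_cohort(
    sessions: Sequence[SessionSeries], assignment: NetworkAssignment
) -> Cohort:
    """Check that all sessions share TR and parcel ordering and match the assignment."""
    if not sessions:
        raise ValidationError("empty cohort")
    ref = sessions[0]
    offenders = []
    for s in sessions[1:]:
        if s.tr != ref.tr:
            offenders.append(f"{s.session_id} (tr {s.tr} != {ref.tr})")
        elif s.parcel_ids != ref.parcel_ids:
            missing = set(ref.parcel_ids) - set(s.parcel_ids)
            extra = set(s.parcel_ids) - set(ref.parcel_ids)
            detail = []
            if missing:
                detail.append(f"missing {sorted(missing)[:3]}")
            if extra:
                detail.append(f"extra {sorted(extra)[:3]}")
            offenders.append(f"{s.session_id} ({'; '.join(detail) or 'parcel order differs'})")
    if offenders:
        raise ValidationError("inconsistent sessions: " + "; ".join(offenders))
    if set(ref.parcel_ids) != set(assignment.parcel_ids):
        raise ValidationError(
            "session parcels do not match the network assignment table"
        )
    ids = [s.session_id for s in sessions]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate session ids in cohort")
    return Cohort(sessions=tuple(sessions), assignment=assignment)
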