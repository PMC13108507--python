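"""Network synchrony, metastability, feature vectors, and the static-FC comparator.

For the parcels of a network *n* with instantaneous phases θ_p(t), the
Kuramoto order parameter

    φ_n(t) = | ⟨ e^{iθ_p(t)} ⟩_{p∈n} |

measures the instantaneous level of phase alignment (1 = fully locked, → 0
for uniformly dispersed phases). "Sync" is the time mean of φ_n(t) and
"metastability" its standard deviation over time (population normalization,
ddof = 0, the Kuramoto-literature convention); metastability indexes how
flexibly a network moves between coordinated and desynchronized states.

The sync-metastability feature vector concatenates all networks' sync values
followed by all metastability values in the fixed assignment order (14
networks → a 28-dimensional vector). Static functional connectivity — the
Fisher-z-transformed Pearson correlation matrix between parcel time series —
serves as the classical comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import GLOBAL_NETWORK, NetworkAssignment, ValidationError
from .emdphase import PhaseSeries

__all__ = [
    "SyncTimeCourse",
    "NetworkMetrics",
    "FeatureVector",
    "FCMatrix",
    "RedundancyReport",
    "order_parameter",
    "sync_and_metastability",
    "network_metrics",
    "feature_vector",
    "static_fc",
    "fc_vector",
    "metric_redundancy",
]

_FISHER_CLIP = 1.0 - 1e-15  # keeps atanh finite at |r| = 1


@dataclass(frozen=True)
class SyncTimeCourse:
    """Per-network instantaneous synchrony φ_n(t), each series in [0, 1]."""

    phi: np.ndarray  # (n_time, n_networks)
    networks: tuple[str, ...]
    tr: float


@dataclass(frozen=True)
class NetworkMetrics:
    """Per-network sync (mean of φ_n) and metastability (SD of φ_n)."""

    networks: tuple[str, ...]
    sync: np.ndarray
    metastability: np.ndarray

    def __getitem__(self, network: str) -> tuple[float, float]:
        i = self.networks.index(network)
        return float(self.sync[i]), float(self.metastability[i])


@dataclass(frozen=True)
class FeatureVector:
    """Ordered metric vector; for kind='combined' sync block precedes metastability."""

    values: np.ndarray
    kind: str
    labels: tuple[str, ...]


@dataclass(frozen=True)
class FCMatrix:
    """Fisher-z-transformed Pearson correlation matrix between parcels."""

    z: np.ndarray
    parcel_ids: tuple[str, ...]


def order_parameter(
    phases: PhaseSeries | np.ndarray, parcel_subset: np.ndarray | None = None
) -> np.ndarray:
    """Kuramoto order parameter time series over a subset of parcels.

    φ(t) is the modulus of the complex mean of the unit phasors e^{iθ_p(t)}
    over the subset, evaluated per time point.
    """
    theta = phases.phases if isinstance(phases, PhaseSeries) else np.asarray(phases)
    if parcel_subset is not None:
        subset = np.asarray(parcel_subset, dtype=int)
        if subset.size == 0:
            raise ValidationError("empty parcel subset")
        theta = theta[:, subset]
    if theta.ndim != 2 or theta.shape[1] == 0:
        raise ValidationError("phase matrix must be 2-D with at least one parcel")
    # modulus can exceed 1 by float round-off for a single phasor
    return np.minimum(np.abs(np.exp(1j * theta).mean(axis=1)), 1.0)


def sync_and_metastability(phi: np.ndarray) -> tuple[float, float]:
    """Time mean and population SD (ddof = 0) of an order-parameter series."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1 or phi.size < 2:
        raise ValidationError("need an order-parameter series of length >= 2")
    return float(phi.mean()), float(phi.std(ddof=0))


def sync_time_course(
    phases: PhaseSeries, assignment: NetworkAssignment
) -> SyncTimeCourse:
    """φ_n(t) for every network of the assignment, including Global."""
    phi = np.empty((phases.n_time, assignment.n_networks))
    for j, network in enumerate(assignment.networks):
        idx = assignment.member_indices(network, phases.parcel_ids)
        if idx.size == 0:
            raise ValidationError(f"network {network!r} has no parcels in this session")
        if idx.size == 1:
            warnings.warn(
                f"network {network!r} has a single parcel; sync is 1 and "
                "metastability 0 by definition",
                stacklevel=2,
            )
        phi[:, j] = order_parameter(phases, idx)
    return SyncTimeCourse(phi=phi, networks=assignment.networks, tr=phases.tr)


def network_metrics(
    phases: PhaseSeries, assignment: NetworkAssignment
) -> NetworkMetrics:
    """Sync and metastability per network (Global included)."""
    course = sync_time_course(phases, assignment)
    return NetworkMetrics(
        networks=course.networks,
        sync=course.phi.mean(axis=0),
        metastability=course.phi.std(axis=0, ddof=0),
    )


def feature_vector(metrics: NetworkMetrics, kind: str) -> FeatureVector:
    """Assemble the ordered feature vector of a NetworkMetrics.

    kind='sync' or 'metastability' give one value per network; 'combined'
    concatenates the sync block then the metastability block (2 × n_networks).
    """
    if kind == "sync":
        return FeatureVector(
            values=metrics.sync.copy(), kind=kind, labels=metrics.networks
        )
    if kind == "metastability":
        return FeatureVector(
            values=metrics.metastability.copy(), kind=kind, labels=metrics.networks
        )
    if kind == "combined":
        labels = tuple(f"sync:{n}" for n in metrics.networks) + tuple(
            f"meta:{n}" for n in metrics.networks
        )
        return FeatureVector(
            values=np.concatenate([metrics.sync, metrics.metastability]),
            kind=kind,
            labels=labels,
        )
    raise ValidationError(f"unknown feature-vector kind {kind!r}")


def static_fc(data: np.ndarray, parcel_ids=None) -> FCMatrix:
    """Fisher-z Pearson correlation matrix of a time × parcels matrix.

    r is clipped to ±(1 − 1e−15) before atanh so perfectly correlated pairs
    map to a large finite z instead of infinity; the clip is inert for real
    data. The diagonal is retained in the matrix but never enters
    ``fc_vector``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValidationError("static FC needs a 2-D matrix with >= 3 time points")
    sd = data.std(axis=0)
    # constant columns accumulate to sd ~ 1e-15, not exactly 0
    dead = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(data).max(axis=0)))
    if parcel_ids is None:
        parcel_ids = tuple(f"P{i:03d}" for i in range(data.shape[1]))
    parcel_ids = tuple(parcel_ids)
    if dead.size:
        names = ", ".join(parcel_ids[i] for i in dead[:5])
        raise ValidationError(f"zero-variance parcel(s): {names}")
    r = np.corrcoef(data, rowvar=False)
    z = np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
    z = 0.5 * (z + z.T)  # enforce exact symmetry against round-off
    return FCMatrix(z=z, parcel_ids=parcel_ids)


def fc_vector(fc: FCMatrix, parcel_subset: np.ndarray) -> FeatureVector:
    """Upper-triangle (diagonal excluded) of a subset's FC submatrix, row-major."""
    subset = np.asarray(parcel_subset, dtype=int)
    if subset.size < 2:
        raise ValidationError("FC vectorization needs a subset of >= 2 parcels")
    sub = fc.z[np.ix_(subset, subset)]
    iu = np.triu_indices(subset.size, k=1)
    labels = tuple(
        f"{fc.parcel_ids[subset[i]]}~{fc.parcel_ids[subset[j]]}"
        for i, j in zip(*iu)
    )
    return FeatureVector(values=sub[iu], kind="fc", labels=labels)


@dataclass(frozen=True)
class RedundancyReport:
    """Cross-correlation structure of per-replicate network metrics."""

    columns: tuple[str, ...]
    corr: np.ndarray
    mean_abs_offdiag: float
    mean_abs_with_global: float | None
    excluded: tuple[str, ...]


def metric_redundancy(
    metric_values: np.ndarray, columns=None, global_label: str = GLOBAL_NETWORK
) -> RedundancyReport:
    """Mean absolute pairwise correlation among metric columns across replicates.

    Rows are replication units (sessions or iterations — the caller decides),
    columns are network metrics. Constant columns are excluded with a warning.
    Also reports the mean |r| restricted to pairs that include the column
    matching ``global_label``, when present.
    """
    values = np.asarray(metric_values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValidationError("need >= 3 replicate rows")
    if columns is None:
        columns = tuple(f"m{i}" for i in range(values.shape[1]))
    columns = tuple(columns)
    sd = values.std(axis=0)
    keep = np.flatnonzero(sd > 0.0)
    excluded = tuple(columns[i] for i in np.flatnonzero(sd == 0.0))
    if excluded:
        warnings.warn(f"constant metric column(s) excluded: {excluded}", stacklevel=2)
    if keep.size < 2:
        raise ValidationError("fewer than 2 non-constant metric columns")
    kept_cols = tuple(columns[i] for i in keep)
    corr = np.corrcoef(values[:, keep], rowvar=False)
    iu = np.triu_indices(keep.size, k=1)
    mean_abs = float(np.abs(corr[iu]).mean())
    mean_abs_global = None
    if global_label in kept_cols:
        g = kept_cols.index(global_label)
        others = [i for i in range(keep.size) if i != g]
        mean_abs_global = float(np.abs(corr[g, others]).mean())
    return RedundancyReport(
        columns=kept_cols,
        corr=corr,
        mean_abs_offdiag=mean_abs,
        mean_abs_with_global=mean_abs_global,
        excluded=excluded,
    )
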