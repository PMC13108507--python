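"""Split-half reliability of network metrics as a function of acquisition time.

The engine repeatedly splits a cohort's sessions into two disjoint halves.
One half defines the "baseline" metric vector (computed from the phase time
courses of all its sessions concatenated in time). From the other half, k
sessions (k = 1 … half size) are drawn at random for each duration level, the
test vector is computed from their concatenation, and its similarity to the
baseline is recorded — Pearson correlation for vectors, a normalized absolute
error (1 − |err|/baseline) for single-network scalars. Averaging over many
unique random splits yields a convergence profile: mean similarity ± SD and a
95% CI of the mean at each total duration.

Because the order parameter is instantaneous, concatenating sessions never
requires cross-session phase continuity; pooled means and SDs of φ_n(t) are
computed from cached per-session moments, and pooled FC from cached
per-session cross-product statistics, so each of the thousands of
iteration × duration cells costs O(networks), not O(time).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import Cohort, GLOBAL_NETWORK, RunConfig, ValidationError
from .emdphase import SiftConfig, session_phases, trimmed_raw
from .netmetrics import (
    FeatureVector,
    NetworkMetrics,
    _FISHER_CLIP,
    feature_vector,
    sync_time_course,
)

__all__ = [
    "SplitPlan",
    "SplitIteration",
    "ReliabilityProfile",
    "CohortCache",
    "build_split_plan",
    "baseline_metrics",
    "convergence_profile",
    "scalar_similarity",
    "scalar_convergence_profile",
    "departure_from_baseline",
    "summarize_profile",
    "msc_session_split",
]

VECTOR_KINDS = ("sync", "metastability", "combined", "fc")


@dataclass(frozen=True)
class SplitIteration:
    """One random half-split and its per-duration session draws."""

    subset_a: tuple[str, ...]
    subset_b: tuple[str, ...]
    samples: tuple[tuple[str, ...], ...]  # samples[k-1] = k sessions drawn from B


@dataclass(frozen=True)
class SplitPlan:
    iterations: tuple[SplitIteration, ...]
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def _n_unique_partitions(n: int) -> int:
    return math.comb(n, n // 2) // 2


def build_split_plan(
    session_ids: Sequence[str], n_iterations: int, seed: int
) -> SplitPlan:
    """Unique random half-splits with fresh per-duration session draws.

    Partition uniqueness ignores the A/B labeling (splitting {1,2}|{3,4} and
    {3,4}|{1,2} are the same partition). For each duration level k within an
    iteration, the k sessions are an independent fresh draw from subset B
    without replacement.
    """
    ids = tuple(session_ids)
    n = len(ids)
    if n < 4 or n % 2:
        raise ValidationError(f"need an even session count >= 4, got {n}")
    bound = _n_unique_partitions(n)
    if n_iterations > bound:
        raise ValidationError(
            f"{n_iterations} unique half-splits requested but only {bound} exist "
            f"for {n} sessions"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B]))
    half = n // 2
    seen: set[frozenset] = set()
    iterations = []
    while len(iterations) < n_iterations:
        perm = rng.permutation(n)
        a = frozenset(perm[:half])
        key = a if 0 in a else frozenset(perm[half:])
        if key in seen:
            continue
        seen.add(key)
        subset_a = tuple(ids[i] for i in sorted(perm[:half]))
        subset_b = tuple(ids[i] for i in sorted(perm[half:]))
        samples = tuple(
            tuple(rng.choice(subset_b, size=k, replace=False))
            for k in range(1, half + 1)
        )
        iterations.append(
            SplitIteration(subset_a=subset_a, subset_b=subset_b, samples=samples)
        )
    return SplitPlan(iterations=tuple(iterations), seed=seed)


class CohortCache:
    """Per-session sufficient statistics for pooled metrics.

    For every session: the number of retained samples, per-network Σφ and
    Σφ², and (for FC) the column sums and cross-product matrix of the trimmed
    raw data. Metrics of any concatenation of sessions follow exactly from
    the summed statistics.
    """

    def __init__(
        self,
        cohort: Cohort,
        config: RunConfig,
        sift_config: SiftConfig = SiftConfig(),
    ) -> None:
        self.cohort = cohort
        self.config = config
        self.networks = cohort.assignment.networks
        self.n_time: dict[str, int] = {}
        self.phi_sum: dict[str, np.ndarray] = {}
        self.phi_sumsq: dict[str, np.ndarray] = {}
        self.raw_sum: dict[str, np.ndarray] = {}
        self.raw_cross: dict[str, np.ndarray] = {}
        self.session_minutes: dict[str, float] = {}
        for session in cohort.sessions:
            ph = session_phases(session, cohort.assignment, config, sift_config)
            course = sync_time_course(ph, cohort.assignment)
            sid = session.session_id
            self.n_time[sid] = course.phi.shape[0]
            self.phi_sum[sid] = course.phi.sum(axis=0)
            self.phi_sumsq[sid] = (course.phi**2).sum(axis=0)
            raw = trimmed_raw(session, config)
            self.raw_sum[sid] = raw.sum(axis=0)
            self.raw_cross[sid] = raw.T @ raw
            self.session_minutes[sid] = ph.duration / 60.0

    def pooled_metrics(self, session_ids: Sequence[str]) -> NetworkMetrics:
        n = sum(self.n_time[s] for s in session_ids)
        total = sum(self.phi_sum[s] for s in session_ids)
        totsq = sum(self.phi_sumsq[s] for s in session_ids)
        mean = total / n
        var = np.maximum(totsq / n - mean**2, 0.0)
        return NetworkMetrics(
            networks=self.networks, sync=mean, metastability=np.sqrt(var)
        )

    def pooled_fc_vector(self, session_ids: Sequence[str]) -> np.ndarray:
        """Fisher-z upper triangle of the FC of the concatenated trimmed raw data."""
        n = sum(self.n_time[s] for s in session_ids)
        total = sum(self.raw_sum[s] for s in session_ids)
        cross = sum(self.raw_cross[s] for s in session_ids)
        mean = total / n
        cov = cross / n - np.outer(mean, mean)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if np.any(sd <= 1e-12 * np.maximum(1.0, np.abs(mean))):
            raise ValidationError("zero-variance parcel in pooled FC")
        r = cov / np.outer(sd, sd)
        z = np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
        iu = np.triu_indices(z.shape[0], k=1)
        return z[iu]

    def vector(self, session_ids: Sequence[str], metric_kind: str) -> np.ndarray:
        if metric_kind == "fc":
            return self.pooled_fc_vector(session_ids)
        metrics = self.pooled_metrics(session_ids)
        return feature_vector(metrics, metric_kind).values


@dataclass(frozen=True)
class ReliabilityProfile:
    """Per-duration similarity-to-baseline summary across iterations."""

    metric: str
    durations_min: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_iterations: int
    seed: int
    raw: np.ndarray | None = None  # (n_iterations, n_durations)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        raise ValidationError("zero-variance feature vector in correlation")
    return float((a * b).sum() / denom)


def baseline_metrics(
    cohort_or_cache: Cohort | CohortCache,
    subset_a: Sequence[str],
    metric_kind: str,
    config: RunConfig | None = None,
) -> FeatureVector:
    """Baseline feature vector from the concatenation of one subset's sessions."""
    if not tuple(subset_a):
        raise ValidationError("empty baseline subset")
    cache = _as_cache(cohort_or_cache, config)
    values = cache.vector(tuple(subset_a), metric_kind)
    return FeatureVector(values=values, kind=metric_kind, labels=())


def _as_cache(
    cohort_or_cache: Cohort | CohortCache, config: RunConfig | None
) -> CohortCache:
    if isinstance(cohort_or_cache, CohortCache):
        return cohort_or_cache
    if config is None:
        raise ValidationError("a RunConfig is required when passing a raw cohort")
    return CohortCache(cohort_or_cache, config)


def summarize_profile(
    raw: np.ndarray,
    durations_min: np.ndarray,
    metric: str = "",
    seed: int = 0,
    keep_raw: bool = True,
) -> ReliabilityProfile:
    """Mean, population SD, and 95% normal CI of the mean per duration.

    CI half-width = 1.96·SD/√n_iterations. With a single iteration the SD is
    0 and the CI degenerate (flagged with a warning).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n_iter = raw.shape[0]
    if n_iter < 1:
        raise ValidationError("need at least one iteration")
    if n_iter == 1:
        warnings.warn(
            "single iteration: SD is 0 and the CI degenerate", stacklevel=2
        )
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    half = 1.96 * sd / np.sqrt(n_iter)
    return ReliabilityProfile(
        metric=metric,
        durations_min=np.asarray(durations_min, dtype=float),
        mean=mean,
        sd=sd,
        ci_lo=mean - half,
        ci_hi=mean + half,
        n_iterations=n_iter,
        seed=seed,
        raw=raw if keep_raw else None,
    )


def convergence_profile(
    cohort_or_cache: Cohort | CohortCache,
    plan: SplitPlan,
    metric_kind: str,
    config: RunConfig | None = None,
) -> ReliabilityProfile:
    """Similarity-to-baseline vs. total duration for a vector metric.

    metric_kind ∈ {'sync', 'metastability', 'combined', 'fc'}; similarity is
    the Pearson correlation between the test and baseline vectors.
    """
    if metric_kind not in VECTOR_KINDS:
        raise ValidationError(
            f"metric_kind must be one of {VECTOR_KINDS}, got {metric_kind!r}"
        )
    cache = _as_cache(cohort_or_cache, config)
    minutes = np.mean(list(cache.session_minutes.values()))
    half = len(plan.iterations[0].subset_b)
    raw = np.empty((plan.n_iterations, half))
    for i, it in enumerate(plan.iterations):
        base = cache.vector(it.subset_a, metric_kind)
        for k, sample in enumerate(it.samples):
            test = cache.vector(sample, metric_kind)
            raw[i, k] = _pearson(test, base)
    durations = minutes * np.arange(1, half + 1)
    return summarize_profile(raw, durations, metric=metric_kind, seed=plan.seed)


def scalar_similarity(test: float, baseline: float) -> float:
    """1 − |test − baseline| / |baseline|; negative values are allowed."""
    if baseline == 0:
        raise ValidationError("scalar similarity undefined for a zero baseline")
    return 1.0 - abs(test - baseline) / abs(baseline)


def scalar_convergence_profile(
    cohort_or_cache: Cohort | CohortCache,
    plan: SplitPlan,
    network: str,
    metric: str,
    config: RunConfig | None = None,
) -> ReliabilityProfile:
    """Similarity profile of a single network's scalar sync or metastability.

    Correlation is undefined for scalars, so similarity is the normalized
    absolute error 1 − |test − baseline|/baseline.
    """
    if metric not in ("sync", "metastability"):
        raise ValidationError("metric must be 'sync' or 'metastability'")
    cache = _as_cache(cohort_or_cache, config)
    if network not in cache.networks:
        raise ValidationError(f"unknown network {network!r}")
    j = cache.networks.index(network)
    minutes = np.mean(list(cache.session_minutes.values()))
    half = len(plan.iterations[0].subset_b)
    raw = np.empty((plan.n_iterations, half))
    for i, it in enumerate(plan.iterations):
        base = getattr(cache.pooled_metrics(it.subset_a), metric)[j]
        for k, sample in enumerate(it.samples):
            test = getattr(cache.pooled_metrics(sample), metric)[j]
            raw[i, k] = scalar_similarity(test, base)
    durations = minutes * np.arange(1, half + 1)
    return summarize_profile(
        raw, durations, metric=f"{metric}:{network}", seed=plan.seed
    )


def departure_from_baseline(
    session_vectors: Sequence[FeatureVector | np.ndarray],
    reference_index: int = 0,
) -> np.ndarray:
    """1 − Pearson r of each session's feature vector to the reference session's.

    0 for the reference itself, 1 for an uncorrelated vector, 2 for a
    perfectly anti-correlated one.
    """
    vectors = [
        v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
        for v in session_vectors
    ]
    if len(vectors) < 2:
        raise ValidationError("need at least 2 session vectors")
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise ValidationError(f"feature-vector length mismatch: {sorted(lengths)}")
    ref = vectors[reference_index]
    return np.array([1.0 - _pearson(v, ref) for v in vectors])


def msc_session_split(sessions, parts: int):
    """Divide each session into ``parts`` equal contiguous sub-sessions.

    Used for cohorts of long runs (e.g., 30-min sessions split into three
    10-min sessions) so the half-split engine sees more, shorter sessions.
    """
    from .dataio import SessionSeries

    if parts < 1:
        raise ValidationError("parts must be >= 1")
    if parts == 1:
        return list(sessions)
    out = []
    for session in sessions:
        remainder = session.n_time % parts
        if remainder:
            raise ValidationError(
                f"session {session.session_id!r}: {session.n_time} samples not "
                f"divisible into {parts} parts (remainder {remainder})"
            )
        block = session.n_time // parts
        for j in range(parts):
            out.append(
                SessionSeries(
                    data=session.data[j * block : (j + 1) * block, :],
                    tr=session.tr,
                    session_id=f"{session.session_id}_part{j}",
                    parcel_ids=session.parcel_ids,
                )
            )
    return out
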