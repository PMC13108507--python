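import math

import numpy as np
import pytest

import syncmeta as sm
from syncmeta.dataio import ValidationError
from .conftest import make_tone_session


class TestSplitPlan:
    def test_four_sessions_three_unique_partitions(self):
        ids = ["a", "b", "c", "d"]
        plan = sm.build_split_plan(ids, 3, seed=0)
        partitions = {
            frozenset([frozenset(it.subset_a), frozenset(it.subset_b)])
            for it in plan.iterations
        }
        assert len(partitions) == 3  # C(4,2)/2 = 3, all realized

    def test_requesting_more_than_bound_errors_with_bound(self):
        with pytest.raises(ValidationError, match="3"):
            sm.build_split_plan(["a", "b", "c", "d"], 4, seed=0)

    def test_seed_determinism(self):
        ids = [f"s{i}" for i in range(8)]
        assert sm.build_split_plan(ids, 20, 5) == sm.build_split_plan(ids, 20, 5)

    def test_halves_disjoint_equal_and_samples_from_b(self):
        ids = [f"s{i}" for i in range(10)]
        plan = sm.build_split_plan(ids, 50, seed=2)
        for it in plan.iterations:
            assert set(it.subset_a).isdisjoint(it.subset_b)
            assert len(it.subset_a) == len(it.subset_b) == 5
            assert set(it.subset_a) | set(it.subset_b) == set(ids)
            for k, sample in enumerate(it.samples, start=1):
                assert len(sample) == k == len(set(sample))
                assert set(sample) <= set(it.subset_b)

    def test_odd_session_count_rejected(self):
        with pytest.raises(ValidationError, match="even"):
            sm.build_split_plan(["a", "b", "c"], 1, seed=0)


class TestScalarSimilarity:
    def test_exact_match(self):
        assert sm.scalar_similarity(0.3, 0.3) == 1.0

    def test_hand_examples(self):
        assert sm.scalar_similarity(0.25, 0.2) == pytest.approx(0.75)
        assert sm.scalar_similarity(0.3, 0.1) == pytest.approx(-1.0)  # not clipped

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            sm.scalar_similarity(0.1, 0.0)


class TestSummarizeProfile:
    def test_constant_similarities(self):
        prof = sm.summarize_profile(np.full((10, 3), 0.9), [1, 2, 3])
        np.testing.assert_allclose(prof.mean, 0.9)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.ci_lo, 0.9, atol=1e-12)
        np.testing.assert_allclose(prof.ci_hi, 0.9, atol=1e-12)

    def test_two_iteration_hand_arithmetic(self):
        prof = sm.summarize_profile(np.array([[0.8], [0.9]]), [1.0])
        assert prof.mean[0] == pytest.approx(0.85)
        assert prof.sd[0] == pytest.approx(0.05)
        half = 1.96 * 0.05 / math.sqrt(2)
        assert prof.ci_lo[0] == pytest.approx(0.85 - half)
        assert prof.ci_hi[0] == pytest.approx(0.85 + half)

    def test_ci_shrinks_as_root_n(self, rng):
        sims = rng.normal(0.9, 0.02, size=(400, 1))
        p100 = sm.summarize_profile(sims[:100], [1.0])
        p400 = sm.summarize_profile(sims, [1.0])
        w100 = p100.ci_hi[0] - p100.ci_lo[0]
        w400 = p400.ci_hi[0] - p400.ci_lo[0]
        assert w400 == pytest.approx(w100 / 2, rel=0.25)

    def test_single_iteration_flagged(self):
        with pytest.warns(UserWarning, match="single iteration"):
            prof = sm.summarize_profile(np.array([[0.7, 0.8]]), [1, 2])
        np.testing.assert_allclose(prof.sd, 0.0)
        np.testing.assert_allclose(prof.ci_lo, prof.mean)


class TestDeparture:
    def test_reference_departure_zero(self, rng):
        v = rng.standard_normal(10)
        dep = sm.departure_from_baseline([v, v + rng.standard_normal(10)], 0)
        assert dep[0] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_and_anticorrelated_bounds(self, rng):
        ref = np.tile([1.0, -1.0], 50)
        orth = np.tile([1.0, 1.0, -1.0, -1.0], 25)
        dep = sm.departure_from_baseline([ref, orth, -ref], 0)
        assert dep[1] == pytest.approx(1.0, abs=1e-12)  # r = 0
        assert dep[2] == pytest.approx(2.0, abs=1e-12)  # r = -1

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError, match="mismatch"):
            sm.departure_from_baseline([rng.standard_normal(5), rng.standard_normal(6)])


class TestMscSessionSplit:
    def _session(self, n, sid="long"):
        return make_tone_session(n=n, n_parcels=2, session_id=sid)

    def test_thirty_minutes_into_three_tens(self):
        sessions = sm.msc_session_split([self._session(1800)], parts=3)
        assert len(sessions) == 3
        assert all(s.n_time == 600 for s in sessions)
        # contiguous, non-overlapping reassembly
        np.testing.assert_array_equal(
            np.vstack([s.data for s in sessions]), self._session(1800).data
        )

    def test_ten_sessions_give_thirty(self):
        sessions = [self._session(900, sid=f"s{i}") for i in range(10)]
        assert len(sm.msc_session_split(sessions, parts=3)) == 30

    def test_single_part_identity(self):
        ses = [self._session(500)]
        assert sm.msc_session_split(ses, parts=1) == ses

    def test_indivisible_length_errors_with_remainder(self):
        with pytest.raises(ValidationError, match="remainder 1"):
            sm.msc_session_split([self._session(601)], parts=3)


def _copies_cohort(n_sessions=6):
    """Cohort whose sessions are bit-identical copies of one deterministic session."""
    cfg = sm.SimulationConfig(
        n_parcels=8, network_sizes=(4, 4), n_sessions=1,
        session_duration=300.0, tr=1.0, intrinsic_freq_range=(0.03, 0.07),
        coupling_per_network=(0.1, 0.1), seed=42,
    )
    base = sm.simulate_kuramoto_sessions(cfg)[0]
    sessions = [
        sm.SessionSeries(
            data=base.data.copy(), tr=base.tr,
            session_id=f"copy{i}", parcel_ids=base.parcel_ids,
        )
        for i in range(n_sessions)
    ]
    asg = sm.make_network_assignment(cfg.network_sizes, cfg.labels)
    return sm.validate_cohort(sessions, asg)


@pytest.fixture(scope="module")
def copies():
    cohort = _copies_cohort()
    rc = sm.RunConfig(discard_initial=30.0, edge_trim=5, n_iterations=10, seed=1)
    cache = sm.CohortCache(cohort, rc)
    plan = sm.build_split_plan(cohort.session_ids, 10, rc.seed)
    return cohort, rc, cache, plan


class TestEngineOnDegenerateCohorts:
    @pytest.mark.parametrize("kind", ["sync", "metastability", "combined", "fc"])
    def test_copies_cohort_similarity_identically_one(self, copies, kind):
        _, _, cache, plan = copies
        prof = sm.convergence_profile(cache, plan, kind)
        np.testing.assert_allclose(prof.mean, 1.0, atol=1e-9)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-9)

    def test_copies_cohort_scalar_similarity_one(self, copies):
        _, _, cache, plan = copies
        prof = sm.scalar_convergence_profile(cache, plan, "Global", "metastability")
        np.testing.assert_allclose(prof.mean, 1.0, atol=1e-9)

    def test_baseline_equals_single_session_metrics(self, copies):
        cohort, rc, cache, _ = copies
        single = cache.pooled_metrics(cohort.session_ids[:1])
        concat = cache.pooled_metrics(cohort.session_ids[:4])
        np.testing.assert_allclose(concat.sync, single.sync, atol=1e-12)
        np.testing.assert_allclose(concat.metastability, single.metastability, atol=1e-12)

    def test_self_similarity_is_exactly_one(self, copies):
        """Test sample == baseline subset -> correlation 1 for a deterministic metric."""
        cohort, _, cache, _ = copies
        subset = cohort.session_ids[:3]
        base = sm.baseline_metrics(cache, subset, "combined")
        test = cache.vector(subset, "combined")
        r = np.corrcoef(base.values, test)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def cohort_and_cache():
    cfg = sm.SimulationConfig(
        n_parcels=10, network_sizes=(5, 5), n_sessions=4,
        session_duration=240.0, tr=1.0, intrinsic_freq_range=(0.03, 0.07),
        coupling_per_network=(0.1, 0.3), seed=9,
    )
    sessions = sm.simulate_kuramoto_sessions(cfg)
    asg = sm.make_network_assignment(cfg.network_sizes, cfg.labels)
    cohort = sm.validate_cohort(sessions, asg)
    rc = sm.RunConfig(discard_initial=30.0, edge_trim=5, n_iterations=1, seed=0)
    return cohort, rc, sm.CohortCache(cohort, rc)


class TestPooledStatisticsOracle:
    """The cached-moment pooling must equal direct computation on concatenations."""

    def test_pooled_metrics_match_direct_concatenation(self, cohort_and_cache):
        cohort, rc, cache = cohort_and_cache
        ids = cohort.session_ids[:3]
        stacked = np.vstack(
            [
                sm.session_phases(cohort.session(sid), cohort.assignment, rc).phases
                for sid in ids
            ]
        )
        from syncmeta.emdphase import PhaseSeries

        concat = PhaseSeries(
            phases=stacked, tr=cohort.tr, parcel_ids=cohort.parcel_ids,
            mode_index=0, n_trimmed_start=0, n_trimmed_end=0,
        )
        direct = sm.network_metrics(concat, cohort.assignment)
        pooled = cache.pooled_metrics(ids)
        np.testing.assert_allclose(pooled.sync, direct.sync, atol=1e-12)
        np.testing.assert_allclose(pooled.metastability, direct.metastability, atol=1e-10)

    def test_pooled_fc_matches_direct_concatenation(self, cohort_and_cache):
        cohort, rc, cache = cohort_and_cache
        ids = cohort.session_ids[:3]
        raw = np.vstack([sm.trimmed_raw(cohort.session(sid), rc) for sid in ids])
        fc = sm.static_fc(raw, cohort.parcel_ids)
        direct = sm.fc_vector(fc, np.arange(len(cohort.parcel_ids))).values
        pooled = cache.pooled_fc_vector(ids)
        np.testing.assert_allclose(pooled, direct, atol=1e-9)

    def test_concatenation_order_invariance(self, cohort_and_cache):
        cohort, _, cache = cohort_and_cache
        ids = list(cohort.session_ids[:3])
        a = cache.pooled_metrics(ids)
        b = cache.pooled_metrics(ids[::-1])
        np.testing.assert_allclose(a.sync, b.sync, atol=1e-14)
        np.testing.assert_allclose(a.metastability, b.metastability, atol=1e-14)


class TestEngineDeterminism:
    def test_profile_bit_reproducible(self, stationary_cache, stationary_cohort, run_config):
        plan1 = sm.build_split_plan(stationary_cohort.session_ids, 10, 3)
        plan2 = sm.build_split_plan(stationary_cohort.session_ids, 10, 3)
        p1 = sm.convergence_profile(stationary_cache, plan1, "combined")
        p2 = sm.convergence_profile(stationary_cache, plan2, "combined")
        np.testing.assert_array_equal(p1.raw, p2.raw)

    def test_unknown_metric_kind_rejected(self, stationary_cache, stationary_plan):
        with pytest.raises(ValidationError, match="metric_kind"):
            sm.convergence_profile(stationary_cache, stationary_plan, "bogus")

    def test_unknown_network_rejected(self, stationary_cache, stationary_plan):
        with pytest.raises(ValidationError, match="unknown network"):
            sm.scalar_convergence_profile(stationary_cache, stationary_plan, "Nope", "sync")
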