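import numpy as np
import pytest
from hypothesis import given, strategies as st

import syncmeta as sm
from syncmeta.dataio import ValidationError
from syncmeta.emdphase import PhaseSeries


def phase_series(theta, tr=1.0):
    theta = np.asarray(theta, dtype=float)
    ids = tuple(f"P{i:03d}" for i in range(theta.shape[1]))
    return PhaseSeries(
        phases=theta, tr=tr, parcel_ids=ids, mode_index=0,
        n_trimmed_start=0, n_trimmed_end=0,
    )


def naive_order_parameter(theta):
    """Independent brute-force oracle: per-time-point complex mean via loops."""
    out = np.empty(theta.shape[0])
    for t in range(theta.shape[0]):
        acc = 0j
        for p in range(theta.shape[1]):
            acc += complex(np.cos(theta[t, p]), np.sin(theta[t, p]))
        out[t] = abs(acc / theta.shape[1])
    return out


class TestOrderParameter:
    def test_identical_phases_give_unity(self):
        theta = np.tile(np.linspace(-3, 3, 50)[:, None], (1, 7))
        np.testing.assert_allclose(sm.order_parameter(theta), 1.0, atol=1e-12)

    def test_antipodal_pair_cancels(self):
        theta = np.array([[0.0, np.pi]])
        assert sm.order_parameter(theta)[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_phase_hand_example(self):
        # (e^{i0} + e^{iπ/2} + e^{iπ})/3 = (1 + i - 1)/3 = i/3
        theta = np.array([[0.0, np.pi / 2, np.pi]])
        assert sm.order_parameter(theta)[0] == pytest.approx(1 / 3, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_t = rng.integers(2, 40)
        n_p = rng.integers(1, 20)
        theta = rng.uniform(-np.pi, np.pi, size=(n_t, n_p))
        np.testing.assert_allclose(
            sm.order_parameter(theta), naive_order_parameter(theta), atol=1e-12
        )

    def test_permutation_invariance(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(30, 9))
        perm = rng.permutation(9)
        np.testing.assert_allclose(
            sm.order_parameter(theta), sm.order_parameter(theta[:, perm]), atol=1e-14
        )

    def test_empty_subset_rejected(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(5, 3))
        with pytest.raises(ValidationError, match="empty"):
            sm.order_parameter(theta, np.array([], dtype=int))


class TestSyncAndMetastability:
    def test_constant_series(self):
        sync, meta = sm.sync_and_metastability(np.full(20, 0.7))
        assert sync == pytest.approx(0.7)
        assert meta == pytest.approx(0.0)

    def test_hand_example_population_sd(self):
        sync, meta = sm.sync_and_metastability(np.array([0.2, 0.4, 0.6]))
        assert sync == pytest.approx(0.4)
        assert meta == pytest.approx(np.sqrt(2.0 / 75.0))

    def test_alternating_series_attains_sd_bound(self):
        phi = np.tile([0.0, 1.0], 25)
        sync, meta = sm.sync_and_metastability(phi)
        assert sync == pytest.approx(0.5)
        assert meta == pytest.approx(0.5)  # SD bound for a [0,1] variable

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            sm.sync_and_metastability(np.array([0.5]))

    @given(st.integers(0, 10_000))
    def test_bounds_hold_for_random_phases(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-np.pi, np.pi, size=(rng.integers(2, 60), rng.integers(1, 15)))
        phi = sm.order_parameter(theta)
        sync, meta = sm.sync_and_metastability(phi)
        assert np.all(phi >= 0.0) and np.all(phi <= 1.0)
        assert 0.0 <= sync <= 1.0
        assert 0.0 <= meta <= 0.5


class TestNetworkMetrics:
    def test_identical_phases_all_networks_locked(self, tiny_assignment):
        theta = np.tile(np.linspace(0, 2, 40)[:, None], (1, 5))
        m = sm.network_metrics(phase_series(theta), tiny_assignment)
        np.testing.assert_allclose(m.sync, 1.0, atol=1e-12)
        np.testing.assert_allclose(m.metastability, 0.0, atol=1e-12)

    def test_entry_count_includes_global(self, tiny_assignment, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(30, 5))
        m = sm.network_metrics(phase_series(theta), tiny_assignment)
        assert m.networks == ("A", "B", "Global")

    def test_fourteen_networks_metric_count(self, rng):
        asg = sm.make_network_assignment([2] * 13, [f"n{i}" for i in range(13)])
        theta = rng.uniform(-np.pi, np.pi, size=(20, 26))
        m = sm.network_metrics(phase_series(theta), asg)
        assert len(m.networks) == 14

    def test_singleton_network_warns_and_is_locked(self, rng):
        asg = sm.make_network_assignment([1, 3], ["solo", "rest"])
        theta = rng.uniform(-np.pi, np.pi, size=(25, 4))
        with pytest.warns(UserWarning, match="single parcel"):
            m = sm.network_metrics(phase_series(theta), asg)
        sync, meta = m["solo"]
        assert sync == pytest.approx(1.0)
        assert meta == pytest.approx(0.0)


class TestFeatureVector:
    def _metrics(self, n):
        rng = np.random.default_rng(0)
        return sm.NetworkMetrics(
            networks=tuple(f"n{i}" for i in range(n)),
            sync=rng.uniform(0, 1, n),
            metastability=rng.uniform(0, 0.5, n),
        )

    @pytest.mark.parametrize("n,expected", [(14, 28), (15, 30)])
    def test_combined_length(self, n, expected):
        vec = sm.feature_vector(self._metrics(n), "combined")
        assert vec.values.size == expected

    def test_sync_block_leads_combined(self):
        m = self._metrics(6)
        combined = sm.feature_vector(m, "combined").values
        sync = sm.feature_vector(m, "sync").values
        meta = sm.feature_vector(m, "metastability").values
        np.testing.assert_array_equal(combined[:6], sync)
        np.testing.assert_array_equal(combined[6:], meta)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError, match="kind"):
            sm.feature_vector(self._metrics(3), "bogus")

    def test_network_reorder_equivariance(self, rng):
        """Reordering networks permutes vector entries without changing values."""
        theta = rng.uniform(-np.pi, np.pi, size=(40, 6))
        ids = tuple(f"P{i:03d}" for i in range(6))
        a1 = sm.NetworkAssignment.from_pairs([(p, "X" if i < 3 else "Y") for i, p in enumerate(ids)])
        a2 = sm.NetworkAssignment.from_pairs(
            [(p, "X" if i < 3 else "Y") for i, p in enumerate(ids)][::-1]
        )
        m1 = sm.network_metrics(phase_series(theta), a1)
        m2 = sm.network_metrics(phase_series(theta), a2)
        for net in ("X", "Y", "Global"):
            assert m1[net] == pytest.approx(m2[net])


class TestStaticFC:
    def test_fisher_z_closed_form(self, rng):
        # construct two columns with known r = 0.5 via z-scored mixing
        n = 100_000
        a = rng.standard_normal(n)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        fc = sm.static_fc(np.column_stack([a, b]))
        assert fc.z[0, 1] == pytest.approx(np.arctanh(0.5), abs=0.02)
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_perfect_correlation_clipped_finite(self):
        x = np.linspace(0, 1, 50)
        fc = sm.static_fc(np.column_stack([x, 2 * x + 1]))
        assert np.isfinite(fc.z[0, 1])
        assert fc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-15))

    def test_symmetry_and_diagonal_excluded(self, rng):
        data = rng.standard_normal((60, 5))
        fc = sm.static_fc(data)
        np.testing.assert_array_equal(fc.z, fc.z.T)
        vec = sm.fc_vector(fc, np.arange(5))
        assert vec.values.size == 10  # 5*4/2, no diagonal entries

    def test_zero_variance_parcel_named(self, rng):
        data = rng.standard_normal((30, 3))
        data[:, 1] = 4.2
        with pytest.raises(ValidationError, match="P001"):
            sm.static_fc(data)


class TestFCVector:
    def test_subset_of_three_gives_three_edges(self, rng):
        fc = sm.static_fc(rng.standard_normal((50, 6)))
        assert sm.fc_vector(fc, np.array([0, 2, 5])).values.size == 3

    def test_global_edge_count_formula(self):
        # 333 parcels -> 333*332/2 = 55,278 edges
        assert 333 * 332 // 2 == 55278

    def test_self_correlation_is_one(self, rng):
        fc = sm.static_fc(rng.standard_normal((50, 6)))
        v = sm.fc_vector(fc, np.arange(6)).values
        assert np.corrcoef(v, v)[0, 1] == pytest.approx(1.0)

    def test_small_subset_rejected(self, rng):
        fc = sm.static_fc(rng.standard_normal((50, 6)))
        with pytest.raises(ValidationError):
            sm.fc_vector(fc, np.array([3]))


class TestMetricRedundancy:
    def test_duplicated_columns_fully_redundant(self, rng):
        x = rng.standard_normal(200)
        rep = sm.metric_redundancy(np.column_stack([x, x, x]))
        assert rep.mean_abs_offdiag == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        values = rng.standard_normal((1000, 6))
        rep = sm.metric_redundancy(values)
        # E|r| = sqrt(2/(pi n)) ~ 0.025 at n=1000; 0.08 allows 3 SE of slack
        assert rep.mean_abs_offdiag < 0.08

    def test_anticorrelated_pair_counts_as_redundant(self, rng):
        x = rng.standard_normal(300)
        rep = sm.metric_redundancy(np.column_stack([x, -x]))
        assert rep.mean_abs_offdiag == pytest.approx(1.0)

    def test_constant_column_excluded_with_warning(self, rng):
        values = np.column_stack(
            [rng.standard_normal(100), np.full(100, 2.0), rng.standard_normal(100)]
        )
        with pytest.warns(UserWarning, match="excluded"):
            rep = sm.metric_redundancy(values, columns=("a", "b", "c"))
        assert rep.excluded == ("b",)
        assert rep.columns == ("a", "c")

    def test_global_row_reported(self, rng):
        values = rng.standard_normal((500, 4))
        rep = sm.metric_redundancy(values, columns=("a", "b", "c", "Global"))
        assert rep.mean_abs_with_global is not None
        g = rep.columns.index("Global")
        manual = np.abs(np.delete(rep.corr[g], g)).mean()
        assert rep.mean_abs_with_global == pytest.approx(manual)
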