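import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypermem import (
    InputError,
    TemporalHypergraph,
    adjacency_sequence,
    binned_average,
    cross_order_function,
    cross_order_gap,
    cross_order_matrix,
    interaction_matrix,
    intra_order_function,
    intra_order_matrix,
    variance,
)
from hypermem.correlations import (
    CorrelationSeries,
    interaction_from_csv,
    interaction_to_csv,
    series_from_csv,
    series_to_csv,
)
from oracles import (
    oracle_binned,
    oracle_cross_matrix,
    oracle_cross_trace,
    oracle_gap,
    oracle_intra_matrix,
    oracle_intra_trace,
)

from conftest import random_hypergraph


@pytest.fixture
def blink_pair():
    """N=2: the single dyad present at t=0, absent at t=1."""
    th = TemporalHypergraph(2, 2, [[(0, 1)], []])
    return th, adjacency_sequence(th, 2)


class TestIntraOrderMatrix:
    def test_lag1_hand_value(self, blink_pair):
        _, seq = blink_pair
        assert np.allclose(
            intra_order_matrix(seq, 1), [[-0.25, 0.0], [0.0, -0.25]], atol=1e-12
        )

    def test_lag0_hand_value(self, blink_pair):
        _, seq = blink_pair
        assert np.allclose(
            intra_order_matrix(seq, 0), [[0.25, 0.0], [0.0, 0.25]], atol=1e-12
        )

    def test_constant_sequence_is_zero(self):
        th = TemporalHypergraph(3, 2, [[(0, 1), (1, 2)]] * 5)
        seq = adjacency_sequence(th, 2)
        for tau in range(5):
            assert np.allclose(intra_order_matrix(seq, tau), 0.0, atol=1e-14)

    def test_lag_out_of_range(self, blink_pair):
        _, seq = blink_pair
        with pytest.raises(InputError):
            intra_order_matrix(seq, 2)


class TestIntraOrderFunction:
    def test_blink_pair_traces(self, blink_pair):
        _, seq = blink_pair
        series = intra_order_function(seq, [0, 1])
        assert series.values[0] == pytest.approx(0.5)
        assert series.values[1] == pytest.approx(-0.5)
        assert variance(seq) == pytest.approx(0.5)

    def test_triad_factorial_prefactor(self):
        # single 3-hyperedge present then absent: 1/((d-1)!)^2 = 1/4
        th = TemporalHypergraph(3, 3, [[(0, 1, 2)], []])
        seq = adjacency_sequence(th, 3)
        series = intra_order_function(seq, [1])
        assert series.values[0] == pytest.approx(-0.375)

    def test_trace_of_matrix_form(self, rng):
        th = random_hypergraph(rng, 5, 3, 8, density=0.3)
        seq = adjacency_sequence(th, 2)
        series = intra_order_function(seq, [0, 1, 2, 3])
        for tau, val in zip(series.lags, series.values):
            assert val == pytest.approx(np.trace(intra_order_matrix(seq, int(tau))), abs=1e-12)


class TestCrossOrder:
    def test_same_order_recovers_intra(self, rng):
        th = random_hypergraph(rng, 5, 3, 10, density=0.3)
        seq = adjacency_sequence(th, 3)
        for tau in (0, 2, 5):
            assert (
                cross_order_matrix(seq, seq, tau) == intra_order_matrix(seq, tau)
            ).all()

    def test_constant_second_order_gives_zero(self):
        snaps = [[(0, 1), (0, 1, 2)], [(0, 1, 2)], [(1, 2), (0, 1, 2)]]
        th = TemporalHypergraph(3, 3, snaps)
        s2 = adjacency_sequence(th, 2)
        s3 = adjacency_sequence(th, 3)
        assert np.allclose(cross_order_matrix(s2, s3, 1), 0.0, atol=1e-14)

    def test_mismatched_shapes_rejected(self):
        a = adjacency_sequence(TemporalHypergraph(3, 2, [[(0, 1)], []]), 2)
        b = adjacency_sequence(TemporalHypergraph(4, 2, [[(0, 1)], []]), 2)
        with pytest.raises(InputError):
            cross_order_matrix(a, b, 0)

    def test_symmetric_trace_at_lag_zero(self, rng):
        th = random_hypergraph(rng, 6, 4, 10, density=0.25)
        s2 = adjacency_sequence(th, 2)
        s3 = adjacency_sequence(th, 3)
        c23 = cross_order_function(s2, s3, [0]).values[0]
        c32 = cross_order_function(s3, s2, [0]).values[0]
        assert c23 == pytest.approx(c32, abs=1e-12)

    def test_matches_oracle(self, rng):
        for _ in range(10):
            th = random_hypergraph(rng, 6, 3, 10, density=0.3)
            s2 = adjacency_sequence(th, 2)
            s3 = adjacency_sequence(th, 3)
            for tau in (0, 1, 3):
                assert np.allclose(
                    cross_order_matrix(s2, s3, tau),
                    oracle_cross_matrix(th, 2, 3, tau),
                    atol=1e-10,
                )
                got = cross_order_function(s2, s3, [tau]).values[0]
                assert got == pytest.approx(oracle_cross_trace(th, 2, 3, tau), abs=1e-10)


class TestInteractionMatrix:
    def test_diagonal_half_at_lag_zero(self, rng):
        th = random_hypergraph(rng, 6, 3, 12, density=0.3)
        km = interaction_matrix(th, 0)
        for a, d in enumerate(km.orders):
            if km.variances[a] > 0:
                assert km.entries[a, a] == pytest.approx(0.5, abs=1e-12)

    def test_absent_order_is_nan(self):
        th = TemporalHypergraph(4, 3, [[(0, 1)], [(1, 2)]])  # no 3-hyperedges
        km = interaction_matrix(th, 0)
        idx3 = km.orders.index(3)
        assert np.isnan(km.entries[idx3]).all()
        assert np.isnan(km.entries[:, idx3]).all()

    def test_entries_match_oracle_ratio(self, rng):
        th = random_hypergraph(rng, 5, 3, 10, density=0.35)
        km = interaction_matrix(th, 1)
        sig = {d: oracle_intra_trace(th, d, 0) for d in (2, 3)}
        for a, d1 in enumerate(km.orders):
            for b, d2 in enumerate(km.orders):
                expected = oracle_cross_trace(th, d1, d2, 1) / (
                    2 * math.sqrt(sig[d1] * sig[d2])
                )
                assert km.entries[a, b] == pytest.approx(expected, abs=1e-10)


class TestCrossOrderGap:
    def test_zero_at_lag_zero(self, rng):
        th = random_hypergraph(rng, 6, 3, 12, density=0.3)
        s2 = adjacency_sequence(th, 2)
        s3 = adjacency_sequence(th, 3)
        gap = cross_order_gap(s2, s3, [0])
        assert abs(gap.values[0]) < 1e-12

    def test_antisymmetry(self, rng):
        th = random_hypergraph(rng, 6, 3, 12, density=0.3)
        s2 = adjacency_sequence(th, 2)
        s3 = adjacency_sequence(th, 3)
        lags = [0, 1, 2, 5]
        g23 = cross_order_gap(s2, s3, lags).values
        g32 = cross_order_gap(s3, s2, lags).values
        assert np.allclose(g23, -g32, atol=1e-12)

    def test_matches_oracle(self, rng):
        th = random_hypergraph(rng, 5, 3, 10, density=0.35)
        s2 = adjacency_sequence(th, 2)
        s3 = adjacency_sequence(th, 3)
        got = cross_order_gap(s2, s3, [1, 2]).values
        for k, tau in enumerate((1, 2)):
            assert got[k] == pytest.approx(oracle_gap(th, 2, 3, tau), abs=1e-10)

    def test_zero_variance_yields_nan(self):
        th = TemporalHypergraph(4, 3, [[(0, 1)], [(1, 2)]])
        s2 = adjacency_sequence(th, 2)
        s3 = adjacency_sequence(th, 3)
        gap = cross_order_gap(s2, s3, [1])
        assert np.isnan(gap.values).all()


class TestBinnedAverage:
    def test_single_bin_is_global_stats(self):
        series = CorrelationSeries(
            kind="intra", orders=(2, 2), lags=np.arange(1, 11),
            values=np.arange(1, 11, dtype=float),
        )
        out = binned_average(series, 1)
        assert len(out.binned) == 1
        b = out.binned[0]
        assert b.mean == pytest.approx(5.5)
        assert b.std == pytest.approx(np.arange(1, 11).std())
        assert b.count == 10

    def test_constant_series_zero_std(self):
        series = CorrelationSeries(
            kind="intra", orders=(2, 2), lags=np.arange(1, 50),
            values=np.full(49, 3.25),
        )
        out = binned_average(series, 5)
        assert all(b.std == 0.0 for b in out.binned)
        assert sum(b.count for b in out.binned) == 49

    def test_log_bins_match_independent_recomputation(self, rng):
        lags = np.arange(1, 1001)
        values = rng.normal(size=1000)
        series = CorrelationSeries(kind="cross", orders=(2, 3), lags=lags, values=values)
        out = binned_average(series, 10, scale="log")
        edges = np.geomspace(1, 1000, 11)
        expected = oracle_binned(lags, values, edges, geometric=True)
        assert len(out.binned) == len(expected)
        for got, exp in zip(out.binned, expected):
            assert got.center == pytest.approx(exp[0])
            assert got.mean == pytest.approx(exp[1], abs=1e-12)
            assert got.std == pytest.approx(exp[2], abs=1e-12)
            assert got.count == exp[3]

    def test_linear_bins(self, rng):
        lags = np.arange(0, 100)
        values = rng.normal(size=100)
        series = CorrelationSeries(kind="intra", orders=(2, 2), lags=lags, values=values)
        out = binned_average(series, 4, scale="linear")
        edges = np.linspace(0, 99, 5)
        expected = oracle_binned(lags, values, edges, geometric=False)
        for got, exp in zip(out.binned, expected):
            assert got.mean == pytest.approx(exp[1], abs=1e-12)

    def test_all_nan_rejected(self):
        series = CorrelationSeries(
            kind="gap", orders=(2, 3), lags=np.arange(1, 5), values=np.full(4, np.nan)
        )
        with pytest.raises(InputError):
            binned_average(series, 2)


class TestBinnedProperties:
    @given(
        st.integers(min_value=1, max_value=8),
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False),
            min_size=2, max_size=60,
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_conserved_and_bins_ordered(self, nbins, values):
        series = CorrelationSeries(
            kind="intra", orders=(2, 2),
            lags=np.arange(1, len(values) + 1), values=np.array(values),
        )
        out = binned_average(series, nbins)
        assert sum(b.count for b in out.binned) == len(values)
        centers = [b.center for b in out.binned]
        assert centers == sorted(centers)
        assert all(b.std >= 0 for b in out.binned)


class TestOracleEquivalenceProperty:
    def test_random_instances(self, rng):
        # broad randomized sweep of every estimator against the loops
        for _ in range(50):
            n = int(rng.integers(3, 8))
            d_max = int(rng.integers(2, 5))
            if d_max > n:
                d_max = n
            t_len = int(rng.integers(3, 20))
            th = random_hypergraph(rng, n, d_max, t_len, density=float(rng.uniform(0.05, 0.5)))
            d1 = int(rng.integers(2, d_max + 1))
            d2 = int(rng.integers(2, d_max + 1))
            tau = int(rng.integers(0, t_len))
            s1 = adjacency_sequence(th, d1)
            s2 = adjacency_sequence(th, d2)
            assert np.allclose(
                cross_order_matrix(s1, s2, tau), oracle_cross_matrix(th, d1, d2, tau),
                atol=1e-10,
            )
            assert intra_order_function(s1, [tau]).values[0] == pytest.approx(
                oracle_intra_trace(th, d1, tau), abs=1e-10
            )


class TestCsvRoundTrip:
    def test_series_lossless(self, tmp_path, rng):
        series = CorrelationSeries(
            kind="gap", orders=(2, 3), lags=np.arange(1, 30),
            values=rng.normal(size=29),
        )
        path = tmp_path / "series.csv"
        series_to_csv(series, path)
        back = series_from_csv(path)
        assert back.kind == series.kind
        assert back.orders == series.orders
        assert (back.lags == series.lags).all()
        assert (back.values == series.values).all()  # bit-exact via %.17g

    def test_interaction_lossless(self, tmp_path, rng):
        th = random_hypergraph(rng, 6, 3, 10, density=0.3)
        km = interaction_matrix(th, 1)
        path = tmp_path / "K.csv"
        interaction_to_csv(km, path)
        back = interaction_from_csv(path)
        assert back.lag == km.lag
        assert back.orders == km.orders
        assert np.array_equal(back.entries, km.entries, equal_nan=True)
        assert (back.variances == km.variances).all()
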