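"""Recurrence matrix, white-run period extraction, P(T) and SREPS."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import recamp
from recamp import (EmbeddingParams, RecurrenceMatrix, Series, delay_embed,
                    mean_step_distance, period_distribution,
                    predicted_period_shift, recurrence_matrix,
                    recurrence_periods, sreps, state_distance)
from recamp import synth


def make_matrix(entries):
    e = np.asarray(entries, dtype=bool)
    return RecurrenceMatrix(entries=e, eps_abs=1.0, eps_pct=10.0, metric="maximum")


def brute_force_periods(entries):
    """Independent oracle: character-by-character scan of each column below
    the diagonal, counting zero runs of length >= 2 strictly between ones."""
    n = len(entries)
    found = []
    for t in range(n):
        col = [bool(entries[t + k][t]) for k in range(n - t)]  # offsets 0..
        run = 0
        seen_one = False
        for k, v in enumerate(col):
            if v:
                if seen_one and run >= 2:
                    found.append((t, run))
                run = 0
                seen_one = True
            elif seen_one:
                run += 1
    return sorted(found)


class TestStateDistance:
    def test_closed_forms(self):
        assert state_distance([0, 0], [3, 4], "euclidean") == 5.0
        assert state_distance([0, 0], [3, 4], "maximum") == 4.0
        assert state_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimensions differ"):
            state_distance([1, 2], [1, 2, 3])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=3),
           st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=3))
    @settings(derandomize=True, max_examples=50)
    def test_maximum_norm_bounded_by_euclidean(self, a, b):
        assert state_distance(a, b, "maximum") <= state_distance(a, b, "euclidean") + 1e-9


class TestRecurrenceMatrix:
    def test_huge_eps_all_ones_tiny_eps_identity(self):
        rng = np.random.default_rng(0)
        x = Series(np.cumsum(rng.normal(size=60)), 10.0)
        states = delay_embed(x, EmbeddingParams(2, 3))
        big = recurrence_matrix(states, 1e6, window_std=x.std)
        assert big.entries.all()
        tiny = recurrence_matrix(states, 1e-9, window_std=x.std)
        np.testing.assert_array_equal(tiny.entries, np.eye(states.n_states, dtype=bool))

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        x = Series(rng.normal(size=120), 10.0)
        states = delay_embed(x, EmbeddingParams(3, 2))
        m = recurrence_matrix(states, 30.0, window_std=x.std)
        assert np.array_equal(m.entries, m.entries.T)
        assert m.entries.diagonal().all()

    def test_zero_std_window_degenerate(self):
        states = delay_embed(Series(np.ones(20), 10.0), EmbeddingParams(2, 1))
        m = recurrence_matrix(states, 10.0, window_std=0.0)
        assert m.degenerate and m.n == 0

    def test_periodic_line_spacing(self, sine20):
        # 20 Hz at fs=1000: recurrence points 50 samples apart along a column
        states = delay_embed(sine20, EmbeddingParams(2, 13))
        m = recurrence_matrix(states, 10.0, window_std=sine20.std)
        offsets = np.flatnonzero(m.entries[:, 0])
        spacing = np.diff(offsets)
        assert np.all((spacing >= 49) & (spacing <= 51))
        assert np.median(spacing) == 50


class TestRecurrencePeriods:
    def test_single_column_pattern(self):
        # offsets 1..6 below the reference: [1,1,0,0,0,1] -> one white run of 3
        n = 7
        e = np.eye(n, dtype=bool)
        for j in (1, 2, 6):
            e[j, 0] = e[0, j] = True
        events = [ev for ev in recurrence_periods(make_matrix(e)) if ev.ref_index == 0]
        assert [ev.period for ev in events] == [3]
        assert events[0].span == (2, 6) and events[0].n_span == 5

    def test_all_ones_matrix_has_no_events(self):
        assert recurrence_periods(make_matrix(np.ones((8, 8)))) == []

    def test_fourteen_sample_excursion(self):
        # sojourn cluster, 14 white samples, re-entry: period 14
        n = 20
        e = np.eye(n, dtype=bool)
        e[1, 0] = e[0, 1] = True          # cluster
        e[16, 0] = e[0, 16] = True        # re-entry after 14 zeros
        periods = [ev.period for ev in recurrence_periods(make_matrix(e))
                   if ev.ref_index == 0]
        assert periods == [14]

    def test_trailing_and_length_one_runs_discarded(self):
        # offsets: [1,0,1,0,0] -> the single zero is skipped, trailing run dropped
        n = 6
        e = np.eye(n, dtype=bool)
        for j in (1, 3):
            e[j, 0] = e[0, j] = True
        assert [ev for ev in recurrence_periods(make_matrix(e)) if ev.ref_index == 0] == []

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        upper = rng.random((n, n)) < rng.uniform(0.1, 0.9)
        e = np.triu(upper, 1)
        e = e | e.T
        np.fill_diagonal(e, True)
        got = sorted((ev.ref_index, ev.period) for ev in recurrence_periods(make_matrix(e)))
        assert got == brute_force_periods(e)


class TestPeriodDistribution:
    def test_example_and_normalization(self):
        ev = [recamp.RecurrenceEvent(0, 3, (0, 4), 5),
              recamp.RecurrenceEvent(1, 3, (1, 5), 5),
              recamp.RecurrenceEvent(2, 5, (2, 8), 7)]
        d = period_distribution(ev, 2, 10)
        assert d.prob.sum() == pytest.approx(1.0)
        assert d.prob[d.T_grid == 3] == pytest.approx(2 / 3)
        assert d.prob[d.T_grid == 5] == pytest.approx(1 / 3)

    def test_events_outside_grid_excluded_before_normalization(self):
        ev = [recamp.RecurrenceEvent(0, 3, (0, 4), 5),
              recamp.RecurrenceEvent(1, 99, (1, 101), 101)]
        d = period_distribution(ev, 2, 10)
        assert d.n_events == 1 and d.prob.sum() == pytest.approx(1.0)

    def test_empty_is_degenerate_not_nan(self):
        d = period_distribution([], 2, 10)
        assert d.degenerate and np.all(d.prob == 0) and np.all(np.isfinite(d.prob))

    def test_full_grid_default_needs_n_states(self):
        d = period_distribution([], n_states=100)
        assert d.T_grid[0] == 2 and d.T_grid[-1] == 99
        with pytest.raises(ValueError):
            period_distribution([], 0, 0)

    def test_tmin_below_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            period_distribution([], 1, 10)


@pytest.fixture(scope="module")
def noisy3hz():
    return synth.fig3_slow(seed=1, duration=5.0)


class TestSreps:
    def test_rows_are_distributions(self, noisy3hz, sine20):
        params = EmbeddingParams(2, 13)
        res = sreps(sine20, params, [5.0, 10.0, 20.0])
        sums = res.prob.sum(axis=1)
        np.testing.assert_allclose(sums[~res.degenerate_rows], 1.0)

    def test_small_eps_noise_floor_spreads_mass(self, noisy3hz):
        params = recamp.auto_embedding_params(noisy3hz.samples, max_lag=500)
        res = sreps(noisy3hz, params, [2.0])
        assert not res.degenerate_rows[0]
        assert res.prob[0].max() < 0.05   # no dominant ridge, noise regime

    def test_large_eps_shifts_mass_to_small_periods(self, noisy3hz):
        params = recamp.auto_embedding_params(noisy3hz.samples, max_lag=500)
        res = sreps(noisy3hz, params, [300.0])
        modal = res.T_grid[np.argmax(res.prob[0])]
        assert modal <= 5

    def test_modal_period_nonincreasing_in_eps(self, sine20):
        params = EmbeddingParams(2, 13)
        res = sreps(sine20, params, [5.0, 10.0, 30.0, 60.0, 100.0])
        modal = [res.T_grid[np.argmax(row)] for row in res.prob]
        assert np.all(np.diff(modal) <= 0)

    def test_ridge_shift_two_samples_per_step_distance(self, sine20):
        # growing eps by q state-to-state distances drops the modal period ~2q
        params = EmbeddingParams(2, 13)
        states = delay_embed(sine20, params)
        step_pct = 100 * mean_step_distance(states, "maximum") / sine20.std
        grid = [10.0 + q * step_pct for q in range(4)]
        res = sreps(sine20, params, grid)
        modal = np.array([res.T_grid[np.argmax(row)] for row in res.prob])
        for q in range(4):
            eps_err, t_shift = predicted_period_shift(10.0, q, step_pct)
            assert eps_err == pytest.approx(grid[q])
            assert abs((modal[q] - modal[0]) - t_shift) <= 1

    def test_eps_grid_validation(self, sine20):
        with pytest.raises(ValueError):
            sreps(sine20, EmbeddingParams(2, 13), [10.0, 5.0])


def test_rescaling_leaves_distribution_unchanged(sine20):
    """eps follows the window STD, so P(T) is invariant to amplitude scaling."""
    params = EmbeddingParams(2, 13)

    def dist(series):
        states = delay_embed(series, params)
        m = recurrence_matrix(states, 10.0, window_std=series.std)
        return period_distribution(recurrence_periods(m), n_states=states.n_states)

    d1 = dist(sine20)
    d2 = dist(sine20.scaled(7.3))
    np.testing.assert_allclose(d1.prob, d2.prob)


def test_predicted_shift_closed_form():
    assert predicted_period_shift(10.0, 0, 3.0) == (10.0, 0)
    assert predicted_period_shift(10.0, 3, 3.0) == (19.0, -6)
    with pytest.raises(ValueError):
        predicted_period_shift(10.0, -1, 3.0)
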