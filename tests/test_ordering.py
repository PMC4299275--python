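"""Ordering objective, annealer, oracle and permutation distance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockorder import (
    AnnealConfig,
    DomainError,
    NoSignalError,
    Ordering,
    SampleSet,
    TooFewSamplesError,
    ZeroVarianceError,
    anneal_order,
    canonicalize_ordering,
    circular_autocorrelation,
    exhaustive_order,
    metropolis_accept,
    metropolis_step,
    ordering_distance,
    ordering_error,
    target_autocorrelation,
)


def naive_g(matrix, perm, n_cycles=1):
    """Independent brute-force ordering error: explicit Python loops."""
    x = np.asarray(matrix, float)[np.asarray(perm)]
    n, m = x.shape
    total, count = 0.0, 0
    for j in range(m):
        col = x[:, j]
        xc = col - col.mean()
        denom = float(xc @ xc)
        if denom == 0.0:
            continue
        count += 1
        for tau in range(1, n):
            a = sum(xc[t] * xc[(t + tau) % n] for t in range(n)) / denom
            total += (a - math.cos(2 * math.pi * n_cycles * tau / n)) ** 2
    return total / count


class TestCircularAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        a = circular_autocorrelation(rng.normal(size=17))
        assert a[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(a) <= 1 + 1e-12)

    def test_single_cycle_cosine_gives_cosine_autocorrelation(self):
        n = 16
        t = np.arange(n)
        a = circular_autocorrelation(np.cos(2 * np.pi * t / n))
        np.testing.assert_allclose(a, np.cos(2 * np.pi * t / n), atol=1e-12)

    def test_matches_direct_summation(self, rng):
        x = rng.normal(size=13)
        xc = x - x.mean()
        direct = [
            sum(xc[t] * xc[(t + tau) % 13] for t in range(13)) / float(xc @ xc)
            for tau in range(13)
        ]
        np.testing.assert_allclose(circular_autocorrelation(x), direct, atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ZeroVarianceError):
            circular_autocorrelation(np.array([3.0, 3.0, 3.0, 3.0]))

    def test_too_short_series_rejected(self):
        with pytest.raises(TooFewSamplesError):
            circular_autocorrelation(np.array([1.0, 2.0]))


class TestTargetAutocorrelation:
    def test_quarter_period_values(self):
        np.testing.assert_allclose(
            target_autocorrelation(4).values, [1.0, 0.0, -1.0, 0.0], atol=1e-12
        )

    @pytest.mark.parametrize("n", [5, 12, 31])
    def test_symmetry_and_unit_lag_zero(self, n):
        v = target_autocorrelation(n).values
        assert v[0] == 1.0
        np.testing.assert_allclose(v[1:], v[1:][::-1], atol=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(DomainError):
            target_autocorrelation(2)


class TestOrderingError:
    def test_offset_amplitude_cosine_columns_give_zero(self, rng):
        n, m = 12, 9
        t = np.arange(n)
        cols = [
            c + a * np.cos(2 * np.pi * t / n + ph)
            for c, a, ph in zip(
                rng.uniform(0, 5, m), rng.uniform(0.5, 3, m), rng.uniform(0, 2 * np.pi, m)
            )
        ]
        matrix = np.column_stack(cols)
        assert ordering_error(matrix, np.arange(n)) < 1e-10

    def test_matches_independent_naive_implementation(self, rng):
        matrix = rng.normal(size=(8, 6))
        perm = rng.permutation(8)
        assert ordering_error(matrix, perm) == pytest.approx(
            naive_g(matrix, perm), abs=1e-10
        )

    def test_cyclic_shift_and_reversal_invariance(self, rng):
        matrix = rng.normal(size=(11, 7))
        perm = rng.permutation(11)
        g = ordering_error(matrix, perm)
        assert abs(ordering_error(matrix, np.roll(perm, 4)) - g) < 1e-12
        assert abs(ordering_error(matrix, perm[::-1]) - g) < 1e-12

    def test_constant_columns_excluded_from_average(self, rng):
        matrix = rng.normal(size=(9, 5))
        with_flat = np.column_stack([matrix, np.ones(9)])
        perm = rng.permutation(9)
        assert ordering_error(with_flat, perm) == pytest.approx(
            ordering_error(matrix, perm), abs=1e-12
        )

    def test_all_constant_columns_rejected(self):
        with pytest.raises(NoSignalError):
            ordering_error(np.ones((6, 5)), np.arange(6))

    def test_invalid_permutation_rejected(self, rng):
        with pytest.raises(DomainError):
            ordering_error(rng.normal(size=(6, 5)), np.array([0, 1, 2, 3, 4, 4]))

    @given(shift=st.integers(0, 19), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance_property(self, shift, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.normal(size=(10, 6))
        perm = rng.permutation(10)
        g = ordering_error(matrix, perm)
        assert abs(ordering_error(matrix, np.roll(perm, shift)) - g) < 1e-12


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-0.1, 0.5, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 0.0, rng) for _ in range(100))

    def test_zero_temperature_never_accepts_uphill(self, rng):
        assert not any(metropolis_accept(1e-9, 0.0, rng) for _ in range(100))

    def test_step_returns_valid_ordering(self, rng, noisy_set_factory):
        sset, _, _ = noisy_set_factory(n_samples=10, n_positions=20, seed=4)
        current = Ordering(np.arange(10), ordering_error(sset, np.arange(10)))
        stepped = metropolis_step(current, sset, temperature=0.5, rng=rng)
        assert np.array_equal(np.sort(stepped.permutation), np.arange(10))
        assert stepped.g_value == pytest.approx(
            ordering_error(sset, stepped.permutation), abs=1e-12
        )

    def test_step_at_zero_temperature_never_increases_g(self, noisy_set_factory):
        sset, _, _ = noisy_set_factory(n_samples=8, n_positions=20, seed=5)
        current = Ordering(np.arange(8), ordering_error(sset, np.arange(8)))
        for seed in range(30):
            nxt = metropolis_step(current, sset, temperature=0.0, rng=seed)
            assert nxt.g_value <= current.g_value + 1e-15
            current = nxt


class TestAnnealOrder:
    def test_recovers_true_order_of_noiseless_cosine_set(self, cosine_set_factory):
        sset, _, true_perm = cosine_set_factory(n_samples=16, n_positions=40, seed=2)
        res = anneal_order(sset, AnnealConfig(n_sweeps=300, n_restarts=3, rng_seed=0))
        assert ordering_distance(res.permutation, true_perm) == pytest.approx(0.0, abs=1e-12)

    def test_reported_g_matches_returned_permutation(self, noisy_set_factory):
        sset, _, _ = noisy_set_factory(n_samples=12, n_positions=30, seed=6)
        res = anneal_order(sset, AnnealConfig(n_sweeps=100, n_restarts=2, rng_seed=1))
        assert res.g_value == pytest.approx(ordering_error(sset, res.permutation), abs=1e-12)

    def test_final_g_never_exceeds_first_sweep(self, noisy_set_factory):
        sset, _, _ = noisy_set_factory(n_samples=12, n_positions=30, seed=7)
        res = anneal_order(sset, AnnealConfig(n_sweeps=100, n_restarts=1, rng_seed=2))
        assert res.trace is not None
        assert res.g_value <= res.trace[0] + 1e-12

    def test_zero_sweeps_returns_canonicalized_initial_ordering(self, noisy_set_factory):
        sset, _, _ = noisy_set_factory(n_samples=10, n_positions=20, seed=8)
        res = anneal_order(sset, AnnealConfig(n_sweeps=0, n_restarts=1, rng_seed=3))
        initial = np.random.default_rng(3).permutation(10)
        expected = canonicalize_ordering(sset.matrix, initial)
        np.testing.assert_array_equal(res.permutation, expected)
        assert res.g_value == pytest.approx(ordering_error(sset, initial), abs=1e-12)

    def test_seeded_runs_identical(self, noisy_set_factory):
        sset, _, _ = noisy_set_factory(n_samples=10, n_positions=20, seed=9)
        cfg = AnnealConfig(n_sweeps=50, n_restarts=2, rng_seed=4)
        a = anneal_order(sset, cfg)
        b = anneal_order(sset, cfg)
        np.testing.assert_array_equal(a.permutation, b.permutation)
        assert a.g_value == b.g_value


class TestExhaustiveOrder:
    def test_three_samples_all_orderings_equivalent(self, rng):
        matrix = rng.normal(size=(3, 5))
        from itertools import permutations

        gs = [ordering_error(matrix, np.array(p)) for p in permutations(range(3))]
        assert max(gs) - min(gs) < 1e-12

    def test_noiseless_cosine_set_attains_zero(self, cosine_set_factory):
        sset, _, true_perm = cosine_set_factory(n_samples=6, n_positions=30, seed=1)
        res = exhaustive_order(sset)
        assert res.g_value < 1e-10
        assert ordering_distance(res.permutation, true_perm) == pytest.approx(0.0, abs=1e-12)

    def test_oracle_minimum_bounds_random_permutations(self, noisy_set_factory):
        sset, _, _ = noisy_set_factory(n_samples=7, n_positions=20, seed=10)
        res = exhaustive_order(sset)
        rng = np.random.default_rng(0)
        assert all(
            res.g_value <= ordering_error(sset, rng.permutation(7)) + 1e-12
            for _ in range(1000)
        )

    def test_large_n_guarded(self, rng):
        with pytest.raises(DomainError):
            exhaustive_order(rng.normal(size=(10, 6)))


class TestOrderingDistance:
    def test_identity_shift_and_reversal_are_distance_zero(self, rng):
        perm = rng.permutation(20)
        assert ordering_distance(perm, perm) == pytest.approx(0.0, abs=1e-12)
        assert ordering_distance(perm, np.roll(perm, 3)) == pytest.approx(0.0, abs=1e-12)
        assert ordering_distance(perm, perm[::-1]) == pytest.approx(0.0, abs=1e-12)
        assert ordering_distance(perm, np.roll(perm[::-1], 7)) == pytest.approx(0.0, abs=1e-12)

    def test_random_permutations_are_far(self):
        rng = np.random.default_rng(6)
        far = [
            ordering_distance(rng.permutation(50), rng.permutation(50)) for _ in range(20)
        ]
        assert min(far) > 0.5

    def test_size_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ordering_distance(np.arange(5), np.arange(6))

    def test_matches_scipy_spearman_over_alignments(self, rng):
        from scipy.stats import spearmanr

        n = 12
        a, b = rng.permutation(n), rng.permutation(n)
        ranks_a = np.argsort(a)
        ranks_b = np.argsort(b)
        best = max(
            spearmanr(ranks_a, np.mod(d * ranks_b + s, n)).statistic
            for d in (1, -1)
            for s in range(n)
        )
        assert ordering_distance(a, b) == pytest.approx(1 - best, abs=1e-12)


class TestCanonicalization:
    def test_canonical_form_is_symmetry_invariant(self, cosine_set_factory):
        sset, _, true_perm = cosine_set_factory(n_samples=12, n_positions=40, seed=3)
        base = canonicalize_ordering(sset.matrix, true_perm)
        for variant in (np.roll(true_perm, 5), true_perm[::-1], np.roll(true_perm[::-1], 2)):
            np.testing.assert_array_equal(canonicalize_ordering(sset.matrix, variant), base)

    def test_caudal_series_peaks_at_first_row(self, cosine_set_factory):
        sset, _, true_perm = cosine_set_factory(n_samples=12, n_positions=40, seed=4)
        canon = canonicalize_ordering(sset.matrix, true_perm, caudal_fraction=0.3)
        n_caudal = math.ceil(0.3 * 40)
        series = sset.matrix[canon][:, :n_caudal].mean(axis=1)
        assert series.argmax() == 0
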