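import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tugfall.entropy import (
    MseParams,
    PeParams,
    coarse_grain,
    complexity_index,
    mse_mean,
    mse_profile,
    mse_sd,
    ordinal_distribution,
    ordinal_patterns,
    permutation_entropy,
    sample_entropy,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def sampen_bruteforce(x, m, r):
    """O(N^2) literal pair enumeration, independent of the implementation."""
    x = list(map(float, x))
    n = len(x)
    n_templates = n - m

    def count(length):
        matches = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if max(abs(x[i + t] - x[j + t]) for t in range(length)) <= r:
                    matches += 1
        return matches

    b = count(m)
    a = count(m + 1)
    if b == 0:
        return math.nan
    if a == 0:
        return math.inf
    return -math.log(a / b)


def ordinal_bruteforce(x, order, delay):
    """Column-by-column rank enumeration with explicit tie handling."""
    x = list(map(float, x))
    counts = {}
    n_cols = len(x) - (order - 1) * delay
    for start in range(n_cols):
        window = [x[start + i * delay] for i in range(order)]
        pattern = [0] * order
        order_idx = sorted(range(order), key=lambda i: (window[i], i))
        for rank, i in enumerate(order_idx):
            pattern[i] = rank
        counts[tuple(pattern)] = counts.get(tuple(pattern), 0) + 1
    return {k: v / n_cols for k, v in counts.items()}


# ---------------------------------------------------------------------------
# coarse_grain
# ---------------------------------------------------------------------------

class TestCoarseGrain:
    def test_identity_scale(self):
        np.testing.assert_array_equal(coarse_grain([1, 2, 3, 4, 5, 6], 1), [1, 2, 3, 4, 5, 6])

    def test_block_means(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5, 6], 2), [1.5, 3.5, 5.5])

    def test_truncated_tail(self):
        assert coarse_grain([1, 2, 3, 4, 5, 6, 7], 3).size == 2

    @pytest.mark.parametrize("tau", [0, -1, 11])
    def test_bad_scale(self, tau):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(10), tau)

    @given(n=st.integers(2, 300), tau=st.integers(1, 300))
    @settings(max_examples=60, deadline=None)
    def test_length_is_floor_n_over_tau(self, n, tau):
        if tau > n:
            return
        x = np.random.default_rng(n * 1000 + tau).normal(size=n)
        out = coarse_grain(x, tau)
        assert out.size == n // tau
        if tau == 1:
            np.testing.assert_array_equal(out, x)


# ---------------------------------------------------------------------------
# sample_entropy
# ---------------------------------------------------------------------------

class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy([5.0] * 8, m=2, r_absolute=0.1) == 0.0

    def test_alternating_matches_oracle(self):
        x = [1, 2, 1, 2, 1, 2, 1, 2]
        r = 0.5 * np.std(x)
        assert sample_entropy(x, 2, r) == pytest.approx(sampen_bruteforce(x, 2, r), abs=1e-12)

    def test_long_uniform_matches_oracle(self, rng):
        x = rng.uniform(size=1000)
        r = 0.2 * np.std(x)
        assert sample_entropy(x, 2, r) == pytest.approx(sampen_bruteforce(x, 2, r), abs=1e-12)

    def test_random_series_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            x = rng.normal(size=n)
            m = int(rng.integers(1, 4))
            r = float(rng.uniform(0.1, 0.5)) * np.std(x)
            got = sample_entropy(x, m, r)
            want = sampen_bruteforce(x, m, r)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_no_m_matches_is_nan(self):
        # strictly increasing with huge gaps: no template pairs match
        x = [0, 10, 100, 1000, 10000, 100000]
        assert math.isnan(sample_entropy(x, 2, 0.5))

    def test_errors(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy([1, 2, 3], m=2, r_absolute=0.1)
        with pytest.raises(ValueError, match="tolerance"):
            sample_entropy([1, 2, 3, 4, 5], m=2, r_absolute=0.0)

    def test_non_negative(self, rng):
        for _ in range(10):
            x = rng.normal(size=80)
            v = sample_entropy(x, 2, 0.2 * np.std(x))
            assert math.isnan(v) or v >= 0


# ---------------------------------------------------------------------------
# MSE profile and summaries
# ---------------------------------------------------------------------------

class TestMseProfile:
    def test_tau_max_one_equals_raw_sampen(self, rng):
        x = rng.normal(size=120)
        profile = mse_profile(x, MseParams(m=2, r=0.15, tau_max=1))
        assert profile.size == 1
        assert profile[0] == pytest.approx(sample_entropy(x, 2, 0.15 * np.std(x)), abs=1e-12)

    def test_constant_series_all_zero(self):
        np.testing.assert_array_equal(mse_profile([3.0] * 100, MseParams(tau_max=4)), np.zeros(4))

    def test_white_noise_profile_matches_composed_oracle(self, rng):
        x = rng.normal(size=400)
        params = MseParams(m=2, r=0.15, tau_max=5)
        profile = mse_profile(x, params)
        r_abs = 0.15 * np.std(x)
        for tau in range(1, 6):
            cg = [np.mean(x[i * tau : (i + 1) * tau]) for i in range(len(x) // tau)]
            assert profile[tau - 1] == pytest.approx(
                sampen_bruteforce(cg, 2, r_abs), abs=1e-12
            )

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            mse_profile(np.arange(12), MseParams(tau_max=5))


class TestProfileSummaries:
    def test_zeros(self):
        assert complexity_index([0, 0, 0]) == 0.0
        assert mse_mean([0, 0, 0]) == 0.0
        assert mse_sd([0, 0, 0]) == 0.0

    def test_singleton(self):
        assert complexity_index([1.3]) == pytest.approx(1.3)
        assert mse_mean([1.3]) == pytest.approx(1.3)
        assert mse_sd([1.3]) == 0.0

    def test_ci_is_tau_max_times_mean(self, rng):
        profile = rng.uniform(size=7)
        assert complexity_index(profile) == pytest.approx(7 * mse_mean(profile), abs=1e-12)

    def test_nonfinite_flagged_missing(self):
        assert math.isnan(complexity_index([1.0, math.inf, 0.5]))
        assert math.isnan(mse_mean([1.0, math.nan]))

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            complexity_index([])


# ---------------------------------------------------------------------------
# Ordinal patterns and permutation entropy
# ---------------------------------------------------------------------------

WORKED_SERIES = [8, 5, 4, 3, 11, 9, 1]


class TestOrdinalDistribution:
    def test_worked_example_consistent_entries(self):
        p = ordinal_distribution(WORKED_SERIES, PeParams(order=3, delay=1))
        pats = ordinal_patterns(3)
        assert p[pats.index((0, 1, 2))] == 0.0
        assert p[pats.index((0, 2, 1))] == pytest.approx(1 / 5)
        assert p[pats.index((1, 0, 2))] == pytest.approx(1 / 5)
        assert p[pats.index((1, 2, 0))] == 0.0

    def test_worked_example_full_bruteforce(self):
        p = ordinal_distribution(WORKED_SERIES, PeParams(3, 1))
        want = ordinal_bruteforce(WORKED_SERIES, 3, 1)
        for i, pat in enumerate(ordinal_patterns(3)):
            assert p[i] == pytest.approx(want.get(pat, 0.0))

    def test_monotone_series_single_pattern(self):
        for order, delay in [(2, 1), (3, 1), (4, 2)]:
            p = ordinal_distribution(np.arange(30), PeParams(order, delay))
            pats = ordinal_patterns(order)
            assert p[pats.index(tuple(range(order)))] == 1.0

    def test_random_series_match_bruteforce(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(10, 60)))
            order = int(rng.integers(2, 5))
            delay = int(rng.integers(1, 3))
            if len(x) < order * delay:
                continue
            p = ordinal_distribution(x, PeParams(order, delay))
            want = ordinal_bruteforce(x, order, delay)
            for i, pat in enumerate(ordinal_patterns(order)):
                assert p[i] == pytest.approx(want.get(pat, 0.0))

    def test_ties_broken_by_temporal_order(self):
        p = ordinal_distribution([1.0, 1.0, 2.0], PeParams(3, 1))
        pats = ordinal_patterns(3)
        assert p[pats.index((0, 1, 2))] == 1.0

    def test_sums_to_one(self, rng):
        for _ in range(5):
            p = ordinal_distribution(rng.normal(size=50), PeParams(3, 1))
            assert p.sum() == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            ordinal_distribution([1, 2], PeParams(3, 1))


class TestPermutationEntropy:
    def test_monotone_is_zero(self):
        assert permutation_entropy(np.arange(100), PeParams(3, 1)) == 0.0
        assert permutation_entropy(np.exp(-np.arange(50.0)), PeParams(3, 1)) == 0.0

    def test_alternating_period2_is_one_bit(self):
        x = [1, 2] * 10 + [1]
        assert permutation_entropy(x, PeParams(order=2, delay=1)) == pytest.approx(1.0)

    def test_iid_approaches_log2_factorial(self, rng):
        x = rng.uniform(size=10_000)
        assert permutation_entropy(x, PeParams(3, 1)) == pytest.approx(math.log2(6), abs=0.05)

    def test_bounds(self, rng):
        for _ in range(10):
            pe = permutation_entropy(rng.normal(size=40), PeParams(3, 1))
            assert 0.0 <= pe <= math.log2(6) + 1e-12

    @given(
        # integer-valued bases keep strict monotonicity exact in floats
        data=st.lists(st.integers(-100, 100), min_size=10, max_size=60, unique=True),
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_monotone_transform(self, data, scale, shift):
        x = np.asarray(data, dtype=float)
        params = PeParams(3, 1)
        base = permutation_entropy(x, params)
        assert permutation_entropy(scale * x + shift, params) == pytest.approx(base, abs=1e-9)
        assert permutation_entropy(np.exp(x / 50.0), params) == pytest.approx(base, abs=1e-9)


class TestParams:
    def test_mse_params_validation(self):
        with pytest.raises(ValueError):
            MseParams(m=0)
        with pytest.raises(ValueError):
            MseParams(r=0)
        with pytest.raises(ValueError):
            MseParams(tau_max=0)

    def test_pe_params_validation(self):
        with pytest.raises(ValueError):
            PeParams(order=1)
        with pytest.raises(ValueError):
            PeParams(delay=0)
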