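import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuevote import (
    Category,
    DecisionParams,
    RokuSpmParams,
    ValidationError,
    decision_function_classify,
    roku_entropy,
    roku_spm_classify,
    spm,
    tukey_biweight,
    ueda_outliers,
)

profiles = st.lists(
    st.floats(min_value=-20, max_value=20, allow_nan=False), min_size=3, max_size=8
)


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain-python reimplementations)
# ---------------------------------------------------------------------------

def oracle_biweight(values, c=5.0, eps=1e-4):
    xs = sorted(values)
    n = len(xs)
    med = (xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2)
    devs = sorted(abs(v - med) for v in values)
    mad = devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2
    num = den = 0.0
    for v in values:
        u = (v - med) / (c * mad + eps)
        if abs(u) < 1:
            w = (1 - u * u) ** 2
            num += w * v
            den += w
    return num / den if den else med


def oracle_entropy(profile):
    center = oracle_biweight(profile)
    processed = [abs(v - center) for v in profile]
    total = sum(processed)
    if total == 0:
        return math.log2(len(profile))
    return -sum(
        (p / total) * math.log2(p / total) for p in processed if p > 0
    )


def oracle_ueda(profile, max_outliers=2):
    """Exhaustive AIC over all high-side-consistent subsets of size <= max."""
    n = len(profile)
    best, best_aic = [], math.inf
    for size in range(0, max_outliers + 1):
        for subset in itertools.combinations(range(n), size):
            inside = [profile[i] for i in subset]
            outside = [profile[i] for i in range(n) if i not in subset]
            if inside and outside and min(inside) < max(outside):
                continue  # not a high-side outlier set
            m = len(outside)
            if m == 0:
                continue
            mean = sum(outside) / m
            rss = sum((v - mean) ** 2 for v in outside)
            aic = m * math.log(max(rss, 1e-12) / m) + 2 * (size + 1)
            if aic < best_aic:
                best_aic = aic
                best = sorted(subset, key=lambda i: (-profile[i], i))
    return best


# ---------------------------------------------------------------------------
# Tukey biweight
# ---------------------------------------------------------------------------

class TestTukeyBiweight:
    def test_constant_vector(self):
        assert tukey_biweight([5, 5, 5]) == 5

    def test_symmetric_vector(self):
        assert tukey_biweight([1, 2, 3]) == pytest.approx(2)

    def test_outlier_fully_rejected(self):
        # MAD is 0, so the epsilon guard zeroes the outlier's weight entirely
        value = tukey_biweight([1, 1, 1, 10])
        assert 1.0 <= value < 3.25
        assert abs(value - 1.0) < abs(value - 3.25)
        assert value == pytest.approx(oracle_biweight([1, 1, 1, 10]))

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            tukey_biweight([])

    @settings(deadline=None, derandomize=True)
    @given(profiles)
    def test_matches_oracle(self, values):
        assert tukey_biweight(values) == pytest.approx(
            oracle_biweight(values), abs=1e-9
        )


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

class TestRokuEntropy:
    def test_flat_profile_maximal(self):
        assert roku_entropy([3.0] * 6) == pytest.approx(math.log2(6))

    def test_concentrated_profile_zero(self):
        # biweight centre is exactly 1; all mass on the single spike
        assert roku_entropy([10, 1, 1, 1, 1]) == pytest.approx(0.0)

    def test_symmetric_half_split_one_bit(self):
        # centre 2 by symmetry -> processed (2, 2, 0, 0) -> H = 1 bit
        assert roku_entropy([0, 4, 2, 2]) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(profiles)
    def test_matches_oracle_and_permutation_invariant(self, values):
        h = roku_entropy(values)
        assert h == pytest.approx(oracle_entropy(values), abs=1e-9)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(values)))
        assert roku_entropy([values[i] for i in perm]) == pytest.approx(h, abs=1e-9)

    def test_needs_three_tissues(self):
        with pytest.raises(ValidationError):
            roku_entropy([1.0, 2.0])


# ---------------------------------------------------------------------------
# SPM
# ---------------------------------------------------------------------------

class TestSpm:
    def test_one_hot_is_one(self):
        assert spm([0, 5, 0, 0], [1]) == pytest.approx(1.0)

    def test_uniform_is_one_over_n(self):
        assert spm([2, 2, 2, 2, 2], [3]) == pytest.approx(1 / 5)

    def test_hand_value(self):
        assert spm([3, 1, 1, 1], [0]) == pytest.approx(0.75)

    def test_pair_equals_squared_cosine(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.uniform(0, 10, size=6)
            indicator = np.zeros(6)
            indicator[[1, 4]] = 1.0
            cos = np.dot(x, indicator) / (
                np.linalg.norm(x) * np.linalg.norm(indicator)
            )
            assert spm(x, [1, 4]) == pytest.approx(cos**2)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=3, max_size=8)
    )
    def test_single_tissue_values_sum_to_one(self, values):
        total = sum(spm(values, [i]) for i in range(len(values)))
        assert total == pytest.approx(1.0)

    def test_all_zero_profile_errors(self):
        with pytest.raises(ValidationError):
            spm([0, 0, 0], [0])


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------

class TestUedaOutliers:
    def test_single_spike(self):
        assert ueda_outliers([10, 1, 1, 1, 1, 1], 2) == [0]

    def test_flat_profile_no_outliers(self):
        assert ueda_outliers([2, 2, 2, 2], 2) == []

    def test_two_spikes(self):
        assert ueda_outliers([10, 9, 1, 1, 1, 1], 2) == [0, 1]

    @settings(deadline=None, derandomize=True)
    @given(profiles, st.sampled_from([1, 2]))
    def test_matches_exhaustive_oracle(self, values, max_outliers):
        assert ueda_outliers(values, max_outliers) == oracle_ueda(
            values, max_outliers
        )


# ---------------------------------------------------------------------------
# composed classifiers
# ---------------------------------------------------------------------------

PERMISSIVE = RokuSpmParams(h_max=3.0, spm1=0.5, spm2=0.5)


class TestRokuSpmClassify:
    def test_single_specific(self):
        call = roku_spm_classify([12, 2, 2, 2, 2, 2], PERMISSIVE)
        assert call.category is Category.SPECIFIC
        assert call.tissues == ("t1",)

    def test_flat_is_ubiquitous(self):
        call = roku_spm_classify([4, 4, 4, 4, 4], PERMISSIVE)
        assert call.category is Category.UBIQUITOUS

    def test_two_selective(self):
        call = roku_spm_classify([10, 9.5, 1, 1, 1, 1], PERMISSIVE)
        assert call.category is Category.TWO_SELECTIVE
        assert set(call.tissues) == {"t1", "t2"}

    def test_pair_failing_spm2_degrades_to_specific(self):
        # two outliers, but a pair threshold of 1.0 is unattainable; the top
        # tissue still passes spm1 so the call degrades to specific
        params = RokuSpmParams(h_max=3.0, spm1=0.3, spm2=1.0)
        call = roku_spm_classify([10, 9.5, 1, 1, 1, 1], params)
        assert call.category is Category.SPECIFIC
        assert call.tissues == ("t1",)

    def test_entropy_gate_blocks(self):
        params = RokuSpmParams(h_max=0.01, spm1=0.3, spm2=0.3)
        call = roku_spm_classify([10, 9.5, 1, 1, 1, 1], params)
        assert call.category is Category.UBIQUITOUS

    def test_spm_monotonicity_in_thresholds(self):
        """Raising a strictness threshold never turns ubiquitous informative."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(8, 2, size=6)
            loose = RokuSpmParams(h_max=2.0, spm1=0.5, spm2=0.5)
            strict = RokuSpmParams(h_max=2.0, spm1=0.9, spm2=0.9)
            if roku_spm_classify(x, loose).category is Category.UBIQUITOUS:
                assert roku_spm_classify(x, strict).category is Category.UBIQUITOUS


class TestDecisionFunction:
    def test_specific_with_zero_spread_low_group(self):
        call = decision_function_classify(
            [10, 2, 2, 2, 2], DecisionParams(g_min=4, sp_min=0.5, d_min=2)
        )
        assert call.category is Category.SPECIFIC
        assert call.tissues == ("t1",)

    def test_flat_is_ubiquitous(self):
        call = decision_function_classify([3, 3, 3, 3], DecisionParams(1, 0.1, 1))
        assert call.category is Category.UBIQUITOUS

    def test_two_selective_when_k1_fails(self):
        call = decision_function_classify(
            [10, 9, 2, 2, 2, 2], DecisionParams(g_min=4, sp_min=0.5, d_min=2)
        )
        assert call.category is Category.TWO_SELECTIVE
        assert set(call.tissues) == {"t1", "t2"}

    def test_needs_four_tissues(self):
        with pytest.raises(ValidationError):
            decision_function_classify([1, 2, 3], DecisionParams())

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(8, 2, size=6)
            loose = DecisionParams(g_min=1.0, sp_min=0.2, d_min=1.0)
            strict = DecisionParams(g_min=3.0, sp_min=0.6, d_min=3.0)
            if decision_function_classify(x, loose).category is Category.UBIQUITOUS:
                assert (
                    decision_function_classify(x, strict).category
                    is Category.UBIQUITOUS
                )

    def test_noise_free_one_hot_specific_for_all_detectors(self):
        profile = [14.0, 6.0, 6.0, 6.0, 6.0, 6.0]
        roku = roku_spm_classify(profile, RokuSpmParams(h_max=2.0, spm1=0.5, spm2=0.5))
        dec = decision_function_classify(profile, DecisionParams(2.0, 0.3, 3.0))
        assert roku.category is dec.category is Category.SPECIFIC
        assert roku.tissues == dec.tissues == ("t1",)
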