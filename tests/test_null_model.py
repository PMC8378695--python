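"""Memoryless-source null model: closed form, oracle, simulation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from menzerath import (
    LengthProfile,
    NullCurve,
    SourceParams,
    WordComposition,
    empirical_conditional_means,
    exact_conditional_mean_oracle,
    expected_consonants,
    expected_mean_syllable_length,
    make_null_curve,
    segment_words,
    simulate_symbols,
)


class TestNullCurve:
    @pytest.mark.parametrize(
        "p_c, a, b",
        [(0.0, 0.0, 1.0), (0.5, 1.0, 2.0), (0.48, 0.48 / 0.52, 1 + 0.48 / 0.52)],
    )
    def test_closed_form(self, p_c, a, b):
        curve = make_null_curve(p_c)
        assert curve.a == pytest.approx(a, abs=1e-12)
        assert curve.b == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("p_c", [0.0, 0.1, 0.48, 0.9, 0.999])
    def test_b_equals_a_plus_one(self, p_c):
        curve = make_null_curve(p_c)
        assert curve.b == 1.0 + curve.a

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            make_null_curve(bad)

    def test_curve_strictly_decreasing_with_limit(self):
        curve = make_null_curve(0.48)
        ms = np.arange(1, 100)
        y = expected_mean_syllable_length(curve, ms)
        assert np.all(np.diff(y) < 0)
        assert y[-1] > curve.b
        assert float(expected_mean_syllable_length(curve, 10**9)) == pytest.approx(
            curve.b, abs=1e-6
        )

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            expected_mean_syllable_length(make_null_curve(0.3), 0)


class TestExpectedConsonants:
    def test_zero_consonant_probability(self):
        assert expected_consonants(0.0, 7) == 0.0

    @pytest.mark.parametrize(
        "p_c, m, expected",
        [(0.5, 1, 2.0), (0.48, 4, 5 * 0.48 / 0.52)],
    )
    def test_values(self, p_c, m, expected):
        assert expected_consonants(p_c, m) == pytest.approx(expected, rel=1e-12)

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            expected_consonants(0.3, -1)


class TestOracle:
    def test_vowel_only_source(self):
        assert exact_conditional_mean_oracle(
            SourceParams(0.0, 0.8), m=2
        ) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "p_c, p_v", [(0.3, 0.5), (0.48, 0.37), (0.1, 0.1), (0.6, 0.2)]
    )
    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
    def test_matches_closed_form(self, p_c, p_v, m):
        oracle = exact_conditional_mean_oracle(
            SourceParams(p_c, p_v), m, max_word_length=150
        )
        closed = float(
            expected_mean_syllable_length(make_null_curve(p_c), m)
        )
        assert oracle == pytest.approx(closed, abs=1e-6)

    def test_literal_enumeration_agrees(self):
        # brute force over explicit C/V strings on a tiny truncation
        p_c, p_v, m = 0.3, 0.5, 1
        p_s = 1 - p_c - p_v
        num = den = 0.0
        for length in range(1, 26):
            for word in itertools.product("CV", repeat=length):
                if word.count("V") != m:
                    continue
                w = p_c ** word.count("C") * p_v**m * p_s
                den += w
                num += w * length / m
        brute = num / den
        oracle = exact_conditional_mean_oracle(
            SourceParams(p_c, p_v), m, max_word_length=25
        )
        assert oracle == pytest.approx(brute, rel=1e-12)

    def test_truncation_mass_check(self):
        with pytest.raises(ValueError, match="max_word_length"):
            exact_conditional_mean_oracle(
                SourceParams(0.7, 0.2), m=5, max_word_length=10
            )


class TestSimulation:
    def test_deterministic_given_seed(self):
        p = SourceParams(0.48, 0.37)
        a = simulate_symbols(p, 10_000, seed=42)
        b = simulate_symbols(p, 10_000, seed=42)
        assert np.array_equal(a, b)

    def test_degenerate_limit_mostly_consonants(self):
        p = SourceParams(0.999, 0.0005)
        sym = simulate_symbols(p, 2000, seed=0)
        assert (sym == "C").mean() > 0.99

    def test_empirical_frequencies(self):
        p = SourceParams(0.48, 0.37)
        n = 1_000_000
        sym = simulate_symbols(p, n, seed=123)
        for symbol, prob in (("C", 0.48), ("V", 0.37), ("S", 0.15)):
            freq = (sym == symbol).mean()
            tol = 3 * np.sqrt(prob * (1 - prob) / n)
            assert abs(freq - prob) < tol

    def test_cluster_lengths_geometric(self):
        """Leading consonant runs follow P(N0=n) = p_c^n (1-p_c).

        Runs are taken after every delimiter, including zero-length
        segments: conditioning on non-empty words would deplete the
        N0 = 0 mass and break the geometric law.
        """
        p_c = 0.4
        p = SourceParams(p_c, 0.4)
        rejections = 0
        runs = 20
        for seed in range(runs):
            sym = simulate_symbols(p, 500_000, seed=seed)
            segments = "".join(sym).split("S")
            n0 = np.array(
                [len(seg) - len(seg.lstrip("C")) for seg in segments]
            )[:100_000]
            kmax = 8
            obs = np.bincount(np.minimum(n0, kmax), minlength=kmax + 1)
            probs = np.array(
                [p_c**k * (1 - p_c) for k in range(kmax)] + [p_c**kmax]
            )
            res = stats.chisquare(obs, probs * len(n0))
            if res.pvalue < 0.01:
                rejections += 1
        assert rejections / runs <= 0.05


class TestSegmentation:
    def test_hand_segmentation(self):
        words = segment_words("CVSCVVS")
        assert [(w.n, w.m) for w in words] == [(1, 1), (1, 2)]

    def test_consecutive_delimiters_drop_empty(self):
        assert segment_words("SS") == []

    def test_cluster_counts(self):
        (w,) = segment_words("CCVCVS")
        assert (w.n, w.m) == (3, 2)
        assert w.cluster_counts == (2, 1, 0)

    def test_unknown_symbol_named(self):
        with pytest.raises(ValueError, match="'X'"):
            segment_words("CVXS")

    def test_composition_invariants_enforced(self):
        with pytest.raises(ValueError):
            WordComposition(n=2, m=1, cluster_counts=(1, 0))  # sums to 1 != 2
        with pytest.raises(ValueError):
            WordComposition(n=1, m=2, cluster_counts=(1, 0))  # needs m+1 runs


class TestEmpiricalMeans:
    def test_single_word(self):
        (w,) = segment_words("CCVS")
        profile = empirical_conditional_means([w], min_count=1)
        assert profile[1] == (3.0, 1)

    def test_threshold_empties_profile(self):
        words = segment_words("CVS CVS".replace(" ", "S"))
        assert len(empirical_conditional_means(words, min_count=99)) == 0

    def test_vowel_free_words_excluded(self):
        words = segment_words("CCSCVS")
        profile = empirical_conditional_means(words, min_count=1)
        assert list(profile.bins) == [1]

    def test_agrees_with_closed_form_within_3se(self):
        p_c = 0.48
        p = SourceParams(p_c, 0.37)
        sym = simulate_symbols(p, 1_000_000, seed=9)
        profile = empirical_conditional_means(segment_words(sym), min_count=10)
        curve = make_null_curve(p_c)
        outside = 0
        for m, (mean_y, count) in profile.bins.items():
            theory = curve.a / m + curve.b
            se = np.sqrt((m + 1) * p_c / (1 - p_c) ** 2 / count) / m
            if abs(mean_y - theory) > 3 * se:
                outside += 1
        assert outside <= max(1, int(0.05 * len(profile)))
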