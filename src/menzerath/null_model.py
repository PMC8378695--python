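"""Memoryless-source ("monkey typing") null model.

A one-state source emits i.i.d. symbols C (consonant), V (vowel) and S
(word delimiter) with probabilities ``p_c``, ``p_v`` and
``p_s = 1 - p_c - p_v``.  Treating maximal S-free segments as words and
vowels as syllable nuclei, the conditional mean syllable length obeys the
exact hyperbola

    E((N + M)/M | M = m) = a/m + b,
    a = p_c / (1 - p_c),   b = 1 + a,

where N and M count consonants and vowels in a word.  The curve is
strictly decreasing in ``m`` for any ``p_c > 0``, so this trivial source
satisfies Menzerath's law (negative rank correlation between word length
and mean syllable length) while having no inverted regime.

Besides the closed form, this module provides a seeded simulator of the
source and an exact enumeration oracle that verifies the closed form
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .profiles import LengthProfile

__all__ = [
    "SourceParams",
    "NullCurve",
    "WordComposition",
    "make_null_curve",
    "expected_consonants",
    "expected_mean_syllable_length",
    "exact_conditional_mean_oracle",
    "simulate_symbols",
    "segment_words",
    "empirical_conditional_means",
]

SYMBOLS = ("C", "V", "S")


@dataclass(frozen=True)
class SourceParams:
    """Emission probabilities of the three-symbol memoryless source."""

    p_c: float
    p_v: float

    def __post_init__(self):
        if self.p_c < 0 or self.p_v < 0:
            raise ValueError("emission probabilities must be non-negative")
        if self.p_c + self.p_v >= 1:
            raise ValueError(
                "p_c + p_v must be < 1 so the delimiter probability "
                "p_s = 1 - p_c - p_v is positive"
            )

    @property
    def p_s(self) -> float:
        return 1.0 - self.p_c - self.p_v


@dataclass(frozen=True)
class NullCurve:
    """Parameters of the exact null curve ``y(m) = a/m + b``.

    ``b - a = 1`` holds identically: both parameters derive from the
    single consonant probability ``p_c``.
    """

    a: float
    b: float

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("a must be non-negative")

    def __call__(self, m):
        return expected_mean_syllable_length(self, m)


@dataclass(frozen=True)
class WordComposition:
    """Consonant/vowel composition of one inter-delimiter segment.

    ``cluster_counts`` has ``m + 1`` entries: the run of consonants
    before the first vowel (index 0) and after each of the ``m`` vowels.
    """

    n: int
    m: int
    cluster_counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.cluster_counts) != self.m + 1:
            raise ValueError("cluster_counts must have m + 1 entries")
        if sum(self.cluster_counts) != self.n:
            raise ValueError("cluster_counts must sum to n")

    @property
    def mean_syllable_length(self) -> float:
        if self.m == 0:
            raise ValueError("mean syllable length undefined for m = 0")
        return (self.n + self.m) / self.m


def make_null_curve(p_c: float) -> NullCurve:
    """Closed-form null curve for consonant probability ``p_c``."""
    if not 0 <= p_c < 1:
        raise ValueError("p_c must lie in [0, 1)")
    a = p_c / (1.0 - p_c)
    return NullCurve(a=a, b=1.0 + a)


def expected_consonants(p_c: float, m: int) -> float:
    """Expected consonant count in a word with ``m`` vowels.

    Each of the ``m + 1`` consonant clusters is geometric with mean
    ``p_c/(1 - p_c)``, independent of ``m``.
    """
    if not 0 <= p_c < 1:
        raise ValueError("p_c must lie in [0, 1)")
    if m < 0 or int(m) != m:
        raise ValueError("m must be a non-negative integer")
    return (m + 1) * p_c / (1.0 - p_c)


def expected_mean_syllable_length(curve: NullCurve, m) -> float:
    """Evaluate the null curve ``a/m + b`` at syllable count ``m >= 1``."""
    m_arr = np.asarray(m)
    if np.any(m_arr < 1):
        raise ValueError("mean syllable length undefined for m < 1")
    return curve.a / m_arr + curve.b


def exact_conditional_mean_oracle(
    p: SourceParams,
    m: int,
    max_word_length: int = 60,
) -> float:
    """Exact conditional mean syllable length by truncated enumeration.

    Sums over all C/V words up to ``max_word_length`` graphemes: a word
    with ``n`` consonants and ``m`` vowels has probability
    ``binom(n + m, n) * p_c^n * p_v^m * p_s`` under the source.
    Conditioning on exactly ``m`` vowels and averaging ``(n + m)/m``
    gives the expectation independently of the closed form, which it
    must match within the truncation tolerance.

    Raises if the truncated mass conditioned on ``M = m`` is below
    ``1 - 1e-8`` (negative-binomial tail check).
    """
    if m < 1:
        raise ValueError("oracle requires m >= 1")
    max_n = max_word_length - m
    if max_n < 0:
        raise ValueError("max_word_length smaller than m")
    # conditioned on M = m, N ~ NegBinomial(m + 1 successes, p = 1 - p_c)
    mass = stats.nbinom.cdf(max_n, m + 1, 1.0 - p.p_c)
    if mass < 1.0 - 1e-8:
        raise ValueError(
            f"truncated conditional mass {mass:.12f} < 1 - 1e-8; "
            f"increase max_word_length (got {max_word_length})"
        )
    ns = np.arange(max_n + 1)
    # number of distinct C/V orderings times per-word probability
    if p.p_c == 0:
        w = np.where(ns == 0, p.p_v**m * p.p_s, 0.0)
    else:
        log_w = (
            ns * np.log(p.p_c)
            + m * np.log(p.p_v)
            + np.log(p.p_s)
            + _log_binom(ns + m, ns)
        )
        w = np.exp(log_w)
    total = w.sum()
    mean = ((ns + m) / m * w).sum() / total
    return float(mean)


def _log_binom(n, k):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def simulate_symbols(p: SourceParams, length: int, seed: int) -> np.ndarray:
    """Draw ``length`` i.i.d. symbols from the source (seeded).

    Returns an array of single-character strings over {'C', 'V', 'S'}.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(3, size=length, p=[p.p_c, p.p_v, p.p_s])
    return np.array(SYMBOLS, dtype="<U1")[idx]


def segment_words(stream) -> list[WordComposition]:
    """Split a C/V/S stream into words (maximal S-free segments).

    Empty segments between consecutive delimiters are dropped.  Raises
    on any symbol outside {C, V, S}.
    """
    words: list[WordComposition] = []
    clusters = [0]  # consonant run before next vowel
    m = 0
    n = 0
    nonempty = False
    for sym in stream:
        if sym == "S":
            if nonempty:
                words.append(WordComposition(n, m, tuple(clusters)))
            clusters = [0]
            m = 0
            n = 0
            nonempty = False
        elif sym == "C":
            clusters[-1] += 1
            n += 1
            nonempty = True
        elif sym == "V":
            clusters.append(0)
            m += 1
            nonempty = True
        else:
            raise ValueError(f"unknown symbol {sym!r}: expected C, V or S")
    if nonempty:
        words.append(WordComposition(n, m, tuple(clusters)))
    return words


def empirical_conditional_means(
    words, min_count: int = 10
) -> LengthProfile:
    """Bin words by vowel count and average ``(n + m)/m`` per bin.

    Words with no vowel are excluded (the statistic is undefined there);
    bins supported by fewer than ``min_count`` words are dropped.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for w in words:
        if w.m == 0:
            continue
        sums[w.m] = sums.get(w.m, 0.0) + (w.n + w.m) / w.m
        counts[w.m] = counts.get(w.m, 0) + 1
    return LengthProfile(
        {
            m: (sums[m] / counts[m], counts[m])
            for m in sorted(counts)
            if counts[m] >= min_count
        }
    )
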