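"""Corpus pipeline: tokenization, filtering, measurement, aggregation.

Turns raw UTF-8 documents into per-word (syllable count, grapheme count)
measurements, aggregates them into length profiles by two methods —
pooling the whole corpus as one text, or averaging per-document profiles
— and tests Menzerath's law via Spearman rank correlation between word
length and mean syllable length.

Filtering conventions: text is lowercased and NFC-normalized; tokens are
maximal runs of non-delimiter characters (whitespace, digits and a
configurable punctuation set delimit); a token is kept only if every
grapheme belongs to the sonority table; word-length bins supported by
fewer than ``min_count`` tokens (default 25) are discarded; monosyllables
are excluded by default from profiles and correlations.
"""

from __future__ import annotations

import math
import unicodedata
from dataclasses import dataclass, asdict
from itertools import islice, permutations

import numpy as np
from scipy import stats

from .profiles import LengthProfile
from .ssp import SonorityTable, default_sonority_table, syllabify

__all__ = [
    "DEFAULT_DELIMITERS",
    "WordMeasurement",
    "CorpusSummary",
    "CorrelationResult",
    "tokenize",
    "filter_tokens",
    "measure_words",
    "profile_full_corpus",
    "profile_by_document",
    "corpus_summary",
    "spearman_menzerath",
]

# Punctuation treated as word delimiters, in addition to all whitespace
# and digits.  Apostrophes and hyphens delimit: intra-word punctuation
# splits the token.
DEFAULT_DELIMITERS = ".,;:!?\"()[]{}<>«»—–-'’‘“”*_/\\|&%$#@+=~`^…0123456789"


@dataclass(frozen=True)
class WordMeasurement:
    """One word token: syllable count, grapheme count, their ratio."""

    m: int
    g: int
    doc_id: str | None = None

    @property
    def y(self) -> float:
        """Mean syllable length in graphemes, ``g / m``."""
        return self.g / self.m


@dataclass(frozen=True)
class CorpusSummary:
    """Corpus-level symbol statistics.

    Each inter-token gap counts as exactly one delimiter symbol S, so
    the symbol total is C + V + tokens.  ``syll_v_ratio`` is total
    syllables over total vowels; it drops below 1 when vowel runs
    (diphthongs) share a nucleus.
    """

    documents: int
    tokens: int
    syllables: int
    consonants: int
    vowels: int
    excluded_tokens: int

    @property
    def p_c(self) -> float | None:
        t = self.consonants + self.vowels + self.tokens
        return self.consonants / t if t else None

    @property
    def p_v(self) -> float | None:
        t = self.consonants + self.vowels + self.tokens
        return self.vowels / t if t else None

    @property
    def p_s(self) -> float | None:
        t = self.consonants + self.vowels + self.tokens
        return self.tokens / t if t else None

    @property
    def syll_v_ratio(self) -> float | None:
        return self.syllables / self.vowels if self.vowels else None

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            p_c=self.p_c,
            p_v=self.p_v,
            p_s=self.p_s,
            syll_v_ratio=self.syll_v_ratio,
        )
        return d


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between m and mean syllable length."""

    rho: float
    p_value: float
    n_bins: int
    method: str  # "exact" or "asymptotic"

    def to_dict(self) -> dict:
        return asdict(self)


def tokenize(text: str, delimiters: str = DEFAULT_DELIMITERS) -> list[str]:
    """Lowercase, NFC-normalize and split a document into word tokens.

    Tokens are maximal runs of characters that are neither whitespace
    nor in ``delimiters``.
    """
    text = unicodedata.normalize("NFC", text.lower())
    delim = set(delimiters)
    tokens = []
    current: list[str] = []
    for ch in text:
        if ch.isspace() or ch in delim:
            if current:
                tokens.append("".join(current))
                current = []
        else:
            current.append(ch)
    if current:
        tokens.append("".join(current))
    return tokens


def filter_tokens(
    tokens, table: SonorityTable | None = None
) -> tuple[list[str], int]:
    """Keep tokens whose every grapheme is in the sonority table.

    Returns the surviving tokens and the count of excluded ones, for
    run-log reporting.
    """
    if table is None:
        table = default_sonority_table()
    kept = []
    excluded = 0
    for tok in tokens:
        if all(g in table for g in tok):
            kept.append(tok)
        else:
            excluded += 1
    return kept, excluded


def measure_words(
    tokens,
    table: SonorityTable | None = None,
    exclude_vowel_free: bool = True,
    doc_id: str | None = None,
) -> list[WordMeasurement]:
    """Syllabify each token and record (m, g) per word.

    Vowel-free tokens (no rank-7 grapheme) are dropped by default.
    """
    if table is None:
        table = default_sonority_table()
    out = []
    for tok in tokens:
        sw = syllabify(tok, table)
        if sw.vowel_free and exclude_vowel_free:
            continue
        out.append(WordMeasurement(m=sw.n_syllables, g=len(sw.word), doc_id=doc_id))
    return out


def _pooled_counts(measurements) -> dict[int, int]:
    counts: dict[int, int] = {}
    for w in measurements:
        counts[w.m] = counts.get(w.m, 0) + 1
    return counts


def profile_full_corpus(
    measurements,
    min_count: int = 25,
    include_monosyllables: bool = False,
) -> LengthProfile:
    """Length profile treating the whole corpus as a single text.

    Pools every word token; the mean syllable length per ``m`` is the
    token-weighted average of ``g/m``.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for w in measurements:
        if w.m == 1 and not include_monosyllables:
            continue
        sums[w.m] = sums.get(w.m, 0.0) + w.y
        counts[w.m] = counts.get(w.m, 0) + 1
    return LengthProfile(
        {
            m: (sums[m] / counts[m], counts[m])
            for m in sorted(counts)
            if counts[m] >= min_count
        }
    )


def profile_by_document(
    per_document_measurements,
    min_count: int = 25,
    include_monosyllables: bool = False,
) -> LengthProfile:
    """Length profile averaging per-document means (average of averages).

    For each ``m``, every document contributing at least one token to
    the bin enters with equal weight, regardless of its token count.
    The ``min_count`` filter applies to the *pooled* token count per
    bin, as in the pooled method; the reported count is the pooled one.
    """
    per_doc: list[dict[int, tuple[float, int]]] = []
    for doc in per_document_measurements:
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for w in doc:
            if w.m == 1 and not include_monosyllables:
                continue
            sums[w.m] = sums.get(w.m, 0.0) + w.y
            counts[w.m] = counts.get(w.m, 0) + 1
        per_doc.append({m: (sums[m] / counts[m], counts[m]) for m in counts})

    pooled: dict[int, int] = {}
    for doc in per_doc:
        for m, (_, c) in doc.items():
            pooled[m] = pooled.get(m, 0) + c

    bins = {}
    for m in sorted(pooled):
        if pooled[m] < min_count:
            continue
        doc_means = [doc[m][0] for doc in per_doc if m in doc]
        bins[m] = (float(np.mean(doc_means)), pooled[m])
    return LengthProfile(bins)


def corpus_summary(
    documents,
    table: SonorityTable | None = None,
) -> CorpusSummary:
    """Symbol-level statistics over a corpus of document strings.

    Counts consonant and vowel graphemes over kept tokens only and
    approximates the delimiter count by the token count (one S per
    inter-token gap).
    """
    if table is None:
        table = default_sonority_table()
    docs = list(documents)
    tokens = syllables = consonants = vowels = excluded_total = 0
    for text in docs:
        kept, excluded = filter_tokens(tokenize(text), table)
        excluded_total += excluded
        tokens += len(kept)
        for tok in kept:
            sw = syllabify(tok, table)
            syllables += sw.n_syllables
            for g in tok:
                if table.rank(g) == 7:
                    vowels += 1
                else:
                    consonants += 1
    return CorpusSummary(
        documents=len(docs),
        tokens=tokens,
        syllables=syllables,
        consonants=consonants,
        vowels=vowels,
        excluded_tokens=excluded_total,
    )


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of midrank vectors; 0 when either is constant."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def _exact_permutation_pvalue(
    rx: np.ndarray, ry: np.ndarray, rho_obs: float, chunk: int = 200_000
) -> float:
    """Two-sided exact p-value: P(|rho_perm| >= |rho_obs|) over all n!.

    With ranks fixed, each permutation's rho is an affine function of
    the dot product rx . ry_perm, so permutations are scored in
    vectorized chunks.
    """
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return 1.0
    target = abs(rho_obs) * denom - 1e-9 * denom
    hits = total = 0
    it = permutations(ryc)
    while True:
        block = list(islice(it, chunk))
        if not block:
            break
        arr = np.asarray(block)
        dots = arr @ rxc
        hits += int(np.count_nonzero(np.abs(dots) >= target))
        total += len(block)
    return hits / total


def spearman_menzerath(
    profile: LengthProfile, exact_max_bins: int = 10
) -> CorrelationResult:
    """Spearman rank correlation between m and mean syllable length.

    With at most ``exact_max_bins`` bins the two-sided p-value is exact,
    by full enumeration of rank permutations (appropriate for the small
    profiles this statistic is computed on); larger profiles use the
    asymptotic t approximation.  Ties are handled with midranks; a
    constant profile yields rho = 0.
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 bins for a rank correlation")
    x = np.asarray(profile.ms, dtype=float)
    y = np.asarray(profile.mean_y, dtype=float)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = len(x)
    if n <= exact_max_bins:
        return CorrelationResult(
            rho, _exact_permutation_pvalue(rx, ry, rho), n, "exact"
        )
    res = stats.spearmanr(x, y)
    pv = float(res.pvalue)
    if math.isnan(pv):
        pv = 1.0
    return CorrelationResult(rho, pv, n, "asymptotic")
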