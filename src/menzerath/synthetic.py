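"""Seeded synthetic-corpus generators.

Every stage of the analysis can be exercised without external data:

* :func:`render_memoryless_text` — renders the three-symbol memoryless
  source as real graphemes (uniform within sonority class), so the full
  text pipeline can be checked against the closed-form null curve;
* :func:`generate_ssp_words` — sonority-well-formed words with known
  syllable boundaries, the round-trip oracle for the syllabifier;
* :func:`generate_mal_profile` — length profiles lying on a known MAL
  curve plus multiplicative noise, the fit-recovery harness;
* :func:`generate_position_structured_corpus` — corpora whose syllable
  lengths follow a prescribed position profile (by default the
  empirically observed shape: a bump at the second syllable and a dip
  at the penultimate one).

All generators are pure functions of their parameters and seed.

Construction guarantee: generated syllables have a strictly
rising-sonority onset, a single-vowel nucleus and a strictly
falling-sonority coda; every word-internal syllable's onset starts with
a rank-1 (occlusive) grapheme while the preceding coda uses ranks >= 2
only, so each inter-nucleus cluster has a unique sonority minimum at the
true boundary and the split-before-last-minimum rule recovers the
generating boundaries exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mal import MALParams, mal_curve
from .null_model import SourceParams, simulate_symbols
from .profiles import LengthProfile
from .ssp import SonorityTable, default_sonority_table

__all__ = [
    "PositionStructure",
    "default_position_structure",
    "render_memoryless_text",
    "generate_ssp_words",
    "generate_mal_profile",
    "generate_position_structured_corpus",
]


def render_memoryless_text(
    p: SourceParams,
    n_symbols: int,
    seed: int,
    table: SonorityTable | None = None,
) -> tuple[str, np.ndarray]:
    """Render a memoryless C/V/S stream as a grapheme document.

    Each C maps to a uniformly random consonant grapheme, each V to a
    uniformly random vowel grapheme, each S to a space.  Returns the
    document together with the underlying symbol stream, so class-level
    statistics of the two can be compared exactly.
    """
    if table is None:
        table = default_sonority_table()
    consonants = np.array(table.consonants())
    vowels = np.array(table.vowels())
    if len(consonants) == 0 or len(vowels) == 0:
        raise ValueError("table must contain both consonants and vowels")
    symbols = simulate_symbols(p, n_symbols, seed)
    rng = np.random.default_rng(seed + 1)
    out = np.empty(n_symbols, dtype=object)
    c_mask = symbols == "C"
    v_mask = symbols == "V"
    out[c_mask] = rng.choice(consonants, size=int(c_mask.sum()))
    out[v_mask] = rng.choice(vowels, size=int(v_mask.sum()))
    out[symbols == "S"] = " "
    return "".join(out), symbols


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _build_syllable(
    rng: np.random.Generator,
    table: SonorityTable,
    length: int,
    internal_onset: bool,
    restrict_coda: bool,
    by_rank: dict[int, list[str]],
) -> str:
    """One syllable of exactly ``length`` graphemes.

    ``internal_onset``: onset non-empty and starting at rank 1 (needed
    for boundary recovery at the preceding junction).  ``restrict_coda``:
    coda ranks drawn from 2..6 only (needed when a syllable follows).
    """
    onset_ranks_pool = list(range(2, 7)) if internal_onset else list(range(1, 7))
    coda_pool = list(range(2, 7)) if restrict_coda else list(range(1, 7))
    onset_cap = (1 + len(onset_ranks_pool)) if internal_onset else 6
    onset_min = 1 if internal_onset else 0
    coda_cap = len(coda_pool)

    k = length - 1  # consonants to distribute
    lo = max(onset_min, k - coda_cap)
    hi = min(onset_cap, k)
    if lo > hi:
        raise ValueError(
            f"cannot build a {length}-grapheme syllable under the "
            "onset/coda constraints"
        )
    onset_len = int(rng.integers(lo, hi + 1))
    coda_len = k - onset_len

    if internal_onset:
        extra = sorted(
            rng.choice(onset_ranks_pool, size=onset_len - 1, replace=False)
        )
        onset_ranks = [1] + [int(r) for r in extra]
    else:
        onset_ranks = sorted(
            int(r)
            for r in rng.choice(range(1, 7), size=onset_len, replace=False)
        )
    coda_ranks = sorted(
        (int(r) for r in rng.choice(coda_pool, size=coda_len, replace=False)),
        reverse=True,
    )
    onset = "".join(_pick(rng, by_rank[r]) for r in onset_ranks)
    nucleus = _pick(rng, by_rank[7])
    coda = "".join(_pick(rng, by_rank[r]) for r in coda_ranks)
    return onset + nucleus + coda


def _ranks_index(table: SonorityTable) -> dict[int, list[str]]:
    by_rank = {r: table.graphemes_of_rank(r) for r in range(1, 8)}
    missing = [r for r, gs in by_rank.items() if not gs]
    if missing:
        raise ValueError(f"table lacks graphemes for sonority ranks {missing}")
    return by_rank


def generate_ssp_words(
    n_words: int,
    seed: int,
    max_syllables: int = 4,
    table: SonorityTable | None = None,
) -> list[tuple[str, tuple[int, ...]]]:
    """Random SSP-well-formed words with ground-truth boundaries.

    Returns ``(word, boundaries)`` pairs where boundaries are 0-based
    offsets between graphemes, directly comparable to
    :class:`~menzerath.ssp.SyllabifiedWord.boundaries`.
    """
    if table is None:
        table = default_sonority_table()
    by_rank = _ranks_index(table)
    rng = np.random.default_rng(seed)
    words = []
    for _ in range(n_words):
        m = int(rng.integers(1, max_syllables + 1))
        syllables = []
        for i in range(1, m + 1):
            internal = i > 1
            restrict = i < m
            base = 2 if internal else 1
            length = base + int(rng.integers(0, 4))
            syllables.append(
                _build_syllable(rng, table, length, internal, restrict, by_rank)
            )
        boundaries = tuple(np.cumsum([len(s) for s in syllables[:-1]]).tolist())
        words.append(("".join(syllables), boundaries))
    return words


def generate_mal_profile(
    params: MALParams,
    m_range,
    counts_per_m: int = 1000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LengthProfile:
    """Length profile on a known MAL curve plus multiplicative noise.

    ``mean_y(m) = curve(m) * (1 + eps_m)`` with ``eps_m`` Gaussian of
    standard deviation ``noise_sd``, floored at a small positive value.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ms = list(m_range)
    rng = np.random.default_rng(seed)
    ys = mal_curve(params, ms)
    if noise_sd > 0:
        ys = ys * (1.0 + rng.normal(0.0, noise_sd, size=len(ms)))
    ys = np.maximum(ys, 1e-3)
    return LengthProfile.from_pairs(ms, ys, [counts_per_m] * len(ms))


@dataclass(frozen=True)
class PositionStructure:
    """Specification of a position-dependent syllable-length corpus.

    ``length_dist`` is the word-length distribution over m (must sum to
    1); ``mean_length(i, m)`` gives the target mean grapheme count of
    the i-th syllable in an m-syllable word.  Per-syllable noise is a
    shifted Poisson count: ``L = base + Poisson(mean - base)`` with
    ``base = 1`` for the first syllable and ``2`` for later ones (which
    need an onset), so lengths are valid grapheme counts and
    ``E[L] = mean_length(i, m)`` exactly.
    """

    length_dist: dict[int, float]
    mean_length: Callable[[int, int], float]

    def __post_init__(self):
        total = sum(self.length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("word-length distribution must sum to 1")
        for m in self.length_dist:
            for i in range(1, m + 1):
                base = 1 if i == 1 else 2
                if self.mean_length(i, m) < base:
                    raise ValueError(
                        f"mean_length({i}, {m}) below feasible minimum {base}"
                    )


def _default_g(i: int, m: int) -> float:
    # qualitative shape of real text: long second syllable, short
    # penultimate, longer final
    if m == 1:
        return 3.0
    if i == m:
        return 3.0
    if i == 2:
        return 3.5
    if i == m - 1 and i >= 2:
        return 2.0
    return 2.5


def default_position_structure() -> PositionStructure:
    """Bump-at-second / dip-at-penultimate demo structure."""
    return PositionStructure(
        length_dist={1: 0.35, 2: 0.25, 3: 0.17, 4: 0.12, 5: 0.07, 6: 0.04},
        mean_length=_default_g,
    )


def generate_position_structured_corpus(
    structure: PositionStructure,
    n_words: int,
    seed: int,
    table: SonorityTable | None = None,
    n_documents: int = 1,
) -> list[str]:
    """Documents whose syllable lengths follow ``structure``.

    Words are assembled from SSP-well-formed syllables whose grapheme
    counts are shifted-Poisson draws with mean ``mean_length(i, m)``;
    draws beyond the feasible syllable length (onset/coda rank caps)
    are clipped, a negligible-probability event for realistic means.
    The output is plain text consumable by the full pipeline.
    """
    if table is None:
        table = default_sonority_table()
    by_rank = _ranks_index(table)
    rng = np.random.default_rng(seed)
    ms = list(structure.length_dist)
    probs = [structure.length_dist[m] for m in ms]
    words = []
    for _ in range(n_words):
        m = int(rng.choice(ms, p=probs))
        syllables = []
        for i in range(1, m + 1):
            internal = i > 1
            restrict = i < m
            base = 2 if internal else 1
            lam = structure.mean_length(i, m) - base
            length = base + int(rng.poisson(lam))
            # feasible caps: onset<=6 plus coda<=5 (restricted) or 6
            cap = 1 + 6 + (5 if restrict else 6)
            length = min(length, cap)
            syllables.append(
                _build_syllable(rng, table, length, internal, restrict, by_rank)
            )
        words.append("".join(syllables))
    docs = []
    per_doc = int(np.ceil(len(words) / n_documents))
    for d in range(n_documents):
        chunk = words[d * per_doc : (d + 1) * per_doc]
        if chunk:
            docs.append(" ".join(chunk))
    return docs
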