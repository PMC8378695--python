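"""Syllable length by position within the word.

The memoryless null model predicts that every consonant cluster in a
word is equally long on average, i.e. a flat positional profile.  Real
text instead shows a characteristic shape — a maximum around the second
syllable and a minimum around the penultimate one.  This module
estimates the mean syllable length per (word length m, syllable
position i) cell, with the position standardized to

    x = (i - 1)/(m - 1)   for m > 1,     x = 0.5   for m = 1,

so profiles of different word lengths share the [0, 1] axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["PositionProfile", "standardized_position", "positional_means"]


def standardized_position(i: int, m: int) -> float:
    """Standardized syllable position x in [0, 1] (0.5 for monosyllables)."""
    if not 1 <= i <= m:
        raise ValueError(f"position i={i} out of range 1..{m}")
    if m == 1:
        return 0.5
    return (i - 1) / (m - 1)


@dataclass(frozen=True)
class PositionProfile:
    """Mean syllable length per (word length m, 1-based position i).

    For each retained m, every word contributes one syllable at every
    position, so the count is constant across i within an m group.
    """

    entries: dict[tuple[int, int], tuple[float, int]]

    def mean_length(self, m: int, i: int) -> float:
        return self.entries[(m, i)][0]

    def count(self, m: int, i: int) -> int:
        return self.entries[(m, i)][1]

    def word_lengths(self) -> list[int]:
        return sorted({m for m, _ in self.entries})

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "m": m,
                "i": i,
                "x": standardized_position(i, m),
                "mean_length": mean,
                "count": count,
            }
            for (m, i), (mean, count) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["m", "i", "x", "mean_length", "count"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def positional_means(
    syllabified_words, min_words_per_m: int = 25
) -> PositionProfile:
    """Average syllable length per (m, i) cell over syllabified words.

    Word-length groups supported by fewer than ``min_words_per_m``
    words are dropped.
    """
    sums: dict[tuple[int, int], float] = {}
    group_counts: dict[int, int] = {}
    for sw in syllabified_words:
        m = sw.n_syllables
        group_counts[m] = group_counts.get(m, 0) + 1
        for i, length in enumerate(sw.syllable_lengths, start=1):
            sums[(m, i)] = sums.get((m, i), 0.0) + length
    entries = {
        (m, i): (total / group_counts[m], group_counts[m])
        for (m, i), total in sums.items()
        if group_counts[m] >= min_words_per_m
    }
    return PositionProfile(entries)
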