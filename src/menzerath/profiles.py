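"""Shared container for per-length mean-constituent-size profiles.

A :class:`LengthProfile` maps construct size ``m`` (syllables per word)
to the mean constituent size ``mean_y`` (graphemes per syllable) and the
number of word tokens supporting that bin.  It is the common currency
between the simulation, the corpus pipeline and the curve-fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["LengthProfile"]


@dataclass(frozen=True)
class LengthProfile:
    """Ordered map ``m -> (mean_y, count)`` with strictly increasing keys."""

    bins: dict[int, tuple[float, int]]

    def __post_init__(self):
        ms = list(self.bins)
        if ms != sorted(ms):
            object.__setattr__(
                self, "bins", {m: self.bins[m] for m in sorted(ms)}
            )

    @property
    def ms(self) -> list[int]:
        return list(self.bins)

    @property
    def mean_y(self) -> list[float]:
        return [v[0] for v in self.bins.values()]

    @property
    def counts(self) -> list[int]:
        return [v[1] for v in self.bins.values()]

    def __len__(self) -> int:
        return len(self.bins)

    def __getitem__(self, m: int) -> tuple[float, int]:
        return self.bins[m]

    def __contains__(self, m: int) -> bool:
        return m in self.bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": self.ms,
                "mean_syllable_length": self.mean_y,
                "count": self.counts,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LengthProfile":
        df = pd.read_csv(path)
        return cls(
            {
                int(r.m): (float(r.mean_syllable_length), int(r["count"]))
                for _, r in df.iterrows()
            }
        )

    @classmethod
    def from_pairs(cls, ms, ys, counts=None) -> "LengthProfile":
        if counts is None:
            counts = [1] * len(list(ms))
        return cls(
            {int(m): (float(y), int(c)) for m, y, c in zip(ms, ys, counts)}
        )
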