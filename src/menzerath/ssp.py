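"""Sonority-based syllabification.

Implements grapheme-level syllabification by the Sonority Sequencing
Principle (SSP): sonority rises from the syllable onset to the nucleus
(the sonority peak, here a maximal run of vowel graphemes) and falls
through the coda.  Graphemes are ranked on a seven-class sonority scale

    vowels(7) > approximants(6) > liquids(5) > nasals(4)
    > fricatives(3) > affricates(2) > occlusives(1)

and each inter-nucleus consonant cluster is split immediately before the
last grapheme attaining the minimum sonority of the cluster, so that the
onset of the following syllable starts at the sonority trough.

The same table drives the coarse three-way symbol classification used by
the memoryless-source null model: rank-7 graphemes are vowels (V), ranks
1-6 are consonants (C), and anything outside the table (spaces,
punctuation, digits) is a word delimiter (S).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SONORITY_CLASSES",
    "SonorityTable",
    "SyllabifiedWord",
    "load_sonority_table",
    "default_sonority_table",
    "classify_symbol",
    "syllabify",
    "syllable_count",
]

#: Class name -> sonority rank (1 = least sonorous).
SONORITY_CLASSES: dict[str, int] = {
    "vowels": 7,
    "approximants": 6,
    "liquids": 5,
    "nasals": 4,
    "fricatives": 3,
    "affricates": 2,
    "occlusives": 1,
}

VOWEL_RANK = 7

# Built-in grapheme classification (single lowercase code points, NFC).
_DEFAULT_TABLE_TSV = """\
a\tvowels
e\tvowels
i\tvowels
o\tvowels
u\tvowels
y\tvowels
à\tvowels
á\tvowels
â\tvowels
ä\tvowels
æ\tvowels
ã\tvowels
å\tvowels
ā\tvowels
ą\tvowels
è\tvowels
é\tvowels
ê\tvowels
ë\tvowels
ē\tvowels
ė\tvowels
ę\tvowels
î\tvowels
ï\tvowels
í\tvowels
ī\tvowels
į\tvowels
ì\tvowels
ô\tvowels
ö\tvowels
ò\tvowels
ó\tvowels
œ\tvowels
ø\tvowels
ō\tvowels
õ\tvowels
û\tvowels
ü\tvowels
ù\tvowels
ú\tvowels
ū\tvowels
ů\tvowels
ÿ\tvowels
ű\tvowels
ő\tvowels
ŵ\tvowels
ŷ\tvowels
ỳ\tvowels
ẁ\tvowels
ě\tvowels
ý\tvowels
ǫ\tvowels
ŭ\tapproximants
w\tapproximants
ł\tapproximants
l\tliquids
r\tliquids
ř\tliquids
m\tnasals
n\tnasals
ñ\tnasals
ń\tnasals
ŋ\tnasals
ň\tnasals
ß\tfricatives
z\tfricatives
v\tfricatives
s\tfricatives
f\tfricatives
ç\tfricatives
ć\tfricatives
ś\tfricatives
ŝ\tfricatives
ĉ\tfricatives
ĥ\tfricatives
h\tfricatives
ĵ\tfricatives
š\tfricatives
ž\tfricatives
ð\tfricatives
đ\tfricatives
x\taffricates
j\taffricates
ź\taffricates
ż\taffricates
ĝ\taffricates
č\taffricates
b\tocclusives
c\tocclusives
d\tocclusives
g\tocclusives
t\tocclusives
k\tocclusives
p\tocclusives
q\tocclusives
þ\tocclusives
ď\tocclusives
ť\tocclusives
"""


class SonorityTableError(ValueError):
    """Raised when a sonority table cannot be loaded or validated."""


class UnknownGraphemeError(KeyError):
    """Raised when a word contains a grapheme absent from the table."""

    def __init__(self, grapheme: str, position: int):
        self.grapheme = grapheme
        self.position = position
        super().__init__(
            f"unknown grapheme {grapheme!r} at position {position}"
        )


@dataclass(frozen=True)
class SonorityTable:
    """Mapping grapheme -> sonority rank (1..7).

    Graphemes are single Unicode code points, lowercase and
    NFC-normalized.  Rank 7 marks vowels; ranks 1-6 consonants.
    """

    ranks: dict[str, int]

    def __post_init__(self):
        for g, r in self.ranks.items():
            if r not in range(1, 8):
                raise SonorityTableError(f"rank {r} for {g!r} outside 1..7")

    def rank(self, grapheme: str) -> int:
        return self.ranks[grapheme]

    def __contains__(self, grapheme: str) -> bool:
        return grapheme in self.ranks

    def vowels(self) -> list[str]:
        return [g for g, r in self.ranks.items() if r == VOWEL_RANK]

    def consonants(self) -> list[str]:
        return [g for g, r in self.ranks.items() if r < VOWEL_RANK]

    def graphemes_of_rank(self, rank: int) -> list[str]:
        return [g for g, r in self.ranks.items() if r == rank]

    def to_tsv(self, path: str | Path) -> None:
        names = {r: n for n, r in SONORITY_CLASSES.items()}
        with open(path, "w", encoding="utf-8") as fh:
            for g, r in self.ranks.items():
                fh.write(f"{g}\t{names[r]}\n")


def _parse_table(lines, source_name: str) -> SonorityTable:
    ranks: dict[str, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SonorityTableError(
                f"{source_name}:{lineno}: expected 'grapheme<TAB>class'"
            )
        grapheme = unicodedata.normalize("NFC", parts[0].strip().lower())
        cls = parts[1].strip().lower()
        if len(grapheme) != 1:
            raise SonorityTableError(
                f"{source_name}:{lineno}: grapheme {grapheme!r} is not a "
                "single code point"
            )
        if cls not in SONORITY_CLASSES:
            raise SonorityTableError(
                f"{source_name}:{lineno}: unknown sonority class {cls!r}"
            )
        if grapheme in ranks:
            raise SonorityTableError(
                f"{source_name}:{lineno}: duplicate grapheme {grapheme!r}"
            )
        ranks[grapheme] = SONORITY_CLASSES[cls]
    return SonorityTable(ranks)


def load_sonority_table(source: str | Path | None = None) -> SonorityTable:
    """Load a sonority table from a two-column TSV, or the built-in default.

    Parameters
    ----------
    source
        Path to a UTF-8 TSV file with rows ``grapheme<TAB>class-name``;
        ``None`` returns the built-in seven-class default table.
    """
    if source is None:
        return default_sonority_table()
    path = Path(source)
    with open(path, encoding="utf-8") as fh:
        return _parse_table(fh, str(path))


_DEFAULT: SonorityTable | None = None


def default_sonority_table() -> SonorityTable:
    """The built-in default grapheme classification (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _parse_table(_DEFAULT_TABLE_TSV.splitlines(), "<default>")
    return _DEFAULT


def classify_symbol(grapheme: str, table: SonorityTable) -> str:
    """Classify one character as ``'V'``, ``'C'`` or ``'S'``.

    Rank-7 graphemes map to V, ranks 1-6 to C, and any character absent
    from the table (whitespace, punctuation, digits, foreign letters) to
    the delimiter symbol S.  Total function: never raises.
    """
    g = unicodedata.normalize("NFC", grapheme.lower())
    r = table.ranks.get(g)
    if r is None:
        return "S"
    return "V" if r == VOWEL_RANK else "C"


@dataclass(frozen=True)
class SyllabifiedWord:
    """A word together with its syllable decomposition.

    ``boundaries`` are 0-based offsets between graphemes (a boundary at
    position ``k`` splits ``word[:k]`` / ``word[k:]``).  Concatenating
    ``syllables`` reproduces ``word`` exactly.
    """

    word: str
    boundaries: tuple[int, ...]
    vowel_free: bool = False
    syllables: tuple[str, ...] = field(init=False)
    syllable_lengths: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        cuts = (0,) + self.boundaries + (len(self.word),)
        syls = tuple(
            self.word[a:b] for a, b in zip(cuts[:-1], cuts[1:])
        )
        object.__setattr__(self, "syllables", syls)
        object.__setattr__(
            self, "syllable_lengths", tuple(len(s) for s in syls)
        )

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


def _vowel_runs(ranks: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of vowel ranks as half-open (start, stop) index pairs."""
    runs = []
    i = 0
    n = len(ranks)
    while i < n:
        if ranks[i] == VOWEL_RANK:
            j = i
            while j < n and ranks[j] == VOWEL_RANK:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def syllabify(word: str, table: SonorityTable | None = None) -> SyllabifiedWord:
    """Split a word into syllables by the sonority sequencing rule.

    Nuclei are the maximal runs of vowel graphemes (adjacent vowels share
    one nucleus, so e.g. diphthongs do not split).  For each consonant
    cluster ``c_1..c_k`` between two nuclei the boundary is placed
    immediately before ``c_j`` where ``j`` is the *largest* index
    attaining the minimum sonority of the cluster.  Leading consonants
    attach to the first syllable and trailing ones to the last.  A word
    with no vowel at all is returned as a single syllable flagged
    ``vowel_free``.

    Raises
    ------
    UnknownGraphemeError
        If a grapheme is missing from the table (position reported).
    """
    if table is None:
        table = default_sonority_table()
    if not word:
        raise ValueError("cannot syllabify an empty word")
    w = unicodedata.normalize("NFC", word.lower())
    ranks = []
    for pos, g in enumerate(w):
        try:
            ranks.append(table.rank(g))
        except KeyError:
            raise UnknownGraphemeError(g, pos) from None

    runs = _vowel_runs(ranks)
    if not runs:
        return SyllabifiedWord(w, (), vowel_free=True)

    boundaries = []
    for (_, prev_stop), (next_start, _) in zip(runs[:-1], runs[1:]):
        cluster = ranks[prev_stop:next_start]  # >= 1 consonant by maximality
        lo = min(cluster)
        # last index attaining the cluster minimum
        j = max(k for k, r in enumerate(cluster) if r == lo)
        boundaries.append(prev_stop + j)
    return SyllabifiedWord(w, tuple(boundaries))


def syllable_count(word: str, table: SonorityTable | None = None) -> int:
    """Number of syllables: vowel-run count, or 1 for vowel-free words."""
    return syllabify(word, table).n_syllables
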