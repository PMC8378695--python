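# Methods

## The quantities measured

A *construct* is a word token; its *constituents* are syllables measured
in graphemes (single Unicode code points after lowercasing and NFC
normalization). For a word of `m` syllables and `g` graphemes the mean
syllable length is `y = g/m`. A *length profile* collects, for each
word length `m`, the mean of `y` over all word tokens of that length
and the supporting token count. Two statistics are computed from it:

* **Menzerath's law (correlation form):** Spearman's rank correlation
  between `m` and mean `y`. A monotonically decreasing profile gives
  ρ = −1.
* **Menzerath–Altmann's law (parametric form, MAL):**
  `y(m) = α m^β exp(−γ m)` fitted by nonlinear least squares. When
  `β·γ > 0` the curve has an interior extremum at `m* = β/γ` (the
  derivative of `log y` is `β/m − γ`), marking an inverted regime where
  syllables lengthen with word length.

## The memoryless-source null model

A one-state source emits i.i.d. symbols C, V, S with probabilities
`p_c`, `p_v`, `p_s = 1 − p_c − p_v`. Words are maximal S-free segments;
the number of syllables in a word is approximated by its number of
vowels `M`, and `N` counts consonants. Consonant clusters — the runs of
C before the first V and after each V — are i.i.d. geometric,
`P(N_0 = n) = p_c^n (1 − p_c)`, and a word with `M = m` vowels has
`m + 1` of them, so `E(N | M = m) = (m+1) p_c/(1−p_c)` and

    E((N+M)/M | M = m) = a/m + b,  a = p_c/(1−p_c),  b = 1 + a.

The curve depends on `p_c` alone, is strictly decreasing, and tends to
`b` from above: the null model satisfies Menzerath's law for every
parameter value, but never the inverted regime. Its model assumptions —
single-vowel nuclei and position-independent cluster lengths — are
exactly what the corpus statistics `Syll/V` and the positional profile
probe.

**Independent oracle.** `exact_conditional_mean_oracle` recomputes the
conditional mean without the closed form: it sums over all C/V words up
to a truncation length, a word with `n` consonants and `m` vowels
carrying probability `C(n+m, n) p_c^n p_v^m p_s` (the binomial factor
counts the orderings; summing over orderings is mathematically the
literal enumeration of strings, and a test cross-checks it against a
brute-force string enumeration at small size). Conditioned on `M = m`
the consonant count is negative-binomial, which supplies an exact tail
bound: the oracle refuses to answer unless the truncated conditional
mass exceeds 1 − 1e−8. The default truncation of 60 graphemes is ample
for `p_c ≤ 0.5`; larger `p_c` needs a larger bound, which the error
message states.

**Simulation conventions.** Every stochastic operation takes an
explicit integer seed and uses a single `numpy` generator per call.
Simulation profiles are binned with a minimum of 10 tokens per bin;
corpus profiles with a minimum of 25 (the two thresholds are distinct
and configurable). Words with zero vowels are excluded from the
conditional statistic — `(N+M)/M` is undefined at `M = 0` — but still
count in symbol totals. Empty inter-delimiter segments are dropped.
Note that the geometric law for `N_0` holds for runs taken after
*every* delimiter; conditioning on non-empty words depletes the
`N_0 = 0` mass, so the goodness-of-fit test reads runs off the raw
symbol stream.

The standard error used in the simulation-vs-theory comparison follows
from the same derivation: given `M = m`, `N` is negative-binomial with
variance `(m+1) p_c/(1−p_c)^2`, so the bin mean of `(N+m)/m` has
standard error `sqrt((m+1) p_c/(1−p_c)^2 / count) / m`.

## Syllabification

Syllables are found by the Sonority Sequencing Principle over a
seven-class sonority scale (vowels 7 > approximants 6 > liquids 5 >
nasals 4 > fricatives 3 > affricates 2 > occlusives 1), with a built-in
default grapheme table covering the Latin-script inventory. The rule is
deterministic:

1. Nuclei are the maximal runs of rank-7 graphemes, so adjacent vowels
   (diphthongs) share one nucleus and the syllable count equals the
   vowel-run count. This is what drives `Syll/V ≤ 1`.
2. Each inter-nucleus consonant cluster `c_1..c_k` is split immediately
   before `c_j`, where `j` is the **largest** index attaining the
   cluster's minimum sonority. This yields `bar-co`, `gat-to`,
   `as-tro`: the next onset starts at the sonority trough, and sonority
   plateaus (`tt`) break before their last element.
3. Leading consonants join the first syllable, trailing ones the last.
   Vowel-free tokens form a single syllable flagged `vowel_free`
   (excluded from statistics by default, configurable).

Each grapheme belongs to exactly one class; ambiguous letters (`y`,
`w`) keep one fixed class regardless of context. Digraphs are not
units — classification is strictly per code point. The rule is chosen
for reproducibility and testability; matching any particular external
syllabifier implementation is a non-goal. With arbitrary real-word
input the split rule can produce onsets that are not sonority-
monotone (e.g. a cluster whose minimum is followed by a non-monotone
tail); on sonority-well-formed input it provably recovers the
generating boundaries (below).

## Corpus pipeline conventions

* Tokens are maximal runs of non-delimiter characters; whitespace,
  digits and a configurable punctuation set (including apostrophes and
  hyphens) delimit.
* A token survives filtering only if every grapheme is in the sonority
  table; the exclusion tally is reported.
* Two aggregation methods: *pooled* (corpus as one text; token-weighted
  means) and *by-document* (per-document means averaged with equal
  document weight). For a single document they coincide exactly. The
  minimum-count filter applies to the pooled token count per bin in
  both methods; a document enters a bin's average if it contributes at
  least one token.
* Monosyllables are excluded from profiles and correlation by default
  (they are known not to follow the law), with a flag to include them.
* In corpus summaries each inter-token gap counts as exactly one
  delimiter symbol, so `p_c + p_v + p_s = 1` with the symbol total
  `C + V + tokens`.
* Spearman correlation: midranks for ties (a constant profile gives
  ρ = 0); the two-sided p-value is an exact permutation value for
  profiles of ≤ 10 bins (full enumeration, vectorized) and the
  asymptotic approximation above that. Profiles this statistic is
  actually computed on have ~5–15 bins, where exactness matters.

## MAL fitting

Levenberg–Marquardt in linear space on the per-`m` mean values (not raw
tokens), unweighted by default — each profile point counts equally —
with an optional `sqrt(count)` weighting. α is optimized on a log scale
to enforce positivity; this also makes the scale equivariance exact
(scaling `y` by `c` scales α by `c`, leaving β, γ unchanged). The
default start is `α₀ = y` at the smallest fitted `m`,
`β₀ = γ₀ = −0.05`; on non-convergence a small multi-start grid over
`(β₀, γ₀) ∈ {−0.2, −0.05, 0.05}²` is tried. R² = 1 − SS_res/SS_tot is
computed on exactly the fitted bins. Reported `β/γ` is rounded to one
decimal in human-readable output; JSON keeps full precision.

Fitting the null curve `a/m + b` itself (p_c = 0.48, m = 2..12) gives
R² ≈ 0.996 with a fitted curve that is strictly decreasing across
every bin in the range: the null model shows no observable inverted
regime. The least-squares optimum can place a very shallow stationary
point (depth ~1e−4 graphemes) at the edge of the fitted range, so the
meaningful invariant — asserted in the tests — is bin-level
monotonicity, not the sign of `β·γ`.

## Positional profiles

Syllable position `i = 1..m` is standardized to `x = (i−1)/(m−1)`
(`x = 0.5` for monosyllables, which are retained in this analysis).
For each `(m, i)` cell the mean grapheme length of the i-th syllable is
computed over all words of length `m`; groups below 25 words are
dropped. Every word contributes one syllable to every position, so
within an `m` group all cells share one count, and the equally-weighted
mean over `i` reproduces the length-profile value for that `m` exactly.

## Synthetic generators

All generators are pure functions of (parameters, seed).

**Rendered memoryless text** maps each C to a uniformly random
consonant grapheme, V to a uniformly random vowel grapheme, S to a
space. Uniformity within class is the minimal assumption — the null
model constrains only classes — and cannot affect class-level
statistics. Running the tokenizer and symbol classifier over the
rendered text reproduces the per-word (consonants, vowels) counts of
the underlying stream exactly. Note that the *syllabifier*-based
profile of such text sits above `a/m + b`, because adjacent vowel
symbols merge into one nucleus (the diphthong effect the null model
ignores); the class-level profile (`m` = vowel count) is the one the
closed form describes.

**Sonority-well-formed words.** Each syllable is onset (strictly rising
sonority) + single-vowel nucleus + coda (strictly falling). Two extra
constraints make boundary recovery provable: every word-internal
syllable's onset starts with a rank-1 (occlusive) grapheme, and the
preceding coda draws from ranks ≥ 2 only. Each inter-nucleus cluster is
then a falling sequence of ranks ≥ 2 followed by a rising sequence
starting at rank 1, so its sonority minimum is unique and sits exactly
at the true onset — the split-before-last-minimum rule recovers the
generating boundary with certainty, which the round-trip tests confirm
at 100%.

**MAL profiles** place `mean_y(m)` on a chosen curve times
`(1 + ε_m)`, ε Gaussian with configurable sd, floored at a small
positive value.

**Position-structured corpora** draw each word's length `m` from a
configurable distribution and each syllable's grapheme count from a
shifted Poisson, `L = base + Poisson(g(i,m) − base)` with `base = 1`
for the first syllable and `2` for later ones (which need an onset).
The shift keeps lengths valid grapheme counts while `E[L] = g(i, m)`
exactly; draws beyond the feasible syllable length under the rank caps
(12–13 graphemes) are clipped, an event of negligible probability for
realistic means. The default structure mimics the shape seen in real
text — mean lengths 2.5 (first), 3.5 (second), 2.0 (penultimate), 3.0
(final), 2.5 elsewhere, word lengths 1–6 with a decaying distribution —
since no quantitative profile is available to copy.

## Problem sizes and default parameters

| quantity | default | notes |
|---|---|---|
| source probabilities (p_c, p_v) | 0.48, 0.37 | typical consonant/vowel frequencies of alphabetic text |
| simulation length | 10^6 symbols | gives ~150k words; ~25 retained bins at min-count 10 |
| simulation bin minimum | 10 tokens | |
| corpus bin minimum | 25 tokens | also used for positional groups |
| monosyllables | excluded | flag to include |
| oracle truncation | 60 graphemes | with an exact mass check at 1 − 1e−8 |
| fit-recovery study | 200 replicates, 1% noise, m = 2..12 | median abs. β error ≈ 0.017 |
| round-trip corpus | 10^4 words, ≤ 5 syllables | |
| positional corpus | 3·10^4 words | all ≥100-word cells within 3 SE |

## What passing tests do and do not show

The generators emulate the *structural* properties the analysis relies
on (class frequencies, well-formed sonority profiles, known positional
means); they do not reproduce natural-language frequency distributions
(Zipfian token frequencies, morphology, loanword noise, real diphthong
inventories). Passing recovery tests therefore validates the
measurement chain — that the pipeline measures what a corpus actually
contains — not any linguistic claim about a particular language.
Conclusions about real corpora require real corpora; corpus curation
and ingestion of any specific collection are out of scope.

## Known limitations

* The syllabifier is a single deterministic SSP rule; languages with
  syllabic consonants, context-dependent vowels or non-Latin scripts
  need a different table or rule.
* The exact permutation p-value enumerates up to 10! permutations
  (~1–2 s at 10 bins); larger profiles fall back to the asymptotic
  approximation.
* The by-document averaging method reports the pooled token count per
  bin; per-document dispersion is not propagated into the fit.
* `b − a = 1` holds exactly as the identity `b == 1 + a` on the stored
  parameters; the floating-point difference `b − a` can differ from 1
  in the last bit.
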