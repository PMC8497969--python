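"""Phono-lexical measures of child-directed speech.

Given a cleaned session token stream and a pronouncing lexicon, this module
computes:

* type/token counts, TTR, and the moving-average type-token ratio (MATTR,
  10-token window by default);
* per-word-type lexical statistics — word length in phonemes, log10 word
  frequency, phonological neighborhood density (Vitevitch-&-Luce-style
  one-edit neighbors), and positional biphone phonotactic probability with
  a length-stratified z-normalization;
* the derived "unnested" per-caregiver counts (number of long words,
  number of low-frequency words) obtained by median splits pooled across
  caregivers.

Cleaning removes onomatopoeia, exclamations and proper names everywhere;
contractions stay in the token/type/TTR counts but are dropped from the
phono-lexical lookups (pronouncing dictionaries do not list them).
Lexical statistics are computed over word *types*, not tokens.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field

from .arpabet import strip_stress
from .corpus_io import Lexicon, LexiconEntry, SessionTranscript, WordToken

log = logging.getLogger("cdsbattery")

#: tags that remove a token from every measure
EXCLUDE_EVERYWHERE = frozenset({"onomatopoeia", "exclamation", "proper_name"})
#: tags that remove a type only from phono-lexical lookups
EXCLUDE_PHONOLEXICAL = frozenset({"contraction"})

DEFAULT_MATTR_WINDOW = 10


class UndefinedStatError(ValueError):
    """Raised when a statistic is requested on an empty token stream."""


# ---------------------------------------------------------------------------
# cleaning and diversity statistics
# ---------------------------------------------------------------------------

def clean_word_inventory(
    session: SessionTranscript,
) -> tuple[list[WordToken], set[str], dict[str, int]]:
    """Apply the transcript-cleaning rules.

    Returns ``(kept_tokens, phonolexical_types, excluded_counts)`` where
    ``kept_tokens`` feed the token/type/TTR/MATTR counts and
    ``phonolexical_types`` is the subset of kept types eligible for
    lexicon lookups (contractions removed).  The exclusion ledger conserves
    tokens: kept + excluded == input.
    """
    kept: list[WordToken] = []
    excluded = Counter()
    contraction_types: set[str] = set()
    for tok in session.tokens:
        hard = tok.tags & EXCLUDE_EVERYWHERE
        if hard:
            excluded[sorted(hard)[0]] += 1
            continue
        kept.append(tok)
        if tok.tags & EXCLUDE_PHONOLEXICAL:
            contraction_types.add(tok.orthography)
    kept_types = {t.orthography for t in kept}
    ledger = {tag: excluded.get(tag, 0) for tag in sorted(EXCLUDE_EVERYWHERE)}
    ledger["kept"] = len(kept)
    return kept, kept_types - contraction_types, ledger


def type_token_stats(tokens: list[WordToken] | list[str]) -> tuple[int, int, float]:
    """(n_types, n_tokens, TTR) of a token stream."""
    words = _orthographies(tokens)
    if not words:
        raise UndefinedStatError("TTR undefined on an empty token stream")
    n_tokens = len(words)
    n_types = len(set(words))
    return n_types, n_tokens, n_types / n_tokens


def mattr(
    tokens: list[WordToken] | list[str],
    window: int = DEFAULT_MATTR_WINDOW,
) -> tuple[float, bool]:
    """Moving-average TTR over every contiguous window of `window` tokens.

    Windows advance one token at a time and span the whole session stream
    (they are not reset at utterance boundaries).  Streams shorter than the
    window fall back to plain TTR; the second return value flags that.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    words = _orthographies(tokens)
    if not words:
        raise UndefinedStatError("MATTR undefined on an empty token stream")
    n = len(words)
    if n < window:
        _, _, ttr = type_token_stats(words)
        return ttr, True
    # sliding multiset of the current window
    counts: Counter[str] = Counter(words[:window])
    total_distinct = len(counts)
    n_windows = n - window + 1
    acc = total_distinct
    for i in range(window, n):
        incoming, outgoing = words[i], words[i - window]
        counts[incoming] += 1
        if counts[incoming] == 1:
            total_distinct += 1
        counts[outgoing] -= 1
        if counts[outgoing] == 0:
            total_distinct -= 1
            del counts[outgoing]
        acc += total_distinct
    return acc / (n_windows * window), False


def _orthographies(tokens) -> list[str]:
    return [t.orthography if isinstance(t, WordToken) else str(t).lower()
            for t in tokens]


# ---------------------------------------------------------------------------
# biphone phonotactic probability
# ---------------------------------------------------------------------------

@dataclass
class BiphoneTables:
    """Positional biphone counts over a lexicon's pronunciations.

    ``positional_counts[(i, (a, b))]`` is the number of pronunciations with
    segmental pair (a, b) starting at 0-based position ``i``;
    ``positional_totals[i]`` is the number of pronunciations long enough to
    host a biphone there (length > i + 1).  Counting is type-based and
    unweighted by default; ``weighted=True`` weights each pronunciation by
    its word's (linear) frequency 10**log_frequency.
    """

    positional_counts: dict[tuple[int, tuple[str, str]], float] = field(
        default_factory=dict)
    positional_totals: dict[int, float] = field(default_factory=dict)


def build_biphone_tables(lexicon: Lexicon, weighted: bool = False) -> BiphoneTables:
    tables = BiphoneTables()
    for entry in lexicon.entries.values():
        weight = 10.0 ** entry.log_frequency if weighted else 1.0
        for variant in entry.variants:
            segs = [strip_stress(s) for s in variant]
            for i in range(len(segs) - 1):
                key = (i, (segs[i], segs[i + 1]))
                tables.positional_counts[key] = (
                    tables.positional_counts.get(key, 0.0) + weight)
                tables.positional_totals[i] = (
                    tables.positional_totals.get(i, 0.0) + weight)
    return tables


def phonotactic_probability(
    pron: tuple[str, ...] | list[str], tables: BiphoneTables,
) -> float | None:
    """Mean positional biphone probability of a pronunciation.

    Returns None for single-segment pronunciations (no biphones).  A
    biphone at a position with zero total contributes probability 0.
    """
    segs = [strip_stress(s) for s in pron]
    if len(segs) < 2:
        return None
    probs = []
    for i in range(len(segs) - 1):
        total = tables.positional_totals.get(i, 0.0)
        if total <= 0:
            probs.append(0.0)
        else:
            probs.append(
                tables.positional_counts.get((i, (segs[i], segs[i + 1])), 0.0)
                / total
            )
    return sum(probs) / len(probs)


def phonprob_strata(
    lexicon: Lexicon, tables: BiphoneTables | None = None,
) -> dict[int, tuple[float, float]]:
    """(mean, sd) of raw phonotactic probability per word-length stratum.

    The reference distribution for stratum L is the raw probability of
    every lexicon pronunciation of segmental length L; strata with fewer
    than two members or zero spread are omitted.
    """
    if tables is None:
        tables = build_biphone_tables(lexicon)
    strata: dict[int, list[float]] = {}
    for entry in lexicon.entries.values():
        for variant in entry.variants:
            p = phonotactic_probability(variant, tables)
            if p is not None:
                strata.setdefault(len(variant), []).append(p)
    stats: dict[int, tuple[float, float]] = {}
    for n, vals in strata.items():
        if len(vals) < 2:
            continue
        mean = sum(vals) / len(vals)
        sd = statistics.stdev(vals)
        if sd > 0:
            stats[n] = (mean, sd)
    return stats


def zscore_phonprob(
    raw_values: list[float | None],
    lengths: list[int],
    lexicon: Lexicon,
    tables: BiphoneTables | None = None,
    strata: dict[int, tuple[float, float]] | None = None,
) -> list[float | None]:
    """Z-normalize raw phonotactic probabilities within word-length strata
    to remove the length confound (longer words have more, individually
    rarer, biphones)."""
    stats = strata if strata is not None else phonprob_strata(lexicon, tables)
    out: list[float | None] = []
    for raw, length in zip(raw_values, lengths):
        if raw is None or length not in stats:
            if raw is not None:
                log.warning(
                    "zscore_phonprob: no usable length-%d stratum", length)
            out.append(None)
        else:
            mean, sd = stats[length]
            out.append((raw - mean) / sd)
    return out


# ---------------------------------------------------------------------------
# neighborhood density
# ---------------------------------------------------------------------------

def _one_edit_apart(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is shorter by one: b must equal a with one insertion
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


def neighborhood_density(
    pron: tuple[str, ...] | list[str],
    lexicon: Lexicon,
    query_orthography: str | None = None,
) -> int:
    """Number of phonological neighbors of a pronunciation in the lexicon.

    A neighbor is a distinct orthography (never the query word itself) with
    at least one variant exactly one segmental edit away — one substitution,
    deletion or addition.  Stress digits are ignored.
    """
    query = tuple(strip_stress(s) for s in pron)
    me = query_orthography.lower() if query_orthography else None
    n = 0
    for word, entry in lexicon.entries.items():
        if word == me:
            continue
        for variant in entry.variants:
            cand = tuple(strip_stress(s) for s in variant)
            if _one_edit_apart(query, cand):
                n += 1
                break
    return n


# ---------------------------------------------------------------------------
# variant selection and the per-type profile
# ---------------------------------------------------------------------------

def select_variant(
    entry: LexiconEntry, tables: BiphoneTables,
) -> tuple[str, ...]:
    """Pick the pronunciation variant with the highest phonotactic
    probability; ties (and all-length-1 entries) fall back to the first
    listed variant."""
    best = entry.variants[0]
    best_p = phonotactic_probability(best, tables)
    for variant in entry.variants[1:]:
        p = phonotactic_probability(variant, tables)
        if p is not None and (best_p is None or p > best_p):
            best, best_p = variant, p
        elif p is not None and p == best_p:
            log.debug("select_variant: tie for %r, keeping first listed",
                      entry.orthography)
    return best


@dataclass
class LexicalProfile:
    orthography: str
    length_phonemes: int | None
    log_frequency: float | None
    neighborhood_density: int | None
    phonprob_raw: float | None
    phonprob_z: float | None
    in_lexicon: bool


class LexiconProfiler:
    """Precomputes per-word lexical statistics for a fixed lexicon.

    Building the biphone tables, z-score strata and density index once per
    lexicon makes per-session profiling a dictionary lookup, which matters
    when the same lexicon serves hundreds of synthetic sessions.
    """

    def __init__(self, lexicon: Lexicon, weighted_biphones: bool = False):
        self.lexicon = lexicon
        self.tables = build_biphone_tables(lexicon, weighted=weighted_biphones)
        self._strata = phonprob_strata(lexicon, self.tables)
        self._cache: dict[str, LexicalProfile] = {}
        self._density_index = self._build_density_index()

    def _build_density_index(self) -> dict[str, int]:
        # bucket pronunciations by length so only |Δlen| <= 1 pairs are tried
        by_len: dict[int, list[tuple[str, tuple[str, ...]]]] = {}
        selected: dict[str, tuple[str, ...]] = {}
        for word, entry in self.lexicon.entries.items():
            for variant in entry.variants:
                seg = tuple(strip_stress(s) for s in variant)
                by_len.setdefault(len(seg), []).append((word, seg))
            selected[word] = tuple(
                strip_stress(s) for s in select_variant(entry, self.tables))
        out: dict[str, int] = {}
        for word, query in selected.items():
            neighbors: set[str] = set()
            for ln in (len(query) - 1, len(query), len(query) + 1):
                for other, cand in by_len.get(ln, ()):  # noqa: B905
                    if other == word or other in neighbors:
                        continue
                    if _one_edit_apart(query, cand):
                        neighbors.add(other)
            out[word] = len(neighbors)
        return out

    def profile(self, orthography: str) -> LexicalProfile:
        word = orthography.lower()
        if word in self._cache:
            return self._cache[word]
        entry = self.lexicon.get(word)
        if entry is None:
            prof = LexicalProfile(word, None, None, None, None, None, False)
        else:
            variant = select_variant(entry, self.tables)
            raw = phonotactic_probability(variant, self.tables)
            z = zscore_phonprob(
                [raw], [len(variant)], self.lexicon, self.tables,
                strata=self._strata)[0] if raw is not None else None
            prof = LexicalProfile(
                orthography=word,
                length_phonemes=len(variant),
                log_frequency=entry.log_frequency,
                neighborhood_density=self._density_index[word],
                phonprob_raw=raw,
                phonprob_z=z,
                in_lexicon=True,
            )
        self._cache[word] = prof
        return prof


def lexical_profile(
    session: SessionTranscript,
    lexicon: Lexicon | LexiconProfiler,
) -> tuple[dict[str, LexicalProfile], dict[str, float | int | None]]:
    """Per-type profiles and the battery summaries for one session.

    Summary aggregators: median for log frequency and neighborhood density,
    mean for word length and for the z-scored phonotactic probability.
    Types missing from the lexicon are null-profiled and counted.
    """
    profiler = (lexicon if isinstance(lexicon, LexiconProfiler)
                else LexiconProfiler(lexicon))
    _, phonolexical_types, _ = clean_word_inventory(session)
    profiles = {t: profiler.profile(t) for t in sorted(phonolexical_types)}
    in_lex = [p for p in profiles.values() if p.in_lexicon]

    def _median(vals):
        vals = [v for v in vals if v is not None]
        return statistics.median(vals) if vals else None

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else None

    summaries = {
        "mean_word_length": _mean([p.length_phonemes for p in in_lex]),
        "median_log_frequency": _median([p.log_frequency for p in in_lex]),
        "median_neighborhood_density": _median(
            [p.neighborhood_density for p in in_lex]),
        "mean_phonprob_z": _mean([p.phonprob_z for p in in_lex]),
        "n_profiled_types": len(in_lex),
        "n_unprofiled_types": len(profiles) - len(in_lex),
    }
    if summaries["n_unprofiled_types"]:
        log.info("lexical_profile: %d/%d types missing from the lexicon",
                 summaries["n_unprofiled_types"], len(profiles))
    return profiles, summaries


# ---------------------------------------------------------------------------
# median-split unnesting
# ---------------------------------------------------------------------------

def pooled_median(values_per_caregiver: dict[str, list[float]]) -> float:
    """Median over the union of all caregivers' per-type values (one
    observation per caregiver-type; types shared across caregivers are not
    deduplicated)."""
    pooled = [v for vals in values_per_caregiver.values() for v in vals
              if v is not None]
    if not pooled:
        raise UndefinedStatError("pooled median of an empty collection")
    return statistics.median(pooled)


def long_word_count(
    type_profiles: dict[str, LexicalProfile], pooled_median_length: float,
) -> int:
    """Number of word types with length >= the pooled median (inclusive)."""
    return sum(
        1 for p in type_profiles.values()
        if p.length_phonemes is not None
        and p.length_phonemes >= pooled_median_length
    )


def low_freq_count(
    type_profiles: dict[str, LexicalProfile], pooled_median_freq: float,
) -> int:
    """Number of word types with log frequency strictly below the pooled
    median."""
    return sum(
        1 for p in type_profiles.values()
        if p.log_frequency is not None and p.log_frequency < pooled_median_freq
    )
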