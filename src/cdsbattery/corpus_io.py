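"""Reading, writing and validating the on-disk session artifacts.

The module owns the domain containers (phone intervals, word tokens,
sessions, lexicon entries, per-session feature rows) and the plumbing
between formats:

* Praat TextGrid, **long format only** — phone and word interval tiers.
  Whispered / yelled / overlapping speech is marked by suffixing the phone
  label with ``@w`` / ``@y`` / ``@o`` (annotation convention of this
  package; real corpora vary).
* Token tables, lexicons and formant measurements as TSV.
* The per-(dyad, timepoint) feature table as CSV.
* A minimal CHAT main-tier importer for convenience.

Times are seconds; intervals are half-open ``[start, end)``; two phones
count as adjacent when the gap between them is at most a configurable
tolerance (default 1 ms).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .arpabet import INVENTORY, strip_stress, validate_symbol

log = logging.getLogger("cdsbattery")

TIMEPOINTS = ("7", "10-11", "18", "24")
ALLOWED_TAGS = frozenset({"onomatopoeia", "exclamation", "proper_name", "contraction"})
FLAG_SUFFIXES = {"@w": "whispered", "@y": "yelled", "@o": "overlap"}
DEFAULT_ADJACENCY_TOL = 0.001  # seconds


class TextGridParseError(ValueError):
    """Malformed TextGrid; message names the offending line."""


class ValidationError(ValueError):
    """A container invariant was violated."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class PhoneInterval:
    label: str                       # ARPAbet, vowels may carry stress digit
    start: float
    end: float
    word_index: int | None = None    # index into SessionTranscript.tokens
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("phone label must be non-empty")
        if self.start < 0 or not self.end > self.start:
            raise ValidationError(
                f"phone {self.label!r}: need 0 <= start < end, got "
                f"[{self.start}, {self.end}]"
            )
        bad = set(self.flags) - set(FLAG_SUFFIXES.values())
        if bad:
            raise ValidationError(f"unknown phone flags {sorted(bad)}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class WordToken:
    orthography: str
    utterance_index: int
    token_index: int
    tags: frozenset[str] = frozenset()
    is_content: bool = True

    def __post_init__(self) -> None:
        if not self.orthography:
            raise ValidationError("token orthography must be non-empty")
        self.orthography = self.orthography.lower()
        bad = set(self.tags) - ALLOWED_TAGS
        if bad:
            raise ValidationError(
                f"unknown tags {sorted(bad)}; allowed: {sorted(ALLOWED_TAGS)}"
            )


@dataclass
class FormantMeasurement:
    """Midpoint F1/F2 of a peripheral vowel token; Hz raw, z after Lobanov."""

    phone_index: int
    category: str                    # "i", "a", "u" or "other"
    f1_hz: float
    f2_hz: float
    f1_z: float | None = None
    f2_z: float | None = None

    def __post_init__(self) -> None:
        if not (self.f2_hz > self.f1_hz > 0):
            raise ValidationError(
                f"need F2 > F1 > 0 Hz, got F1={self.f1_hz}, F2={self.f2_hz}"
            )


@dataclass
class SessionTranscript:
    dyad_id: str
    timepoint: str
    tokens: list[WordToken] = field(default_factory=list)
    phones: list[PhoneInterval] = field(default_factory=list)
    formants: list[FormantMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint {self.timepoint!r} not in {TIMEPOINTS}"
            )
        last = None
        for tok in self.tokens:
            if last is not None and tok.token_index <= last:
                raise ValidationError("token_index must be strictly increasing")
            last = tok.token_index
        n = len(self.tokens)
        prev_end = None
        for ph in self.phones:
            if ph.word_index is not None and not (0 <= ph.word_index < n):
                raise ValidationError(
                    f"phone {ph.label!r} word_index {ph.word_index} out of range"
                )
            if prev_end is not None and ph.start < prev_end - 1e-9:
                raise ValidationError("phone intervals overlap or are unsorted")
            prev_end = ph.end
        for fm in self.formants:
            if not (0 <= fm.phone_index < len(self.phones)):
                raise ValidationError("formant phone_index out of range")

    def phones_of_word(self, word_index: int) -> list[PhoneInterval]:
        return [p for p in self.phones if p.word_index == word_index]


@dataclass
class LexiconEntry:
    orthography: str
    variants: list[tuple[str, ...]]    # ARPAbet with stress digits on vowels
    log_frequency: float               # log10, SUBTLEX-like scale
    is_function_word: bool = False

    def __post_init__(self) -> None:
        if not self.variants or any(len(v) == 0 for v in self.variants):
            raise ValidationError(
                f"{self.orthography!r}: every entry needs >=1 non-empty variant"
            )


class Lexicon:
    """Pronouncing lexicon: orthography -> entry, plus its symbol inventory."""

    def __init__(self, entries: dict[str, LexiconEntry] | None = None):
        self.entries: dict[str, LexiconEntry] = dict(entries or {})
        self.inventory: set[str] = set()
        for entry in self.entries.values():
            for variant in entry.variants:
                for sym in variant:
                    self.inventory.add(validate_symbol(sym))

    def __contains__(self, orthography: str) -> bool:
        return orthography.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, orthography: str) -> LexiconEntry | None:
        return self.entries.get(orthography.lower())

    def add(self, entry: LexiconEntry) -> None:
        key = entry.orthography.lower()
        for variant in entry.variants:
            for sym in variant:
                self.inventory.add(validate_symbol(sym))
        if key in self.entries:
            existing = self.entries[key]
            for variant in entry.variants:
                if variant not in existing.variants:
                    existing.variants.append(variant)
        else:
            self.entries[key] = replace(
                entry, orthography=key, variants=list(entry.variants)
            )


FEATURE_COLUMNS = [
    "dyad_id", "timepoint", "n_types", "n_tokens", "ttr", "mattr",
    "mattr_fallback", "mean_word_length", "median_log_frequency",
    "median_neighborhood_density", "mean_phonprob_z", "n_long_words",
    "n_low_freq_words", "n_profiled_types", "n_unprofiled_types",
    "vowel_space_area_z", "vowel_space_area_hz", "median_dispersion",
    "median_phone_duration_ms", "median_coarticulation_distance",
    "n_duration_obs", "n_coarticulation_obs", "n_vowel_tokens",
]


@dataclass
class FeatureRow:
    """One (dyad, timepoint) row of the child-directed-speech battery.

    Missing acoustic measures are None (written as empty CSV cells), never 0.
    """

    dyad_id: str
    timepoint: str
    n_types: int = 0
    n_tokens: int = 0
    ttr: float | None = None
    mattr: float | None = None
    mattr_fallback: bool = False
    mean_word_length: float | None = None
    median_log_frequency: float | None = None
    median_neighborhood_density: float | None = None
    mean_phonprob_z: float | None = None
    n_long_words: int | None = None
    n_low_freq_words: int | None = None
    n_profiled_types: int = 0
    n_unprofiled_types: int = 0
    vowel_space_area_z: float | None = None
    vowel_space_area_hz: float | None = None
    median_dispersion: float | None = None
    median_phone_duration_ms: float | None = None
    median_coarticulation_distance: float | None = None
    n_duration_obs: int = 0
    n_coarticulation_obs: int = 0
    n_vowel_tokens: int = 0

    def __post_init__(self) -> None:
        if self.n_tokens and self.ttr is not None and not (0 < self.ttr <= 1):
            raise ValidationError(f"ttr {self.ttr} outside (0, 1]")
        if self.n_tokens and self.mattr is not None and not (0 < self.mattr <= 1):
            raise ValidationError(f"mattr {self.mattr} outside (0, 1]")
        for name in ("n_types", "n_tokens", "n_profiled_types",
                     "n_unprofiled_types", "n_duration_obs",
                     "n_coarticulation_obs", "n_vowel_tokens"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# TextGrid (Praat long format)
# ---------------------------------------------------------------------------

_QUOTED = re.compile(r'"((?:[^"]|"")*)"')


def _read_text(path: str | Path) -> str:
    raw = Path(path).read_bytes()
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    return raw.decode("utf-8")


def _parse_flags(label: str) -> tuple[str, frozenset[str]]:
    flags: set[str] = set()
    changed = True
    while changed:
        changed = False
        for suffix, flag in FLAG_SUFFIXES.items():
            if label.endswith(suffix):
                label = label[: -len(suffix)]
                flags.add(flag)
                changed = True
    return label, frozenset(flags)


def _flag_suffix(flags: frozenset[str]) -> str:
    rev = {v: k for k, v in FLAG_SUFFIXES.items()}
    return "".join(rev[f] for f in sorted(flags))


def read_textgrid(
    path: str | Path,
    phone_tier_name: str = "phones",
    word_tier_name: str = "words",
) -> tuple[list[PhoneInterval], list[tuple[float, float, str]]]:
    """Parse a long-format TextGrid into phone intervals and word intervals.

    Empty-label intervals are dropped.  Phone labels may carry the
    ``@w``/``@y``/``@o`` flag suffixes.  Word intervals are returned as
    ``(start, end, label)`` for :func:`attach_phones_to_words`.
    """
    text = _read_text(path)
    lines = text.splitlines()
    if not any('"ooTextFile"' in ln for ln in lines[:3]):
        raise TextGridParseError(f"{path}: line 1: not an ooTextFile header")
    if not any('"TextGrid"' in ln for ln in lines[:3]):
        raise TextGridParseError(f"{path}: line 2: not a TextGrid object")
    if not any(ln.strip().startswith("item") for ln in lines):
        raise TextGridParseError(
            f"{path}: no 'item' blocks found — short-format TextGrids are "
            "not supported, convert to long format in Praat"
        )

    tiers: dict[str, list[tuple[float, float, str]]] = {}
    current_name: str | None = None
    xmin = xmax = None
    label = None
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if s.startswith("name ="):
            m = _QUOTED.search(s)
            if not m:
                raise TextGridParseError(f"{path}: line {lineno}: bad tier name")
            current_name = m.group(1)
            tiers[current_name] = []
        elif s.startswith("xmin =") and current_name is not None:
            try:
                xmin = float(s.split("=", 1)[1])
            except ValueError as exc:
                raise TextGridParseError(
                    f"{path}: line {lineno}: bad xmin"
                ) from exc
        elif s.startswith("xmax =") and current_name is not None:
            try:
                xmax = float(s.split("=", 1)[1])
            except ValueError as exc:
                raise TextGridParseError(
                    f"{path}: line {lineno}: bad xmax"
                ) from exc
        elif s.startswith("text =") and current_name is not None:
            m = _QUOTED.search(s)
            if m is None:
                raise TextGridParseError(f"{path}: line {lineno}: bad text field")
            label = m.group(1).replace('""', '"').strip()
            if xmin is None or xmax is None:
                raise TextGridParseError(
                    f"{path}: line {lineno}: text before interval bounds"
                )
            if label:
                tiers[current_name].append((xmin, xmax, label))
            xmin = xmax = None

    def _tier(name: str) -> list[tuple[float, float, str]]:
        if name not in tiers:
            raise TextGridParseError(
                f"{path}: tier {name!r} not found; available: {sorted(tiers)}"
            )
        ivs = sorted(tiers[name])
        for (a0, a1, _), (b0, _, lab) in zip(ivs, ivs[1:]):
            if b0 < a1 - 1e-9:
                raise ValidationError(
                    f"{path}: tier {name!r}: interval {lab!r} at {b0:.4f} "
                    f"overlaps previous interval ending {a1:.4f}"
                )
        return ivs

    phone_ivs = _tier(phone_tier_name)
    word_ivs = _tier(word_tier_name)
    if not phone_ivs:
        log.warning("%s: phone tier %r has no labeled intervals",
                    path, phone_tier_name)
    phones = []
    for start, end, raw_label in phone_ivs:
        lab, flags = _parse_flags(raw_label)
        phones.append(PhoneInterval(lab, start, end, flags=flags))
    return phones, word_ivs


def write_textgrid(
    path: str | Path,
    phones: list[PhoneInterval],
    word_intervals: list[tuple[float, float, str]],
    phone_tier_name: str = "phones",
    word_tier_name: str = "words",
) -> None:
    """Write a long-format TextGrid with a phone and a word tier."""
    tmax = 0.0
    for p in phones:
        tmax = max(tmax, p.end)
    for _, end, _ in word_intervals:
        tmax = max(tmax, end)

    def _interval_lines(ivs: list[tuple[float, float, str]]) -> list[str]:
        out = [f"        intervals: size = {len(ivs)}"]
        for i, (start, end, lab) in enumerate(ivs, start=1):
            out += [
                f"        intervals [{i}]:",
                f"            xmin = {start:.6f}",
                f"            xmax = {end:.6f}",
                f'            text = "{lab.replace(chr(34), chr(34) * 2)}"',
            ]
        return out

    phone_ivs = [(p.start, p.end, p.label + _flag_suffix(p.flags))
                 for p in phones]
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {tmax:.6f}",
        "tiers? <exists>",
        "size = 2",
        "item []:",
    ]
    for idx, (name, ivs) in enumerate(
        [(phone_tier_name, phone_ivs), (word_tier_name, word_intervals)],
        start=1,
    ):
        lines += [
            f"    item [{idx}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {tmax:.6f}",
        ]
        lines += _interval_lines(list(ivs))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# token table / lexicon / formants TSV
# ---------------------------------------------------------------------------

def read_token_table(path: str | Path) -> list[WordToken]:
    """Read the token TSV (utterance_index, token_index, orthography, tags)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"utterance_index", "token_index", "orthography", "tags"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        log.warning("%s: token table has no rows", path)
        return []
    tokens: list[WordToken] = []
    seen: set[int] = set()
    for _, row in df.iterrows():
        idx = int(row["token_index"])
        if idx in seen:
            raise ValidationError(f"{path}: duplicate token_index {idx}")
        seen.add(idx)
        tags = frozenset(t.strip() for t in row["tags"].split(",") if t.strip())
        tokens.append(
            WordToken(
                orthography=row["orthography"],
                utterance_index=int(row["utterance_index"]),
                token_index=idx,
                tags=tags,
            )
        )
    tokens.sort(key=lambda t: t.token_index)
    return tokens


def write_token_table(tokens: list[WordToken], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "utterance_index": [t.utterance_index for t in tokens],
            "token_index": [t.token_index for t in tokens],
            "orthography": [t.orthography for t in tokens],
            "tags": [",".join(sorted(t.tags)) for t in tokens],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_lexicon(path: str | Path) -> Lexicon:
    """Read the lexicon TSV; repeated orthography rows become variants."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"orthography", "pronunciation", "log10_frequency",
                "is_function_word"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    lex = Lexicon()
    for _, row in df.iterrows():
        word = row["orthography"].lower()
        if not row["log10_frequency"].strip():
            raise ValidationError(
                f"{path}: {word!r}: log10_frequency is required"
            )
        pron = tuple(row["pronunciation"].split())
        for sym in pron:
            if strip_stress(sym) not in INVENTORY:
                raise ValidationError(
                    f"{path}: {word!r}: symbol {sym!r} outside the inventory"
                )
        lex.add(
            LexiconEntry(
                orthography=word,
                variants=[pron],
                log_frequency=float(row["log10_frequency"]),
                is_function_word=row["is_function_word"].strip() in
                ("1", "true", "True"),
            )
        )
    return lex


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    rows = []
    for word in sorted(lexicon.entries):
        entry = lexicon.entries[word]
        for variant in entry.variants:
            rows.append(
                {
                    "orthography": word,
                    "pronunciation": " ".join(variant),
                    "log10_frequency": repr(entry.log_frequency),
                    "is_function_word": int(entry.is_function_word),
                }
            )
    pd.DataFrame(rows, columns=["orthography", "pronunciation",
                                "log10_frequency", "is_function_word"]
                 ).to_csv(path, sep="\t", index=False)


def read_formants(path: str | Path) -> list[FormantMeasurement]:
    """Formant TSV: phone_index, category, f1_hz, f2_hz."""
    df = pd.read_csv(path, sep="\t")
    return [
        FormantMeasurement(
            phone_index=int(r.phone_index),
            category=str(r.category),
            f1_hz=float(r.f1_hz),
            f2_hz=float(r.f2_hz),
        )
        for r in df.itertuples()
    ]


def write_formants(formants: list[FormantMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "phone_index": [f.phone_index for f in formants],
            "category": [f.category for f in formants],
            "f1_hz": [f.f1_hz for f in formants],
            "f2_hz": [f.f2_hz for f in formants],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature table CSV
# ---------------------------------------------------------------------------

def write_feature_table(rows: list[FeatureRow], path: str | Path) -> None:
    records = []
    for row in rows:
        rec = {}
        for col in FEATURE_COLUMNS:
            val = getattr(row, col)
            rec[col] = "" if val is None else val
        records.append(rec)
    pd.DataFrame(records, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"dyad_id": str, "timepoint": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def feature_rows_to_frame(rows: list[FeatureRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{col: getattr(r, col) for col in FEATURE_COLUMNS} for r in rows],
        columns=FEATURE_COLUMNS,
    )


# ---------------------------------------------------------------------------
# joining phones to words
# ---------------------------------------------------------------------------

def attach_phones_to_words(
    phones: list[PhoneInterval],
    word_intervals: list[tuple[float, float, str]],
    tokens: list[WordToken],
    tol: float = DEFAULT_ADJACENCY_TOL,
    dyad_id: str = "unknown",
    timepoint: str = "24",
) -> SessionTranscript:
    """Assign each phone to the word interval containing its midpoint.

    ``word_intervals`` and ``tokens`` must be equal in count and order.
    Phones whose midpoint falls in no word interval stay unassigned and
    are counted in a log message.  ``tol`` is carried by callers that need
    phone adjacency; it is not used for the midpoint rule itself.
    """
    if len(word_intervals) != len(tokens):
        raise ValidationError(
            f"{len(word_intervals)} word intervals but {len(tokens)} tokens"
        )
    assigned = []
    n_orphans = 0
    for phone in phones:
        mid = phone.midpoint
        word_index = None
        for w_idx, (w_start, w_end, _) in enumerate(word_intervals):
            if w_start <= mid < w_end:
                word_index = w_idx
                break
        if word_index is None:
            n_orphans += 1
        assigned.append(replace(phone, word_index=word_index))
    if n_orphans:
        log.info("attach_phones_to_words: %d phones in no word interval",
                 n_orphans)
    return SessionTranscript(
        dyad_id=dyad_id, timepoint=timepoint, tokens=list(tokens),
        phones=assigned,
    )


def phones_adjacent(
    first: PhoneInterval, second: PhoneInterval,
    tol: float = DEFAULT_ADJACENCY_TOL,
) -> bool:
    """True when the boundary gap between consecutive phones is <= tol."""
    return abs(first.end - second.start) <= tol


# ---------------------------------------------------------------------------
# minimal CHAT import
# ---------------------------------------------------------------------------

_CHAT_STRIP = re.compile(r"[<>\[\](){}&+/!?.,;:\"^~]|@\S*")


def read_chat_main_tier(path: str | Path, speaker: str = "MOT") -> list[WordToken]:
    """Convenience importer for CHAT main tiers (``*MOT:`` lines only).

    Tokens are split on whitespace after stripping CHAT punctuation and
    event codes; dependent tiers and header lines are ignored.  Anything
    richer should be converted to the token-table TSV externally.
    """
    tokens: list[WordToken] = []
    utterance_index = 0
    token_index = 0
    prefix = f"*{speaker}:"
    for line in _read_text(path).splitlines():
        if not line.startswith(prefix):
            continue
        body = line[len(prefix):]
        body = re.sub(r"\x15\d+_\d+\x15", "", body)   # time alignment marks
        body = _CHAT_STRIP.sub(" ", body)
        words = [w for w in body.split() if re.search(r"[a-zA-Z']", w)]
        for word in words:
            tokens.append(
                WordToken(
                    orthography=word.strip("'-").lower() or word.lower(),
                    utterance_index=utterance_index,
                    token_index=token_index,
                )
            )
            token_index += 1
        if words:
            utterance_index += 1
    return tokens
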