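"""ARPAbet phoneme inventory and small symbol utilities.

Vowel symbols carry an optional stress digit (0 unstressed, 1 primary,
2 secondary); consonants never do.  All comparisons in the lexical and
acoustic batteries are segmental, i.e. performed after stripping stress.
"""

from __future__ import annotations

VOWELS: frozenset[str] = frozenset(
    "AA AE AH AO AW AY EH ER EY IH IY OW OY UH UW".split()
)
STOPS: frozenset[str] = frozenset("P B T D K G".split())
AFFRICATES: frozenset[str] = frozenset("CH JH".split())
FRICATIVES: frozenset[str] = frozenset("F V TH DH S Z SH ZH HH".split())
NASALS: frozenset[str] = frozenset("M N NG".split())
APPROXIMANTS: frozenset[str] = frozenset("L R W Y".split())

CONSONANTS: frozenset[str] = (
    STOPS | AFFRICATES | FRICATIVES | NASALS | APPROXIMANTS
)
INVENTORY: frozenset[str] = VOWELS | CONSONANTS

#: voiceless glottal fricative, excluded prevocalically from coarticulation
GLOTTAL_FRICATIVE = "HH"

# peripheral vowel categories used for vowel-space measures
PERIPHERAL_CATEGORY: dict[str, str] = {"IY": "i", "AA": "a", "UW": "u"}


def strip_stress(symbol: str) -> str:
    """Remove a trailing stress digit, if any: 'AE1' -> 'AE'."""
    if symbol and symbol[-1] in "012":
        return symbol[:-1]
    return symbol


def stress_of(symbol: str) -> int | None:
    """Stress digit of a vowel symbol, or None if it carries none."""
    if symbol and symbol[-1] in "012":
        return int(symbol[-1])
    return None


def is_vowel(symbol: str) -> bool:
    return strip_stress(symbol) in VOWELS


def is_stressed_vowel(symbol: str) -> bool:
    """Primary or secondary stress."""
    return is_vowel(symbol) and stress_of(symbol) in (1, 2)


def validate_symbol(symbol: str, inventory: frozenset[str] | set[str] = INVENTORY) -> str:
    """Return the segmental symbol, raising ValueError if unknown."""
    seg = strip_stress(symbol)
    if seg not in inventory:
        raise ValueError(f"unknown phoneme symbol {symbol!r}")
    return seg
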