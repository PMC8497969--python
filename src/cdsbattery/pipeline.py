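"""Session-to-FeatureRow assembly: run the lexical and acoustic batteries
over one session and collect the per-(dyad, timepoint) row."""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import numpy as np

from . import acoustic_battery as ab
from . import lexical_battery as lb
from .corpus_io import (
    DEFAULT_ADJACENCY_TOL,
    FeatureRow,
    Lexicon,
    SessionTranscript,
)

log = logging.getLogger("cdsbattery")


@dataclass
class BatteryConfig:
    """Thresholds and switches for one battery run (JSON-compatible)."""

    mattr_window: int = 10
    adjacency_tol: float = DEFAULT_ADJACENCY_TOL
    weighted_biphones: bool = False
    compute_lexical: bool = True
    compute_acoustic: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "BatteryConfig":
        return cls(**{k: v for k, v in d.items()
                      if k in cls.__dataclass_fields__})


def compute_feature_row(
    session: SessionTranscript,
    lexicon: Lexicon | lb.LexiconProfiler | None = None,
    spectra: dict[int, np.ndarray] | None = None,
    config: BatteryConfig | None = None,
) -> FeatureRow:
    """Run the full battery for one session.

    ``spectra`` maps phone index to a time-averaged Mel log-magnitude
    vector (from audio via the acoustic battery, or generated directly).
    Acoustic fields stay None when their inputs are absent.
    """
    cfg = config or BatteryConfig()
    row = FeatureRow(dyad_id=session.dyad_id, timepoint=session.timepoint)
    row._type_profiles = None          # populated when lexical stats run

    kept, _, ledger = lb.clean_word_inventory(session)
    if kept:
        row.n_types, row.n_tokens, row.ttr = lb.type_token_stats(kept)
        row.mattr, row.mattr_fallback = lb.mattr(kept, cfg.mattr_window)
    log.debug("%s/%s: cleaning ledger %s", session.dyad_id,
              session.timepoint, ledger)

    lex = None
    if lexicon is not None:
        lex = (lexicon.lexicon if isinstance(lexicon, lb.LexiconProfiler)
               else lexicon)
    if cfg.compute_lexical and lexicon is not None and kept:
        profiles, summaries = lb.lexical_profile(session, lexicon)
        for key, val in summaries.items():
            setattr(row, key, val)
        row._type_profiles = profiles

    if cfg.compute_acoustic:
        row.median_phone_duration_ms, durations = ab.duration_summary(session)
        row.n_duration_obs = len(durations)
        if spectra is not None:
            obs, _ = ab.coarticulation_distances(
                session, spectra, lex, cfg.adjacency_tol)
            if obs:
                row.median_coarticulation_distance = statistics.median(
                    o.distance for o in obs)
            row.n_coarticulation_obs = len(obs)
        if session.formants:
            normalized = ab.lobanov_normalize(session.formants)
            row.n_vowel_tokens = len(normalized)
            row.vowel_space_area_z, row.vowel_space_area_hz = (
                ab.vowel_space_area(normalized))
            per_type, _ = ab.vowel_dispersion(normalized, session)
            if per_type:
                row.median_dispersion = statistics.median(per_type.values())
    return row


def fill_unnested_counts(rows: list[FeatureRow]) -> None:
    """Populate n_long_words / n_low_freq_words across a corpus, in place.

    The split points are pooled medians per timepoint over all caregivers'
    profiled types (one observation per caregiver-type): word length uses
    an inclusive >= boundary, log frequency a strict < boundary.  Rows
    whose feature computation skipped the lexical battery are left null.
    """
    by_tp: dict[str, list[FeatureRow]] = {}
    for row in rows:
        if getattr(row, "_type_profiles", None):
            by_tp.setdefault(row.timepoint, []).append(row)
    for tp_rows in by_tp.values():
        lengths = {r.dyad_id: [p.length_phonemes
                               for p in r._type_profiles.values()
                               if p.in_lexicon]
                   for r in tp_rows}
        freqs = {r.dyad_id: [p.log_frequency
                             for p in r._type_profiles.values()
                             if p.in_lexicon]
                 for r in tp_rows}
        try:
            med_len = lb.pooled_median(lengths)
            med_freq = lb.pooled_median(freqs)
        except lb.UndefinedStatError:
            continue
        for r in tp_rows:
            r.n_long_words = lb.long_word_count(r._type_profiles, med_len)
            r.n_low_freq_words = lb.low_freq_count(r._type_profiles, med_freq)
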