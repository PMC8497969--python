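"""The four hyperarticulation measures of the battery.

* **Vowel space area** — shoelace area of the triangle spanned by the mean
  (F2, F1) positions of the peripheral vowels /i, a, u/, in both
  Lobanov-normalized and raw Hz space.
* **Vowel dispersion** — Euclidean distance of each /i, a, u/ token from
  the speaker-session median (F1, F2) in normalized space, averaged within
  word type so high-frequency words do not dominate.
* **Phone duration** — per-phone durations in ms, summarized by the median.
* **Coarticulation (spectral distance)** — Euclidean distance between the
  time-averaged Mel log-magnitude spectra of adjacent phones; *larger*
  distance means *less* coarticulation.  Pairs are excluded when the
  consonant is a prevocalic stop (utterance-initial closures cannot be
  delimited) or prevocalic /h/ (too weak a spectral signature), when the
  vowel is unstressed, when the word is a function word, or when either
  phone is flagged whispered/yelled/overlapping.

Formant values are consumed as inputs (no tracking is performed).  Mel
frame features can be computed from mono PCM WAV or supplied precomputed.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .arpabet import (
    GLOTTAL_FRICATIVE,
    STOPS,
    is_stressed_vowel,
    is_vowel,
    strip_stress,
)
from .corpus_io import (
    DEFAULT_ADJACENCY_TOL,
    FormantMeasurement,
    Lexicon,
    PhoneInterval,
    SessionTranscript,
)

log = logging.getLogger("cdsbattery")


# ---------------------------------------------------------------------------
# Mel frame features
# ---------------------------------------------------------------------------

@dataclass
class FrameConfig:
    """STFT/Mel analysis parameters.

    Defaults are standard speech-analysis settings: 25 ms Hann window,
    10 ms hop, 40 Mel bands spanning 0–8 kHz at a 16 kHz rate, log floor
    1e-10.  Spectral distances are comparable only within one configuration.
    """

    sample_rate: int = 16_000
    win_ms: float = 25.0
    hop_ms: float = 10.0
    n_mels: int = 40
    fmin: float = 0.0
    fmax: float = 8_000.0
    log_floor: float = 1e-10


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(cfg: FrameConfig, n_fft: int) -> np.ndarray:
    """Triangular Mel filterbank (n_mels x (n_fft//2 + 1)), HTK mel scale."""
    mel_pts = np.linspace(_hz_to_mel(cfg.fmin), _hz_to_mel(cfg.fmax),
                          cfg.n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0, cfg.sample_rate / 2, n_fft // 2 + 1)
    fb = np.zeros((cfg.n_mels, fft_freqs.size))
    for m in range(cfg.n_mels):
        lo, mid, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - mid, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def filterbank_center_freqs(cfg: FrameConfig) -> np.ndarray:
    """Center frequency (Hz) of each Mel band."""
    mel_pts = np.linspace(_hz_to_mel(cfg.fmin), _hz_to_mel(cfg.fmax),
                          cfg.n_mels + 2)
    return _mel_to_hz(mel_pts)[1:-1]


def mel_frame_features(
    wav: np.ndarray, sr: int, cfg: FrameConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-level Mel log-magnitude features of a mono waveform.

    Returns ``(frame_times, features)`` with features shaped
    (n_frames, n_mels) and frame_times at frame centers (seconds).
    """
    cfg = cfg or FrameConfig()
    wav = np.asarray(wav, dtype=float)
    if wav.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    if wav.size == 0:
        raise ValueError("empty audio")
    peak = np.max(np.abs(wav))
    # clipping leaves runs of consecutive samples pinned at full scale;
    # clean periodic signals touch their peak only at isolated samples
    if peak >= 0.999:
        at_peak = np.abs(wav) >= 0.9999 * peak
        if wav.size > 1 and np.mean(at_peak[1:] & at_peak[:-1]) > 0.005:
            raise ValueError(
                "audio appears clipped (plateaus at full scale); spectral "
                "distances would be distorted")
    if sr != cfg.sample_rate:
        from math import gcd
        g = gcd(int(cfg.sample_rate), int(sr))
        wav = signal.resample_poly(wav, cfg.sample_rate // g, sr // g)
        sr = cfg.sample_rate
    nperseg = int(round(cfg.win_ms * 1e-3 * sr))
    hop = int(round(cfg.hop_ms * 1e-3 * sr))
    freqs, times, stft = signal.stft(
        wav, fs=sr, window="hann", nperseg=nperseg,
        noverlap=nperseg - hop, boundary=None, padded=False,
    )
    mag = np.abs(stft)                       # (n_bins, n_frames)
    fb = mel_filterbank(cfg, nperseg)
    mel = fb @ mag                           # (n_mels, n_frames)
    feats = np.log(mel + cfg.log_floor).T
    return times, feats


def load_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV file, scaling integer samples to [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV is supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return np.asarray(data, dtype=float), int(sr)


# ---------------------------------------------------------------------------
# per-phone spectra and distances
# ---------------------------------------------------------------------------

@dataclass
class PhoneSpectrum:
    phone_index: int
    mel_vector: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("PhoneSpectrum needs >= 1 averaged frame")


def phone_mean_spectrum(
    frame_times: np.ndarray,
    frames: np.ndarray,
    phone: PhoneInterval,
    phone_index: int = 0,
) -> PhoneSpectrum | None:
    """Average the Mel frames whose centers fall inside the phone interval.

    Returns None (caller counts the drop) when no frame center lands in
    ``[start, end)``.
    """
    mask = (frame_times >= phone.start) & (frame_times < phone.end)
    n = int(mask.sum())
    if n == 0:
        return None
    return PhoneSpectrum(phone_index, frames[mask].mean(axis=0), n)


def spectral_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """Euclidean distance between two equal-length averaged spectra."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"spectrum shapes differ: {s1.shape} vs {s2.shape}")
    return float(np.linalg.norm(s1 - s2))


@dataclass
class CoarticulationObservation:
    first_index: int
    second_index: int
    word_index: int | None
    distance: float | None = None


def eligible_pairs(
    session: SessionTranscript,
    lexicon: Lexicon | None = None,
    tol: float = DEFAULT_ADJACENCY_TOL,
) -> tuple[list[CoarticulationObservation], dict[str, int]]:
    """Adjacent CV / VC phone pairs eligible for the coarticulation measure.

    Returns the candidate observations (distances unfilled) and an
    exclusion ledger; every rejected adjacent CV/VC pair lands in exactly
    one ledger category (first matching rule wins, in the order below).
    """
    ledger = {
        "not_adjacent": 0, "not_cv_vc": 0, "flagged": 0,
        "stop_before_vowel": 0, "h_before_vowel": 0, "unstressed_vowel": 0,
        "function_word": 0, "eligible": 0,
    }
    out: list[CoarticulationObservation] = []
    phones = session.phones
    cls = [_label_class(p.label) for p in phones]
    for i in range(len(phones) - 1):
        a, b = phones[i], phones[i + 1]
        if abs(a.end - b.start) > tol:
            ledger["not_adjacent"] += 1
            continue
        (a_vowel, a_stressed, a_seg), (b_vowel, b_stressed, b_seg) = \
            cls[i], cls[i + 1]
        if a_vowel == b_vowel:          # CC or VV
            ledger["not_cv_vc"] += 1
            continue
        if a.flags or b.flags:
            ledger["flagged"] += 1
            continue
        prevocalic = not a_vowel        # consonant precedes the vowel
        cons_seg = b_seg if a_vowel else a_seg
        if prevocalic and cons_seg in STOPS:
            ledger["stop_before_vowel"] += 1
            continue
        if prevocalic and cons_seg == GLOTTAL_FRICATIVE:
            ledger["h_before_vowel"] += 1
            continue
        vowel = a if a_vowel else b
        vowel_stressed = a_stressed if a_vowel else b_stressed
        if not vowel_stressed:
            ledger["unstressed_vowel"] += 1
            continue
        # content-word requirement, judged at the vowel's word; the VC
        # member may cross a syllable (or word-internal) boundary
        word_index = vowel.word_index
        if lexicon is not None and word_index is not None:
            entry = lexicon.get(session.tokens[word_index].orthography)
            if entry is not None and entry.is_function_word:
                ledger["function_word"] += 1
                continue
        ledger["eligible"] += 1
        out.append(CoarticulationObservation(i, i + 1, word_index))
    return out, ledger


def coarticulation_distances(
    session: SessionTranscript,
    spectra: "dict[int, np.ndarray] | np.ndarray",
    lexicon: Lexicon | None = None,
    tol: float = DEFAULT_ADJACENCY_TOL,
) -> tuple[list[CoarticulationObservation], dict[str, int]]:
    """Fill spectral distances for the eligible pairs that have spectra.

    ``spectra`` is either a mapping from phone index to averaged spectrum
    or a dense (n_phones, n_mels) matrix covering every phone.
    """
    candidates, ledger = eligible_pairs(session, lexicon, tol)
    ledger["missing_spectrum"] = 0
    if isinstance(spectra, np.ndarray):
        kept = candidates
        s1 = spectra[[o.first_index for o in kept]]
        s2 = spectra[[o.second_index for o in kept]]
    else:
        kept, missing = [], 0
        for obs in candidates:
            if obs.first_index in spectra and obs.second_index in spectra:
                kept.append(obs)
            else:
                missing += 1
        ledger["missing_spectrum"] = missing
        ledger["eligible"] -= missing
        if not kept:
            return [], ledger
        s1 = np.array([spectra[o.first_index] for o in kept])
        s2 = np.array([spectra[o.second_index] for o in kept])
    if len(kept) == 0:
        return [], ledger
    dists = np.linalg.norm(s1 - s2, axis=1)
    return (
        [replace(o, distance=float(d)) for o, d in zip(kept, dists)],
        ledger,
    )


@lru_cache(maxsize=None)
def _label_class(label: str) -> tuple[bool, bool, str]:
    """(is_vowel, is_stressed_vowel, segmental symbol) for a phone label."""
    return (is_vowel(label), is_stressed_vowel(label), strip_stress(label))


# ---------------------------------------------------------------------------
# formant-based measures
# ---------------------------------------------------------------------------

def lobanov_normalize(
    formants: list[FormantMeasurement],
) -> list[FormantMeasurement]:
    """Per-speaker-session z-scoring of F1 and F2 over all vowel tokens.

    With fewer than two tokens the z fields stay None and raw Hz values are
    retained.  Normalization is invariant to any affine rescaling of the
    input Hz values.
    """
    if len(formants) < 2:
        return [replace(f) for f in formants]
    f1 = np.array([f.f1_hz for f in formants])
    f2 = np.array([f.f2_hz for f in formants])
    out = []
    for f, z1, z2 in zip(formants, _zscore(f1), _zscore(f2)):
        out.append(replace(f, f1_z=float(z1), f2_z=float(z2)))
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _shoelace(points: list[tuple[float, float]]) -> float:
    (x1, y1), (x2, y2), (x3, y3) = points
    return 0.5 * abs(x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))


def vowel_space_area(
    formants: list[FormantMeasurement],
) -> tuple[float | None, float | None]:
    """(area_z, area_hz): triangle area over the /i, a, u/ category means.

    Vertices are the per-category mean (F2, F1) positions.  Either area is
    None when a peripheral category is unattested (or, for area_z,
    when normalization was not possible).
    """
    area = {}
    for space in ("z", "hz"):
        pts = []
        ok = True
        for cat in ("i", "a", "u"):
            fs = [f for f in formants if f.category == cat]
            if not fs:
                log.info("vowel_space_area: no /%s/ tokens", cat)
                ok = False
                break
            if space == "z":
                if any(f.f1_z is None for f in fs):
                    ok = False
                    break
                pts.append((float(np.mean([f.f2_z for f in fs])),
                            float(np.mean([f.f1_z for f in fs]))))
            else:
                pts.append((float(np.mean([f.f2_hz for f in fs])),
                            float(np.mean([f.f1_hz for f in fs]))))
        area[space] = _shoelace(pts) if ok else None
    return area["z"], area["hz"]


def vowel_dispersion(
    formants: list[FormantMeasurement],
    session: SessionTranscript | None = None,
) -> tuple[dict[str, float], list[float]]:
    """Distance of each vowel token from the speaker-session median.

    The median (F1_z, F2_z) is taken over all measured vowel tokens of the
    session.  Returns ``(per_type, per_token)`` where per_type averages the
    token dispersions within word type (each type contributes once); when
    no session is given, types cannot be resolved and per_type groups all
    tokens under ``"*"``.
    """
    measured = [f for f in formants if f.f1_z is not None]
    if not measured:
        return {}, []
    med1 = statistics.median(f.f1_z for f in measured)
    med2 = statistics.median(f.f2_z for f in measured)
    per_token = [
        float(np.hypot(f.f1_z - med1, f.f2_z - med2)) for f in measured
    ]
    groups: dict[str, list[float]] = {}
    for f, d in zip(measured, per_token):
        word = "*"
        if session is not None:
            wi = session.phones[f.phone_index].word_index
            if wi is not None:
                word = session.tokens[wi].orthography
        groups.setdefault(word, []).append(d)
    per_type = {w: sum(v) / len(v) for w, v in groups.items()}
    return per_type, per_token


def duration_summary(
    session: SessionTranscript,
) -> tuple[float | None, list[float]]:
    """Median phone duration (ms) over phones passing the flag filter."""
    durations = [
        p.duration * 1000.0 for p in session.phones if not p.flags
    ]
    if not durations:
        return None, []
    return statistics.median(durations), durations
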