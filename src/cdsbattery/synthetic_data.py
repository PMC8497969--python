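"""Synthetic caregiver-child corpora with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, per dyad and timepoint:

* a Zipfian pronouncing lexicon with pronunciation variants and a
  function-word stratum;
* play-session transcripts whose token counts, lexical diversity (MATTR),
  and phone durations are steered to per-timepoint targets;
* per-phone Mel spectra produced directly (no audio synthesis) by a
  coarticulation carryover model: the realized spectrum of phone *i* is
  ``(1-κ)·prototype_i + κ·realized_{i-1}`` plus Gaussian noise, so larger
  κ yields smaller adjacent spectral distances (more coarticulation) and
  κ = 1 collapses all distances to the noise floor;
* midpoint F1/F2 formant draws for the peripheral vowels /i, a, u/;
* child outcomes (nonword-repetition accuracy, expressive vocabulary)
  generated from declared linear models over standardized battery
  features, with demographic covariates.

Two internal calibrations keep the emergent session statistics on target:
a temperature on the Zipf sampling weights is solved (bisection on the
closed-form expected 10-token-window type count) so the expected MATTR
matches the timepoint target, and the spectral prototype scale is solved
against pilot sessions so the median eligible-pair distance matches the
timepoint target at its κ.

Randomness: one RNG stream per (replicate, dyad, timepoint), derived from
the master seed via ``numpy.random.SeedSequence`` spawn keys, so the same
seed reproduces the corpus byte-for-byte and any session can be
regenerated in isolation.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acoustic_battery as ab
from . import lexical_battery as lb
from .arpabet import CONSONANTS, PERIPHERAL_CATEGORY, VOWELS
from .corpus_io import (
    FormantMeasurement,
    Lexicon,
    LexiconEntry,
    PhoneInterval,
    SessionTranscript,
    WordToken,
)
from .pipeline import BatteryConfig, compute_feature_row

log = logging.getLogger("cdsbattery")

# fixed internal entropy for structures shared across master seeds
# (spectral prototypes, calibration pilots); corpus randomness proper is
# driven by GeneratorConfig.seed
_STRUCTURE_SEED = 0xC0FFEE


@dataclass
class TimepointTargets:
    """Per-timepoint session targets (None = measure not collected)."""

    types_mean: float
    types_sd: float
    tokens_mean: float
    tokens_sd: float
    mattr: float
    phone_duration_ms: float | None      # target median duration
    kappa: float | None                  # coarticulation blend in [0, 1]
    spectral_distance: float | None      # target median eligible-pair distance
    vowel_expansion: float = 1.0         # radial scaling of vowel means

    def __post_init__(self) -> None:
        if self.kappa is not None and not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        for name in ("types_sd", "tokens_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def default_targets() -> dict[str, TimepointTargets]:
    """Session targets for the four sampled ages.

    Token/type counts, MATTR, phone duration and spectral distance follow
    the descriptive statistics of the longitudinal corpus the battery is
    designed for; acoustics were not collected at 18 months, hence the
    Nones there.  The carryover coefficients κ are chosen so that older
    children hear less coarticulated speech (larger spectral distance),
    matching the observed direction of change.
    """
    return {
        "7": TimepointTargets(246.63, 67.22, 873.38, 313.16, 0.88,
                              90.21, 0.50, 6.89, 1.00),
        "10-11": TimepointTargets(237.76, 53.56, 864.88, 277.02, 0.87,
                                  90.02, 0.52, 6.91, 0.98),
        "18": TimepointTargets(261.28, 59.54, 1012.91, 302.73, 0.89,
                               None, None, None, 1.0),
        "24": TimepointTargets(292.68, 54.73, 1247.22, 346.29, 0.91,
                               83.45, 0.45, 7.37, 1.08),
    }


@dataclass
class GeneratorConfig:
    seed: int
    n_dyads: int = 84
    timepoints: tuple[str, ...] = ("7", "10-11", "18", "24")
    targets: dict[str, TimepointTargets] = field(default_factory=default_targets)
    lexicon_size: int = 1000
    zipf_exponent: float = 1.0
    #: shifted-Poisson word-length model: length = 1 + Poisson(lambda)
    length_lambda: float = 3.0
    max_length: int = 9
    variant_rate: float = 0.10
    function_word_fraction: float = 0.05
    mean_utterance_length: float = 5.0
    duration_sigma: float = 0.55         # lognormal shape for phone durations
    n_mels: int = 40
    spectrum_noise_sd: float = 0.3
    vowel_means_hz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"i": (310.0, 2790.0),
                                 "a": (850.0, 1220.0),
                                 "u": (370.0, 950.0)})
    vowel_sds_hz: tuple[float, float] = (60.0, 150.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        """Build from a JSON-compatible mapping; per-timepoint targets may
        be plain dicts."""
        d = dict(d)
        if "targets" in d:
            d["targets"] = {
                tp: (tgt if isinstance(tgt, TimepointTargets)
                     else TimepointTargets(**tgt))
                for tp, tgt in d["targets"].items()
            }
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if "vowel_means_hz" in d:
            d["vowel_means_hz"] = {k: tuple(v)
                                   for k, v in d["vowel_means_hz"].items()}
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class OutcomeModelConfig:
    """Declared linear outcome models over standardized battery features.

    Continuous features are z-scored across dyads before the coefficients
    apply, so each coefficient is an effect per feature SD in outcome
    units; the binary ``gender_male`` coefficient is a direct offset.
    Nonword-repetition accuracy uses an identity link clipped to [0, 1].
    Default magnitudes mirror the observed outcome scales (accuracy
    0.65 ± 0.16; expressive vocabulary 355.94 ± 150.32) with a planted
    negative coarticulation→NWR effect of t ≈ 3 at 84 dyads.
    """

    nwr_coefficients: dict[str, float] = field(default_factory=lambda: {
        "median_coarticulation_distance": -0.05,
        "median_phone_duration_ms": -0.01,
        "maternal_ed": 0.02,
        "vocab_18": 0.02,
    })
    vocab_coefficients: dict[str, float] = field(default_factory=lambda: {
        "n_types": 65.0,
        "maternal_ed": 25.0,
        "gender_male": -50.0,
    })
    nwr_intercept: float = 0.65
    nwr_noise_sd: float = 0.15
    vocab_intercept: float = 355.94
    vocab_noise_sd: float = 140.0

    def __post_init__(self) -> None:
        if self.nwr_noise_sd <= 0 or self.vocab_noise_sd <= 0:
            raise ValueError("noise sds must be > 0")


# ---------------------------------------------------------------------------
# lexicon generation
# ---------------------------------------------------------------------------

def gen_lexicon(config: GeneratorConfig,
                rng: np.random.Generator | None = None) -> Lexicon:
    """A Zipfian pronouncing lexicon over the ARPAbet inventory.

    Ranked log10 frequencies follow ``A - s·log10(rank)`` (slope −s on
    log-log ranks) with small jitter; the top frequency stratum is flagged
    as function words; ~10% of entries carry a second pronunciation
    variant differing in one segment.
    """
    rng = rng or np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    consonants = sorted(CONSONANTS)
    vowels = sorted(VOWELS)
    lex = Lexicon()
    n_function = max(1, int(round(config.function_word_fraction
                                  * config.lexicon_size)))
    for rank in range(1, config.lexicon_size + 1):
        length = 1 + int(rng.poisson(config.length_lambda))
        length = min(length, config.max_length)
        pron = _random_pron(rng, length, consonants, vowels)
        log_freq = (7.0 - config.zipf_exponent * math.log10(rank)
                    + float(rng.normal(0.0, 0.05)))
        variants = [pron]
        if rng.random() < config.variant_rate and length >= 2:
            variants.append(_perturb_pron(rng, pron, consonants, vowels))
        lex.add(LexiconEntry(
            orthography=f"w{rank:05d}",
            variants=variants,
            log_frequency=log_freq,
            is_function_word=rank <= n_function,
        ))
    return lex


def _random_pron(rng, length, consonants, vowels) -> tuple[str, ...]:
    # loosely CV-alternating; exactly one primary-stressed vowel
    segs: list[str] = []
    want_vowel = bool(rng.random() < 0.5)
    for _ in range(length):
        if want_vowel:
            segs.append(str(rng.choice(vowels)))
        else:
            segs.append(str(rng.choice(consonants)))
        want_vowel = not want_vowel if rng.random() < 0.85 else want_vowel
    vowel_positions = [i for i, s in enumerate(segs) if s in VOWELS]
    if not vowel_positions:
        i = int(rng.integers(len(segs)))
        segs[i] = str(rng.choice(vowels))
        vowel_positions = [i]
    primary = int(rng.choice(vowel_positions))
    out = []
    for i, s in enumerate(segs):
        if s in VOWELS:
            out.append(s + ("1" if i == primary else "0"))
        else:
            out.append(s)
    return tuple(out)


def _perturb_pron(rng, pron, consonants, vowels) -> tuple[str, ...]:
    segs = list(pron)
    i = int(rng.integers(len(segs)))
    if segs[i][:-1] in VOWELS or segs[i] in VOWELS:
        stress = segs[i][-1] if segs[i][-1] in "012" else "0"
        segs[i] = str(rng.choice(vowels)) + stress
    else:
        segs[i] = str(rng.choice(consonants))
    return tuple(segs)


# ---------------------------------------------------------------------------
# the corpus generator
# ---------------------------------------------------------------------------

class CorpusGenerator:
    """Generates sessions, spectra and formants for one configuration.

    Heavy shared state (the lexicon, spectral prototypes, per-timepoint
    calibrations) is built once and reused across sessions and replicates.
    """

    def __init__(self, config: GeneratorConfig,
                 lexicon: Lexicon | None = None):
        self.config = config
        self.lexicon = lexicon if lexicon is not None else gen_lexicon(config)
        self._symbols = sorted(self.lexicon.inventory)
        self._sym_index = {s: i for i, s in enumerate(self._symbols)}
        struct_rng = np.random.default_rng(_STRUCTURE_SEED)
        # unit-scale spectral prototypes, one row per segmental symbol
        self._prototypes = struct_rng.normal(
            0.0, 1.0, (len(self._symbols), config.n_mels))
        self._words = sorted(self.lexicon.entries)
        self._prons = [self.lexicon.entries[w].variants[0]
                       for w in self._words]
        self._base_weights = np.array(
            [10.0 ** self.lexicon.entries[w].log_frequency
             for w in self._words])
        self._base_weights /= self._base_weights.sum()
        self._theta: dict[str, float] = {}
        self._spectral_scale: dict[str, float] = {}
        #: per-timepoint spectral-calibration diagnostics
        self.calibration_info: dict[str, dict[str, float]] = {}

    # -- calibration -------------------------------------------------------

    def _weights(self, timepoint: str) -> np.ndarray:
        theta = self._calibrate_theta(timepoint)
        w = self._base_weights ** theta
        return w / w.sum()

    def _calibrate_theta(self, timepoint: str) -> float:
        """Temperature on Zipf weights so expected MATTR hits the target.

        For i.i.d. token draws with probabilities q, the expected distinct
        count in a w-token window is Σ(1 − (1 − q_i)^w), giving a closed
        form for E[MATTR] that is monotone in the temperature.
        """
        if timepoint in self._theta:
            return self._theta[timepoint]
        target = self.config.targets[timepoint].mattr
        w = 10  # battery default window

        def expected_mattr(theta: float) -> float:
            q = self._base_weights ** theta
            q /= q.sum()
            return float(np.sum(1.0 - (1.0 - q) ** w) / w)

        lo, hi = 0.05, 4.0
        if not (expected_mattr(hi) <= target <= expected_mattr(lo)):
            raise ValueError(
                f"MATTR target {target} unreachable with this lexicon "
                f"(range [{expected_mattr(hi):.3f}, {expected_mattr(lo):.3f}])")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if expected_mattr(mid) > target:
                lo = mid
            else:
                hi = mid
        self._theta[timepoint] = 0.5 * (lo + hi)
        return self._theta[timepoint]

    N_PILOT_SESSIONS = 150

    def _calibrate_spectral_scale(self, timepoint: str) -> float:
        """Prototype scale so the per-session median eligible-pair distance
        hits the target in expectation.

        Pilot sessions are generated at unit scale with the chain and the
        noise kept separate; for a pair the distance at scale s is
        √(a s² + b s + c), so the mean over pilot sessions of the
        session-median distance is an explicit function of s, solved by
        bisection.  Calibrating on the session-median statistic itself
        (rather than the pooled-pair median) absorbs the small-sample skew
        of a median over a few hundred pairs.
        """
        if timepoint in self._spectral_scale:
            return self._spectral_scale[timepoint]
        tgt = self.config.targets[timepoint]
        if tgt.kappa is None or tgt.spectral_distance is None:
            raise ValueError(f"no acoustic targets at timepoint {timepoint}")
        tp_index = list(self.config.targets).index(timepoint)
        pilot_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=_STRUCTURE_SEED,
                                   spawn_key=(1, tp_index)))
        per_session: list[np.ndarray] = []
        for _ in range(self.N_PILOT_SESSIONS):
            built = self._build_session("pilot", timepoint, pilot_rng)
            session, chain, noise = built.session, built.chain, built.noise
            pairs, _ = ab.eligible_pairs(session, self.lexicon)
            if not pairs:
                continue
            i1 = [o.first_index for o in pairs]
            i2 = [o.second_index for o in pairs]
            du = chain[i2] - chain[i1]
            de = noise[i2] - noise[i1]
            per_session.append(np.column_stack([
                np.einsum("ij,ij->i", du, du),
                2.0 * np.einsum("ij,ij->i", du, de),
                np.einsum("ij,ij->i", de, de),
            ]))
        if not per_session:
            raise RuntimeError("pilot sessions produced no eligible pairs")

        def mean_session_median(s: float) -> float:
            meds = [
                float(np.median(np.sqrt(np.clip(
                    arr[:, 0] * s * s + arr[:, 1] * s + arr[:, 2], 0, None))))
                for arr in per_session
            ]
            return float(np.mean(meds))

        lo, hi = 1e-6, 100.0
        while mean_session_median(hi) < tgt.spectral_distance:
            hi *= 2
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mean_session_median(mid) < tgt.spectral_distance:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)
        meds = np.array([
            float(np.median(np.sqrt(np.clip(
                arr[:, 0] * scale ** 2 + arr[:, 1] * scale + arr[:, 2],
                0, None))))
            for arr in per_session
        ])
        self.calibration_info[timepoint] = {
            "n_pilot_sessions": len(per_session),
            "session_median_sd": float(meds.std(ddof=1)),
            "calibration_se": float(meds.std(ddof=1)
                                    / np.sqrt(len(per_session))),
        }
        self._spectral_scale[timepoint] = scale
        return scale

    # -- session generation ------------------------------------------------

    def session_rng(self, dyad_index: int, timepoint: str,
                    replicate: int = 0) -> np.random.Generator:
        tp_index = list(self.config.targets).index(timepoint)
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.config.seed,
            spawn_key=(replicate, dyad_index, tp_index)))

    def gen_session(
        self, dyad_index: int, timepoint: str, replicate: int = 0,
        kappa: float | None = None,
    ) -> tuple[SessionTranscript, np.ndarray | None]:
        """One session plus its per-phone Mel spectra.

        The spectra come back as a dense (n_phones, n_mels) matrix (None
        at timepoints without acoustics).  ``kappa`` overrides the
        timepoint's carryover coefficient (used by the monotonicity
        experiments); the spectral scale stays the one calibrated for the
        timepoint's own κ so distances remain comparable across κ values.
        """
        rng = self.session_rng(dyad_index, timepoint, replicate)
        tgt = self.config.targets[timepoint]
        scale = None
        if tgt.kappa is not None:
            scale = self._calibrate_spectral_scale(timepoint)
        built = self._build_session(
            f"d{dyad_index:03d}", timepoint, rng, kappa_override=kappa)
        if built.chain is None or scale is None:
            return built.session, None
        return built.session, scale * built.chain + built.noise

    def _build_session(self, dyad_id: str, timepoint: str, rng,
                       kappa_override: float | None = None) -> "_BuiltSession":
        cfg = self.config
        tgt = cfg.targets[timepoint]
        n_tokens = max(10, int(round(rng.normal(tgt.tokens_mean,
                                                tgt.tokens_sd))))
        weights = self._weights(timepoint)
        word_ids = rng.choice(len(self._words), size=n_tokens, p=weights)

        # utterance segmentation: geometric lengths
        p_break = 1.0 / cfg.mean_utterance_length
        breaks = rng.random(n_tokens) < p_break
        breaks[0] = False
        utterance_index = np.cumsum(breaks)

        tokens: list[WordToken] = []
        phone_labels: list[str] = []
        phone_word: list[int] = []
        for t_idx, w_id in enumerate(word_ids):
            tokens.append(WordToken(
                orthography=self._words[w_id],
                utterance_index=int(utterance_index[t_idx]),
                token_index=t_idx,
            ))
            for sym in self._prons[w_id]:
                phone_labels.append(sym)
                phone_word.append(t_idx)
        n_phones = len(phone_labels)

        med_s = (tgt.phone_duration_ms or 85.0) / 1000.0
        durations = rng.lognormal(math.log(med_s), cfg.duration_sigma,
                                  n_phones)
        durations = np.maximum(durations, 0.015)
        # contiguous within an utterance; 200 ms pause between utterances
        gaps = np.zeros(n_phones)
        utt_of_phone = utterance_index[np.array(phone_word)]
        gaps[1:] = np.where(np.diff(utt_of_phone) > 0, 0.2, 0.0)
        ends = np.cumsum(durations + gaps)
        starts = ends - durations

        phones = [
            PhoneInterval(label=phone_labels[i], start=float(starts[i]),
                          end=float(ends[i]), word_index=phone_word[i])
            for i in range(n_phones)
        ]
        formants = self._gen_formants(rng, phones, tgt)
        session = SessionTranscript(
            dyad_id=dyad_id, timepoint=timepoint,
            tokens=tokens, phones=phones, formants=formants)

        chain = noise = None
        kappa = kappa_override if kappa_override is not None else tgt.kappa
        if kappa is not None:
            seg_ids = np.array([self._sym_index[s]
                                for s in map(_seg, phone_labels)])
            protos = self._prototypes[seg_ids]
            chain = _carryover(protos, kappa)
            noise = rng.normal(0.0, cfg.spectrum_noise_sd, protos.shape)
        return _BuiltSession(session, chain, noise)

    def _gen_formants(self, rng, phones, tgt) -> list[FormantMeasurement]:
        cfg = self.config
        centroid = np.mean([cfg.vowel_means_hz[c] for c in "iau"], axis=0)
        out = []
        for idx, ph in enumerate(phones):
            seg = _seg(ph.label)
            cat = PERIPHERAL_CATEGORY.get(seg)
            if cat is None:
                continue
            mean = centroid + tgt.vowel_expansion * (
                np.array(cfg.vowel_means_hz[cat]) - centroid)
            f1 = max(150.0, float(rng.normal(mean[0], cfg.vowel_sds_hz[0])))
            f2 = float(rng.normal(mean[1], cfg.vowel_sds_hz[1]))
            f2 = max(f2, f1 + 100.0)
            out.append(FormantMeasurement(idx, cat, f1, f2))
        return out

    # -- corpus-level helpers ---------------------------------------------

    def gen_corpus_features(
        self, timepoint: str, replicate: int = 0,
        battery_config: BatteryConfig | None = None,
        profiler: "lb.LexiconProfiler | None" = None,
    ) -> pd.DataFrame:
        """Generate all dyads at one timepoint and run the battery."""
        from .corpus_io import feature_rows_to_frame
        rows = []
        for d in range(self.config.n_dyads):
            session, spectra = self.gen_session(d, timepoint, replicate)
            rows.append(compute_feature_row(
                session, profiler if profiler is not None else self.lexicon,
                spectra, battery_config))
        return feature_rows_to_frame(rows)


def _seg(symbol: str) -> str:
    return symbol[:-1] if symbol and symbol[-1] in "012" else symbol


def _carryover(protos: np.ndarray, kappa: float) -> np.ndarray:
    """First-order recursive blend r_i = (1-κ)·p_i + κ·r_{i-1}, r_0 = p_0."""
    from scipy.signal import lfilter
    if protos.shape[0] == 0:
        return protos
    if kappa >= 1.0:
        return np.repeat(protos[:1], protos.shape[0], axis=0)
    out = lfilter([1.0 - kappa], [1.0, -kappa], protos, axis=0)
    # make the first phone its own prototype (no left context)
    out += (kappa ** np.arange(1, protos.shape[0] + 1))[:, None] * protos[0]
    return out


@dataclass
class _BuiltSession:
    session: SessionTranscript
    chain: np.ndarray | None
    noise: np.ndarray | None


def render_tone_wav(
    session: SessionTranscript, sample_rate: int = 16_000,
) -> np.ndarray:
    """Render a session as audio of per-phone tone complexes.

    Each phoneme symbol gets a distinct fundamental with two harmonics —
    a crude formant-like spectrum, enough to exercise the WAV → STFT →
    Mel → phone-mean-spectrum path (adjacent distinct phones then have
    nonzero spectral distance).  Not a speech synthesizer.
    """
    if not session.phones:
        return np.zeros(sample_rate // 10)
    symbols = sorted({_seg(p.label) for p in session.phones})
    f0 = {s: 180.0 + 35.0 * i for i, s in enumerate(symbols)}
    n = int(np.ceil(session.phones[-1].end * sample_rate)) + 1
    wav = np.zeros(n)
    t = np.arange(n) / sample_rate
    for phone in session.phones:
        lo = int(phone.start * sample_rate)
        hi = int(phone.end * sample_rate)
        seg_t = t[lo:hi]
        base = f0[_seg(phone.label)]
        tone = sum(0.3 / k * np.sin(2 * np.pi * k * base * seg_t)
                   for k in (1, 2, 3))
        wav[lo:hi] += tone
    return 0.8 * wav / max(np.max(np.abs(wav)), 1e-9)


# ---------------------------------------------------------------------------
# outcome generation
# ---------------------------------------------------------------------------

def gen_outcomes(
    features: pd.DataFrame,
    config: OutcomeModelConfig,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Child outcomes per dyad from the declared linear models.

    ``features`` is a per-dyad frame (battery output at the relevant
    timepoint).  Adds demographics (maternal education in years, child
    gender, earlier vocabulary sizes), then NWR accuracy (clipped to
    [0, 1]; the clipping rate is reported and a warning is raised above
    10%) and expressive vocabulary at 24 months.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = len(features)
    out = pd.DataFrame({"dyad_id": features["dyad_id"].to_numpy()})
    out["maternal_ed"] = rng.integers(12, 21, n).astype(float)
    out["gender_male"] = (rng.random(n) < 35 / 84).astype(float)
    out["vocab_18"] = np.clip(rng.normal(112.03, 108.6, n), 2, None)
    out["vocab_11"] = np.clip(rng.normal(62.49, 59.89, n), 0, None)

    def _standardized(name: str) -> np.ndarray:
        if name in out.columns:
            x = out[name].to_numpy(dtype=float)
        elif name in features.columns:
            x = features[name].to_numpy(dtype=float)
        else:
            raise KeyError(f"outcome model references unknown feature {name!r}")
        if name == "gender_male":
            return x
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"feature {name!r} has no variation")
        return (x - np.nanmean(x)) / sd

    def _predict(coeffs: dict[str, float], intercept: float,
                 noise_sd: float) -> np.ndarray:
        eta = np.full(n, intercept, dtype=float)
        for name, beta in coeffs.items():
            eta += beta * _standardized(name)
        return eta + rng.normal(0.0, noise_sd, n)

    nwr_raw = _predict(config.nwr_coefficients, config.nwr_intercept,
                       config.nwr_noise_sd)
    nwr = np.clip(nwr_raw, 0.0, 1.0)
    clip_rate = float(np.mean(nwr != nwr_raw))
    if clip_rate > 0.10:
        log.warning("gen_outcomes: %.1f%% of NWR accuracies clipped — "
                    "effect sizes inconsistent with the [0, 1] scale",
                    100 * clip_rate)
    out["nwr_accuracy"] = nwr
    out["vocab_24"] = np.clip(
        _predict(config.vocab_coefficients, config.vocab_intercept,
                 config.vocab_noise_sd), 0, None)
    out.attrs["nwr_clip_rate"] = clip_rate
    return out


# ---------------------------------------------------------------------------
# end-to-end recovery experiments
# ---------------------------------------------------------------------------

def scaled_config(seed: int, n_dyads: int = 84,
                  tokens: float | None = None,
                  lexicon_size: int = 600) -> GeneratorConfig:
    """A reduced-size configuration for repeated-replicate experiments.

    Only the session length and lexicon size shrink; targets keep their
    default ratios so the emergent statistics stay on the same scales.
    """
    targets = default_targets()
    if tokens is not None:
        for tgt in targets.values():
            ratio = tokens / tgt.tokens_mean
            tgt.tokens_mean = tokens
            tgt.tokens_sd = max(tgt.tokens_sd * ratio, 10.0)
            tgt.types_mean *= ratio
            tgt.types_sd *= ratio
    return GeneratorConfig(seed=seed, n_dyads=n_dyads, targets=targets,
                           lexicon_size=lexicon_size)


def recovery_experiment(
    config: GeneratorConfig,
    n_reps: int,
    seed: int,
    outcome_config: OutcomeModelConfig | None = None,
    timepoint: str = "10-11",
    alpha: float = 0.05,
) -> dict:
    """End-to-end generate → battery → analyze parameter recovery.

    Per replicate: a fresh corpus at one timepoint is run through the
    battery; outcomes are generated twice from the same features — once
    with the planted coefficients and once all-null — and the declared
    outcome model is refit to each.  Reports per-coefficient mean
    estimate, bias, RMSE and sign-recovery for the planted arm, and 95% CI
    coverage of zero for the null arm.  A feature-level disentangle arm
    plants a direct-x1/indirect-x2 structure (x1, x2 correlated ρ = −0.6,
    y depends on x1 only, n = 500) and records classification rates.
    """
    from .stat_models import disentangle, fit_ols

    ocfg = outcome_config or OutcomeModelConfig()
    gen = CorpusGenerator(config)
    profiler = lb.LexiconProfiler(gen.lexicon)
    bcfg = BatteryConfig(compute_lexical=False)
    master = np.random.SeedSequence(seed)
    planted = dict(ocfg.nwr_coefficients)
    model_terms = list(planted)

    est = {t: [] for t in model_terms}
    covered_null: list[float] = []
    disentangle_class: list[str] = []
    rng_dis = np.random.default_rng(master.spawn(1)[0])

    null_cfg = OutcomeModelConfig(
        nwr_coefficients={t: 0.0 for t in model_terms},
        vocab_coefficients={k: 0.0 for k in ocfg.vocab_coefficients},
        nwr_noise_sd=ocfg.nwr_noise_sd,
        vocab_noise_sd=ocfg.vocab_noise_sd,
    )

    for rep in range(n_reps):
        features = gen.gen_corpus_features(
            timepoint, replicate=rep + 1, battery_config=bcfg,
            profiler=profiler)
        rep_seed = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(2, rep)))
        outcomes = gen_outcomes(features, ocfg, rep_seed)
        X = _model_frame(features, outcomes, model_terms)
        fit = fit_ols(X, outcomes["nwr_accuracy"])
        for t in model_terms:
            est[t].append(float(fit.params[t]))

        null_outcomes = gen_outcomes(features, null_cfg, rep_seed)
        nfit = fit_ols(X, null_outcomes["nwr_accuracy"])
        ci = nfit.conf_int
        for t in model_terms:
            covered_null.append(
                float(ci.loc[t, "lower"] <= 0.0 <= ci.loc[t, "upper"]))

        # feature-level disentangle arm
        n_d = 500
        x1 = rng_dis.normal(size=n_d)
        x2 = -0.6 * x1 + math.sqrt(1 - 0.36) * rng_dis.normal(size=n_d)
        y = 1.0 * x1 + rng_dis.normal(size=n_d)
        disentangle_class.append(
            disentangle(x1, x2, y, alpha=alpha).classification)

    report: dict = {"n_reps": n_reps, "timepoint": timepoint,
                    "coefficients": {}}
    for t in model_terms:
        arr = np.array(est[t])
        truth = planted[t]
        report["coefficients"][t] = {
            "truth": truth,
            "mean_estimate": float(arr.mean()),
            "bias": float(arr.mean() - truth),
            "rmse": float(np.sqrt(np.mean((arr - truth) ** 2))),
            "sign_recovery_rate": float(np.mean(np.sign(arr)
                                                == np.sign(truth)))
            if truth != 0 else None,
        }
    report["null_ci_coverage"] = float(np.mean(covered_null))
    counts = pd.Series(disentangle_class).value_counts()
    report["disentangle_rates"] = {
        k: float(v) / n_reps for k, v in counts.items()}
    return report


def _model_frame(features: pd.DataFrame, outcomes: pd.DataFrame,
                 terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=range(len(features)))
    for t in terms:
        src = outcomes if t in outcomes.columns else features
        x = src[t].to_numpy(dtype=float)
        if t != "gender_male":
            x = (x - x.mean()) / x.std(ddof=1)
        X[t] = x
    return X
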