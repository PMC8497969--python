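"""Hyperarticulation measures: DSP features, eligibility filters, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cdsbattery import acoustic_battery as ab
from cdsbattery.corpus_io import (
    FormantMeasurement,
    PhoneInterval,
    SessionTranscript,
    WordToken,
)

from conftest import make_lexicon


class TestMelFeatures:
    def test_silence_is_log_floor(self):
        cfg = ab.FrameConfig()
        times, feats = ab.mel_frame_features(np.zeros(16000), 16000, cfg)
        assert np.allclose(feats, np.log(cfg.log_floor))

    def test_tone_argmax_band_matches_center_frequency(self):
        cfg = ab.FrameConfig()
        t = np.arange(16000) / 16000
        tone = np.sin(2 * np.pi * 1000 * t)
        times, feats = ab.mel_frame_features(tone, 16000, cfg)
        inner = feats[2:-2]
        bands = np.argmax(inner, axis=1)
        assert len(set(bands.tolist())) == 1
        centers = ab.filterbank_center_freqs(cfg)
        band = bands[0]
        # the winning band's center must be the closest (or adjacent to
        # the closest) center to 1 kHz
        nearest = int(np.argmin(np.abs(centers - 1000.0)))
        assert abs(band - nearest) <= 1

    def test_amplitude_doubling_shifts_log_by_log2(self):
        t = np.arange(8000) / 16000
        tone = 0.3 * np.sin(2 * np.pi * 440 * t)
        _, f1 = ab.mel_frame_features(tone, 16000)
        _, f2 = ab.mel_frame_features(2 * tone, 16000)
        # where energy dominates the log floor the shift is exactly log 2
        mask = f1 > np.log(1e-6)
        assert np.allclose((f2 - f1)[mask], np.log(2), atol=1e-6)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ab.mel_frame_features(np.array([]), 16000)
        with pytest.raises(ValueError, match="mono"):
            ab.mel_frame_features(np.zeros((100, 2)), 16000)

    def test_resampling_path(self):
        t = np.arange(44100) / 44100
        tone = np.sin(2 * np.pi * 500 * t)
        times, feats = ab.mel_frame_features(tone, 44100)
        assert feats.shape[1] == 40
        assert times[-1] <= 1.0


class TestPhoneMeanSpectrum:
    def test_constant_frames(self):
        times = np.linspace(0, 1, 101)
        frames = np.tile(np.arange(5.0), (101, 1))
        spec = ab.phone_mean_spectrum(
            times, frames, PhoneInterval("S", 0.2, 0.4))
        assert np.allclose(spec.mel_vector, np.arange(5.0))

    def test_two_frame_average(self):
        times = np.array([0.10, 0.20])
        frames = np.array([[0.0, 2.0], [4.0, 6.0]])
        spec = ab.phone_mean_spectrum(
            times, frames, PhoneInterval("S", 0.05, 0.25))
        assert np.allclose(spec.mel_vector, [2.0, 4.0])
        assert spec.n_frames == 2

    def test_no_frames_dropped(self):
        times = np.array([0.5])
        frames = np.zeros((1, 3))
        assert ab.phone_mean_spectrum(
            times, frames, PhoneInterval("S", 0.0, 0.1)) is None

    def test_masking_oracle_random_alignments(self, rng):
        times = np.sort(rng.uniform(0, 2, size=80))
        frames = rng.normal(size=(80, 6))
        for _ in range(25):
            start = float(rng.uniform(0, 1.8))
            end = start + float(rng.uniform(0.05, 0.2))
            phone = PhoneInterval("S", start, end)
            expected_rows = [i for i, tt in enumerate(times)
                             if start <= tt < end]
            spec = ab.phone_mean_spectrum(times, frames, phone)
            if not expected_rows:
                assert spec is None
            else:
                assert np.allclose(spec.mel_vector,
                                   frames[expected_rows].mean(axis=0))


class TestSpectralDistance:
    def test_identical_vectors(self):
        assert ab.spectral_distance(np.ones(4), np.ones(4)) == 0.0

    def test_three_four_five(self):
        assert ab.spectral_distance((0, 3, 4), (0, 0, 0)) == pytest.approx(5.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            ab.spectral_distance(np.ones(3), np.ones(4))

    @given(arrays(np.float64, 8, elements=st.floats(-50, 50)),
           arrays(np.float64, 8, elements=st.floats(-50, 50)),
           arrays(np.float64, 8, elements=st.floats(-50, 50)))
    @settings(deadline=None, max_examples=100)
    def test_metric_properties(self, a, b, c):
        dab = ab.spectral_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(ab.spectral_distance(b, a))
        assert ab.spectral_distance(a, c) <= \
            dab + ab.spectral_distance(b, c) + 1e-9


def _cv_session(cons, vowel, word="sat", function=False, flags=frozenset(),
                order="cv"):
    tokens = [WordToken(word, 0, 0)]
    labels = [cons, vowel] if order == "cv" else [vowel, cons]
    phones = [
        PhoneInterval(labels[0], 0.0, 0.1, word_index=0,
                      flags=flags if order == "cv" else frozenset()),
        PhoneInterval(labels[1], 0.1, 0.2, word_index=0),
    ]
    session = SessionTranscript("d", "24", tokens, phones)
    lex = make_lexicon([(word, f"{cons} {vowel}", 4.0, int(function))])
    return session, lex


class TestEligibility:
    def test_stop_vowel_excluded(self):
        session, lex = _cv_session("K", "AE1", "cat")
        pairs, ledger = ab.eligible_pairs(session, lex)
        assert pairs == [] and ledger["stop_before_vowel"] == 1

    def test_fricative_vowel_eligible(self):
        session, lex = _cv_session("S", "AE1")
        pairs, ledger = ab.eligible_pairs(session, lex)
        assert len(pairs) == 1 and ledger["eligible"] == 1

    def test_unstressed_vowel_excluded(self):
        session, lex = _cv_session("S", "AE0")
        pairs, ledger = ab.eligible_pairs(session, lex)
        assert pairs == [] and ledger["unstressed_vowel"] == 1

    def test_h_before_vowel_excluded(self):
        session, lex = _cv_session("HH", "AE1", "hat")
        _, ledger = ab.eligible_pairs(session, lex)
        assert ledger["h_before_vowel"] == 1

    def test_vowel_before_stop_eligible(self):
        session, lex = _cv_session("T", "AE1", "at", order="vc")
        pairs, ledger = ab.eligible_pairs(session, lex)
        assert len(pairs) == 1

    def test_function_word_excluded(self):
        session, lex = _cv_session("S", "AE1", "sat", function=True)
        _, ledger = ab.eligible_pairs(session, lex)
        assert ledger["function_word"] == 1

    def test_flagged_phone_excluded(self):
        session, lex = _cv_session("S", "AE1",
                                   flags=frozenset({"whispered"}))
        _, ledger = ab.eligible_pairs(session, lex)
        assert ledger["flagged"] == 1

    def test_non_adjacent_excluded(self):
        tokens = [WordToken("sat", 0, 0)]
        phones = [PhoneInterval("S", 0.0, 0.1, word_index=0),
                  PhoneInterval("AE1", 0.15, 0.25, word_index=0)]
        session = SessionTranscript("d", "24", tokens, phones)
        _, ledger = ab.eligible_pairs(session, tol=0.001)
        assert ledger["not_adjacent"] == 1

    def test_ledger_partitions_pairs(self, small_generator):
        session, _ = small_generator.gen_session(0, "24")
        _, ledger = ab.eligible_pairs(session, small_generator.lexicon)
        assert sum(ledger.values()) == len(session.phones) - 1


class TestLobanov:
    def _formants(self, f1s, f2s):
        return [FormantMeasurement(i, "i", f1, f2)
                for i, (f1, f2) in enumerate(zip(f1s, f2s))]

    def test_mean_zero_sd_one(self, rng):
        f1 = rng.uniform(300, 900, 40)
        f2 = rng.uniform(1000, 2800, 40)
        out = ab.lobanov_normalize(self._formants(f1, f2))
        z1 = np.array([f.f1_z for f in out])
        z2 = np.array([f.f2_z for f in out])
        assert np.mean(z1) == pytest.approx(0, abs=1e-9)
        assert np.std(z1, ddof=1) == pytest.approx(1)
        assert np.std(z2, ddof=1) == pytest.approx(1)

    def test_single_token_null(self):
        out = ab.lobanov_normalize(self._formants([500.0], [1500.0]))
        assert out[0].f1_z is None and out[0].f1_hz == 500.0

    def test_affine_invariance(self, rng):
        f1 = rng.uniform(300, 900, 20)
        f2 = rng.uniform(1000, 2800, 20)
        a = ab.lobanov_normalize(self._formants(f1, f2))
        b = ab.lobanov_normalize(self._formants(1.1 * f1 + 30, 1.5 * f2 + 10))
        for fa, fb in zip(a, b):
            assert fa.f1_z == pytest.approx(fb.f1_z)
            assert fa.f2_z == pytest.approx(fb.f2_z)


def _formant_at(idx, cat, f2z, f1z):
    f = FormantMeasurement(idx, cat, 500.0, 1500.0)
    f.f1_z, f.f2_z = f1z, f2z
    return f


class TestVowelSpace:
    def test_unit_right_triangle(self):
        formants = [_formant_at(0, "i", 0.0, 0.0),
                    _formant_at(1, "a", 1.0, 0.0),
                    _formant_at(2, "u", 0.0, 1.0)]
        area_z, _ = ab.vowel_space_area(formants)
        assert area_z == pytest.approx(0.5)

    def test_collinear_degenerate(self):
        formants = [_formant_at(0, "i", 0.0, 0.0),
                    _formant_at(1, "a", 1.0, 1.0),
                    _formant_at(2, "u", 2.0, 2.0)]
        area_z, _ = ab.vowel_space_area(formants)
        assert area_z == pytest.approx(0.0)

    def test_missing_category_null(self):
        formants = [_formant_at(0, "i", 0.0, 0.0),
                    _formant_at(1, "a", 1.0, 0.0)]
        area_z, area_hz = ab.vowel_space_area(formants)
        assert area_z is None and area_hz is None

    def test_cross_product_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(3, 2))
            formants = [_formant_at(i, c, pts[i, 0], pts[i, 1])
                        for i, c in enumerate("iau")]
            area_z, _ = ab.vowel_space_area(formants)
            v1, v2 = pts[1] - pts[0], pts[2] - pts[0]
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            assert area_z == pytest.approx(abs(cross) / 2)

    def test_permutation_within_category_invariant(self, rng):
        pts = rng.normal(size=(9, 2))
        cats = list("iiiaaauuu")
        formants = [_formant_at(i, c, *pts[i]) for i, c in enumerate(cats)]
        a1, _ = ab.vowel_space_area(formants)
        perm = [2, 0, 1, 5, 3, 4, 8, 6, 7]     # shuffles within category
        formants2 = [_formant_at(i, cats[j], *pts[j])
                     for i, j in enumerate(perm)]
        a2, _ = ab.vowel_space_area(formants2)
        assert a1 == pytest.approx(a2)


class TestDispersion:
    def test_token_at_median_is_zero(self):
        formants = [_formant_at(i, "i", float(i), float(i))
                    for i in range(3)]
        per_type, per_token = ab.vowel_dispersion(formants)
        assert min(per_token) == pytest.approx(0.0)

    def test_three_four_five_offset(self):
        # two tokens at the median, one offset by (3, 4)
        formants = [_formant_at(0, "i", 0.0, 0.0),
                    _formant_at(1, "a", 0.0, 0.0),
                    _formant_at(2, "u", 4.0, 3.0)]
        _, per_token = ab.vowel_dispersion(formants)
        assert max(per_token) == pytest.approx(5.0)

    def test_type_average_group_by_oracle(self, small_generator):
        session, _ = small_generator.gen_session(1, "24")
        formants = ab.lobanov_normalize(session.formants)
        per_type, per_token = ab.vowel_dispersion(formants, session)
        # oracle: group tokens by owning word type, mean per group
        groups = {}
        for f, d in zip([f for f in formants if f.f1_z is not None],
                        per_token):
            word = session.tokens[
                session.phones[f.phone_index].word_index].orthography
            groups.setdefault(word, []).append(d)
        for word, vals in groups.items():
            assert per_type[word] == pytest.approx(np.mean(vals))


class TestDuration:
    def test_single_phone_ms(self):
        session = SessionTranscript(
            "d", "24", [WordToken("a", 0, 0)],
            [PhoneInterval("AE1", 0.10, 0.25, word_index=0)])
        median, durations = ab.duration_summary(session)
        assert median == pytest.approx(150.0)

    def test_all_filtered_null(self):
        session = SessionTranscript(
            "d", "24", [WordToken("a", 0, 0)],
            [PhoneInterval("AE1", 0.1, 0.2, word_index=0,
                           flags=frozenset({"yelled"}))])
        median, durations = ab.duration_summary(session)
        assert median is None and durations == []
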