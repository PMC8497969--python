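"""Phono-lexical measures against hand computations and brute-force oracles."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdsbattery import lexical_battery as lx
from cdsbattery.arpabet import INVENTORY, strip_stress
from cdsbattery.corpus_io import SessionTranscript, WordToken

from conftest import make_lexicon


def brute_force_mattr(words, window):
    """Independent oracle: explicit loop over all windows."""
    if len(words) < window:
        return len(set(words)) / len(words)
    ttrs = []
    for i in range(len(words) - window + 1):
        chunk = words[i:i + window]
        ttrs.append(len(set(chunk)) / window)
    return sum(ttrs) / len(ttrs)


def brute_force_density(query, lexicon, self_word=None):
    """Independent oracle: generate every one-edit string, intersect."""
    inv = sorted(INVENTORY)
    query = tuple(strip_stress(s) for s in query)
    edits = set()
    for i in range(len(query)):
        for s in inv:
            if s != query[i]:
                edits.add(query[:i] + (s,) + query[i + 1:])   # substitution
        edits.add(query[:i] + query[i + 1:])                  # deletion
    for i in range(len(query) + 1):
        for s in inv:
            edits.add(query[:i] + (s,) + query[i:])           # addition
    n = 0
    for word, entry in lexicon.entries.items():
        if word == self_word:
            continue
        segs = {tuple(strip_stress(x) for x in v) for v in entry.variants}
        if segs & edits:
            n += 1
    return n


def _session(words, tags=None):
    tags = tags or {}
    tokens = [
        WordToken(w, 0, i, frozenset(tags.get(i, ())))
        for i, w in enumerate(words)
    ]
    return SessionTranscript("d0", "18", tokens)


class TestCleaning:
    def test_rules_applied(self):
        session = _session(
            ["cat", "ick", "maryland", "don't"],
            tags={1: ["exclamation"], 3: ["contraction"]})
        kept, phono_types, ledger = lx.clean_word_inventory(session)
        assert {t.orthography for t in kept} == {"cat", "maryland", "don't"}
        assert phono_types == {"cat", "maryland"}
        assert ledger["exclamation"] == 1

    def test_all_tagged_ledger_conserves(self):
        session = _session(["a", "b", "c"],
                           tags={0: ["onomatopoeia"], 1: ["exclamation"],
                                 2: ["proper_name"]})
        kept, phono, ledger = lx.clean_word_inventory(session)
        assert kept == [] and phono == set()
        assert sum(v for k, v in ledger.items() if k != "kept") == 3

    def test_untagged_identity(self):
        session = _session(["a", "b", "a"])
        kept, phono, _ = lx.clean_word_inventory(session)
        assert len(kept) == 3 and phono == {"a", "b"}

    @given(st.lists(st.sampled_from(
        [(), ("onomatopoeia",), ("exclamation",), ("proper_name",),
         ("contraction",)]), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_ledger_conservation_property(self, tag_lists):
        session = _session([f"w{i}" for i in range(len(tag_lists))],
                           tags=dict(enumerate(tag_lists)))
        kept, _, ledger = lx.clean_word_inventory(session)
        excluded = sum(v for k, v in ledger.items() if k != "kept")
        assert len(kept) + excluded == len(tag_lists)
        assert ledger["kept"] == len(kept)


class TestDiversity:
    def test_ttr_examples(self):
        assert lx.type_token_stats(list("abcd")) == (4, 4, 1.0)
        assert lx.type_token_stats(list("aaaa")) == (1, 4, 0.25)

    def test_ttr_set_oracle(self, rng):
        words = [f"t{i}" for i in rng.integers(0, 100, size=1000)]
        n_types, n_tokens, ttr = lx.type_token_stats(words)
        assert n_types == len(set(words))
        assert ttr == pytest.approx(len(set(words)) / 1000)

    def test_empty_stream_undefined(self):
        with pytest.raises(lx.UndefinedStatError):
            lx.type_token_stats([])
        with pytest.raises(lx.UndefinedStatError):
            lx.mattr([])

    def test_mattr_identical_tokens(self):
        value, fallback = lx.mattr(["the"] * 20, window=10)
        assert value == pytest.approx(0.1)
        assert not fallback

    def test_mattr_all_distinct(self):
        value, _ = lx.mattr([f"w{i}" for i in range(20)], window=10)
        assert value == pytest.approx(1.0)

    def test_mattr_brute_force_oracle(self, rng):
        words = [f"t{i}" for i in rng.integers(0, 40, size=200)]
        value, _ = lx.mattr(words, window=10)
        assert value == pytest.approx(brute_force_mattr(words, 10), abs=1e-12)

    def test_mattr_short_stream_falls_back_to_ttr(self):
        value, fallback = lx.mattr(["a", "b", "a"], window=10)
        assert fallback
        assert value == pytest.approx(2 / 3)

    def test_mattr_full_window_equals_ttr(self, rng):
        words = [f"t{i}" for i in rng.integers(0, 20, size=50)]
        _, _, ttr = lx.type_token_stats(words)
        value, _ = lx.mattr(words, window=len(words))
        assert value == pytest.approx(ttr)

    @given(st.lists(st.integers(0, 10), min_size=12, max_size=60),
           st.permutations(list(range(11))))
    @settings(deadline=None, max_examples=50)
    def test_mattr_invariant_to_relabeling(self, ids, perm):
        words = [f"t{i}" for i in ids]
        relabeled = [f"t{perm[i]}" for i in ids]
        assert lx.mattr(words)[0] == pytest.approx(lx.mattr(relabeled)[0])


class TestBiphones:
    def test_hand_counts(self, three_word_lexicon):
        tables = lx.build_biphone_tables(three_word_lexicon)
        assert tables.positional_counts[(0, ("K", "AE"))] == 1
        assert tables.positional_totals[0] == 3
        assert tables.positional_counts[(1, ("AE", "T"))] == 2

    def test_single_phoneme_word_empty_tables(self):
        lex = make_lexicon([("a", "AH0", 6.0, 1)])
        tables = lx.build_biphone_tables(lex)
        assert tables.positional_counts == {}

    def test_counts_sum_to_totals(self, toy_lexicon):
        tables = lx.build_biphone_tables(toy_lexicon)
        for pos, total in tables.positional_totals.items():
            s = sum(v for (p, _), v in tables.positional_counts.items()
                    if p == pos)
            assert s == total

    def test_phonprob_hand_computation(self, three_word_lexicon):
        tables = lx.build_biphone_tables(three_word_lexicon)
        p = lx.phonotactic_probability(("K", "AE1", "T"), tables)
        assert p == pytest.approx(0.5)     # mean(1/3, 2/3)

    def test_phonprob_sole_entry_is_one(self):
        lex = make_lexicon([("cat", "K AE1 T", 4.0, 0)])
        tables = lx.build_biphone_tables(lex)
        assert lx.phonotactic_probability(("K", "AE1", "T"), tables) == 1.0

    def test_phonprob_single_segment_null(self, three_word_lexicon):
        tables = lx.build_biphone_tables(three_word_lexicon)
        assert lx.phonotactic_probability(("K",), tables) is None

    def test_phonprob_bounds_property(self, small_generator):
        tables = lx.build_biphone_tables(small_generator.lexicon)
        for entry in list(small_generator.lexicon.entries.values())[:100]:
            p = lx.phonotactic_probability(entry.variants[0], tables)
            if p is not None:
                assert 0.0 <= p <= 1.0


class TestZScore:
    def test_small_stratum_hand_zscore(self):
        # two orthographies share K AE, one has S AE: raw probabilities in
        # the length-2 stratum are {2/3, 2/3, 1/3}; z uses the n-1 sd
        lex = make_lexicon([("aa", "K AE1", 4.0, 0),
                            ("bb", "K AE1", 4.0, 0),
                            ("cc", "S AE1", 4.0, 0)])
        tables = lx.build_biphone_tables(lex)
        raw = lx.phonotactic_probability(("K", "AE1"), tables)
        assert raw == pytest.approx(2 / 3)
        zs = lx.zscore_phonprob([raw], [2], lex, tables)
        stratum = [2 / 3, 2 / 3, 1 / 3]
        expected = (raw - statistics.mean(stratum)) / statistics.stdev(stratum)
        assert zs[0] == pytest.approx(expected)

    def test_singleton_stratum_null(self):
        lex = make_lexicon([("aa", "K AE1", 4.0, 0),
                            ("ccc", "K AE1 T", 4.0, 0),
                            ("ddd", "S AE1 T", 4.0, 0)])
        zs = lx.zscore_phonprob([0.5], [2], lex)
        assert zs[0] is None

    def test_stratum_mean_zero(self, small_generator):
        lex = small_generator.lexicon
        tables = lx.build_biphone_tables(lex)
        prons = [v for e in lex.entries.values() for v in e.variants
                 if len(v) == 3]
        raws = [lx.phonotactic_probability(p, tables) for p in prons]
        zs = lx.zscore_phonprob(raws, [3] * len(raws), lex, tables)
        zs = [z for z in zs if z is not None]
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)
        assert np.std(zs, ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestDensity:
    def test_hand_example(self, toy_lexicon):
        # neighbors of K AE T: sat (sub), kit (sub), cats (addition),
        # at (deletion); self excluded
        n = lx.neighborhood_density(("K", "AE1", "T"), toy_lexicon,
                                    query_orthography="cat")
        assert n == brute_force_density(("K", "AE1", "T"), toy_lexicon, "cat")
        assert n == 4

    def test_only_self_in_lexicon(self):
        lex = make_lexicon([("cat", "K AE1 T", 4.0, 0)])
        assert lx.neighborhood_density(("K", "AE1", "T"), lex, "cat") == 0

    def test_oracle_equivalence_random_lexicons(self, rng):
        inv = sorted(INVENTORY)
        for _ in range(30):
            words = []
            for j in range(rng.integers(3, 15)):
                length = int(rng.integers(1, 5))
                pron = " ".join(str(rng.choice(inv)) for _ in range(length))
                words.append((f"w{j}", pron, 4.0, 0))
            lex = make_lexicon(words)
            query = tuple(
                str(rng.choice(inv)) for _ in range(rng.integers(1, 5)))
            assert lx.neighborhood_density(query, lex) == \
                brute_force_density(query, lex)

    def test_symmetry_property(self, rng):
        inv = sorted(INVENTORY)[:8]    # small alphabet makes neighbors likely
        prons = {f"w{j}": tuple(str(rng.choice(inv))
                                for _ in range(rng.integers(2, 4)))
                 for j in range(12)}
        lex = make_lexicon([(w, " ".join(p), 4.0, 0)
                            for w, p in prons.items()])
        for wa, pa in prons.items():
            for wb, pb in prons.items():
                a_nb_b = lx._one_edit_apart(pa, pb)
                b_nb_a = lx._one_edit_apart(pb, pa)
                assert a_nb_b == b_nb_a


class TestVariantsAndProfiles:
    def test_single_variant(self, toy_lexicon):
        entry = toy_lexicon.get("cat")
        tables = lx.build_biphone_tables(toy_lexicon)
        assert lx.select_variant(entry, tables) == entry.variants[0]

    def test_highest_probability_wins(self):
        lex = make_lexicon([
            ("cat", "K AE1 T", 4.0, 0),
            ("cot", "K AA1 T", 4.0, 0),
            ("kit", "K AE1 T S", 4.0, 0),
        ])
        entry = lex.get("cat")
        entry.variants.append(("X",))            # length-1: null probability
        entry.variants.append(("JH", "UH1"))     # rare biphones
        tables = lx.build_biphone_tables(lex)
        assert lx.select_variant(entry, tables) == ("K", "AE1", "T")

    def test_exact_tie_keeps_first_listed(self):
        lex = make_lexicon([("ab", "K AE1", 4.0, 0)])
        entry = lex.get("ab")
        entry.variants.append(("S", "AE1"))
        tables = lx.build_biphone_tables(lex)
        p1 = lx.phonotactic_probability(entry.variants[0], tables)
        p2 = lx.phonotactic_probability(entry.variants[1], tables)
        assert p1 == p2
        assert lx.select_variant(entry, tables) == entry.variants[0]

    def test_profile_summaries_hand_computed(self, toy_lexicon):
        session = _session(["cat", "kit", "banana"])
        profiles, summaries = lx.lexical_profile(session, toy_lexicon)
        assert summaries["n_profiled_types"] == 3
        assert summaries["mean_word_length"] == pytest.approx((3 + 3 + 6) / 3)
        assert summaries["median_log_frequency"] == pytest.approx(
            statistics.median([4.2, 3.1, 3.0]))
        assert summaries["median_neighborhood_density"] == statistics.median(
            [profiles["cat"].neighborhood_density,
             profiles["kit"].neighborhood_density,
             profiles["banana"].neighborhood_density])

    def test_out_of_lexicon_types_null(self, toy_lexicon):
        session = _session(["zebra", "quokka"])
        profiles, summaries = lx.lexical_profile(session, toy_lexicon)
        assert summaries["n_unprofiled_types"] == 2
        assert summaries["mean_word_length"] is None
        assert all(not p.in_lexicon for p in profiles.values())

    def test_log_frequency_passes_through(self, toy_lexicon):
        session = _session(["cat"])
        profiles, _ = lx.lexical_profile(session, toy_lexicon)
        assert profiles["cat"].log_frequency == 4.2


class TestMedianSplits:
    def _profiles(self, lengths=None, freqs=None):
        n = len(lengths or freqs)
        return {
            f"w{i}": lx.LexicalProfile(
                f"w{i}",
                lengths[i] if lengths else 3,
                freqs[i] if freqs else 4.0,
                0, 0.1, 0.0, True)
            for i in range(n)
        }

    def test_long_words_inclusive_boundary(self):
        profiles = self._profiles(lengths=[3, 4, 5])
        assert lx.long_word_count(profiles, 4) == 2

    def test_no_long_words(self):
        assert lx.long_word_count(self._profiles(lengths=[1, 2, 3]), 4) == 0

    def test_low_freq_strict_boundary(self):
        profiles = self._profiles(freqs=[2.0, 5.0, 8.0])
        assert lx.low_freq_count(profiles, 5.0) == 1

    def test_no_low_freq(self):
        assert lx.low_freq_count(self._profiles(freqs=[5.0, 6.0]), 5.0) == 0

    def test_filter_oracle_random(self, rng):
        freqs = rng.normal(5, 2, size=60).tolist()
        profiles = self._profiles(freqs=freqs)
        med = float(np.median(freqs))
        assert lx.low_freq_count(profiles, med) == \
            sum(1 for f in freqs if f < med)

    def test_pooled_median_one_obs_per_caregiver_type(self):
        per_cg = {"a": [3, 4], "b": [4, 5, 5]}
        assert lx.pooled_median(per_cg) == 4
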