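import numpy as np
import pytest

from cdsbattery.corpus_io import Lexicon, LexiconEntry
from cdsbattery.lexical_battery import LexiconProfiler
from cdsbattery.synthetic_data import CorpusGenerator, GeneratorConfig, scaled_config


def make_lexicon(rows):
    """rows: (orthography, pron string, log_freq, is_function)."""
    lex = Lexicon()
    for word, pron, freq, func in rows:
        lex.add(LexiconEntry(word, [tuple(pron.split())], freq, bool(func)))
    return lex


@pytest.fixture
def toy_lexicon():
    return make_lexicon([
        ("cat", "K AE1 T", 4.2, 0),
        ("sat", "S AE1 T", 3.9, 0),
        ("kit", "K IH1 T", 3.1, 0),
        ("cats", "K AE1 T S", 3.8, 0),
        ("at", "AE1 T", 5.5, 1),
        ("banana", "B AH0 N AE1 N AH0", 3.0, 0),
    ])


@pytest.fixture
def three_word_lexicon():
    return make_lexicon([
        ("cat", "K AE1 T", 4.0, 0),
        ("sat", "S AE1 T", 4.0, 0),
        ("kit", "K IH1 T", 4.0, 0),
    ])


@pytest.fixture(scope="session")
def small_generator():
    """A reduced-size corpus generator shared across tests (read-only)."""
    return CorpusGenerator(scaled_config(seed=11, n_dyads=6, tokens=250,
                                         lexicon_size=400))


@pytest.fixture(scope="session")
def small_profiler(small_generator):
    return LexiconProfiler(small_generator.lexicon)


@pytest.fixture(scope="session")
def default_generator():
    """Full-size defaults; lexicon built once per test session."""
    return CorpusGenerator(GeneratorConfig(seed=5, n_dyads=4))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
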