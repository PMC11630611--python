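import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import formantlr as flr
from formantlr.corpus import COLUMNS, Corpus

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_tokens(rows):
    """Build a token table from (speaker, twin, style, vowel, dur, f1..f4) tuples."""
    return pd.DataFrame(rows, columns=list(COLUMNS))


@pytest.fixture
def tiny_corpus():
    """Three speakers (one twin pair + one solo), both styles, hand-written."""
    rows = [
        ("A1", "A", "dialogue", "a", 0.08, 600.0, 1400.0, 2400.0, 3400.0),
        ("A1", "A", "interview", "i", 0.06, 330.0, 2000.0, 2650.0, 3560.0),
        ("A2", "A", "dialogue", "a", 0.09, 620.0, 1380.0, 2380.0, 3390.0),
        ("A2", "A", "interview", "u", 0.07, 350.0, 1100.0, 2500.0, 3520.0),
        ("S1", None, "dialogue", "e", 0.05, 410.0, 1900.0, 2600.0, 3530.0),
        ("S1", None, "interview", "a", 0.08, 590.0, 1390.0, 2370.0, 3380.0),
    ]
    return Corpus(make_tokens(rows))


@pytest.fixture(scope="session")
def small_synth_corpus():
    """A quick 10-speaker synthetic corpus shared by I/O and preprocessing tests."""
    cfg = flr.SynthConfig(
        seed=42,
        n_speakers=10,
        n_twin_pairs=5,
        tokens_per_speaker_style={"dialogue": (60, 90), "interview": (50, 80)},
    )
    corpus, truth = flr.generate_corpus(cfg)
    return corpus, truth, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
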