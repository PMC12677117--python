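import numpy as np
import pytest

from speechtrack.lexicon import Lexicon, LexiconEntry


@pytest.fixture(scope="session")
def toy_lexicon():
    """Three-word lexicon with known cohort arithmetic.

    Pronunciations: AB (freq 4), AC (freq 4), BA (freq 2). Hearing 'A'
    leaves {AB, AC} (summed freq 8); hearing 'AB' leaves {AB} (4).
    """
    return Lexicon(
        [
            LexiconEntry("AB", ("A", "B"), 4.0),
            LexiconEntry("AC", ("A", "C"), 4.0),
            LexiconEntry("BA", ("B", "A"), 2.0),
        ]
    )


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(12345)
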