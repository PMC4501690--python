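import numpy as np
import pytest

from flyvirome.mapping import Reference


@pytest.fixture
def rng():
    return np.random.default_rng(20150714)


@pytest.fixture
def reference(rng):
    """A 600 nt random reference with no simple repeats by construction."""
    return Reference("ref1", "".join(rng.choice(list("ACGT"), size=600)))
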