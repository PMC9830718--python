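import numpy as np
import pytest

from prana.containers import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_expr(rng):
    """8 samples x 3 genes of NB-ish counts, enough for a 4+4 group split."""
    values = rng.poisson(50, size=(8, 3)).astype(float)
    return ExpressionMatrix(values, [f"S{i}" for i in range(8)], ["GA", "GB", "GC"])
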