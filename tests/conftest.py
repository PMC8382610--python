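import numpy as np
import pytest

from usmuscle import NPDSeries


@pytest.fixture
def flat_series():
    """Factory for hand-built NPD series at 40 fps."""

    def make(values):
        return NPDSeries(values=np.asarray(values, dtype=float), fps=40.0)

    return make
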