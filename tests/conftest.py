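import numpy as np
import pytest

from luadgrade import case_from_pct


@pytest.fixture
def comp():
    """Build a case composition directly from a percent dict."""

    def _make(pct, case_id="c1", min_secondary_pct=5.0):
        return case_from_pct(case_id, pct, min_secondary_pct=min_secondary_pct)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
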