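import numpy as np
import pytest

from rcirt import GRMItemBank


@pytest.fixture
def symmetric_bank():
    """Five identical items with thresholds symmetric about zero."""
    return GRMItemBank([(2.0, (-1.0, -0.5, 0.5, 1.0))] * 5)


@pytest.fixture
def toy_bank3():
    """Three heterogeneous five-category items (small enough to enumerate)."""
    return GRMItemBank(
        [
            (1.7, (-1.2, -0.4, 0.3, 1.1)),
            (2.2, (-0.6, -0.1, 0.5, 0.9)),
            (1.2, (-1.5, -0.9, 0.2, 1.8)),
        ]
    )


@pytest.fixture
def toy_bank5(toy_bank3):
    """Five mixed items used by the estimator oracle checks."""
    return GRMItemBank(
        list(toy_bank3) + [(2.0, (-1.0, -0.5, 0.5, 1.0)), (1.4, (0.0, 0.6, 1.2, 1.9))]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
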