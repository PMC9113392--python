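import numpy as np
import pytest

from pedtriage import default_config, default_params
from pedtriage.metrics import Confusion2x2, CrossTab


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def reference_confusion():
    """The validation cohort's dichotomized 2x2 (n = 100,506)."""
    return Confusion2x2(tp=1710, fp=15082, fn=528, tn=83186)


@pytest.fixture(scope="session")
def reference_crosstab_counts():
    """The validation cohort's full 2x5 cross-tabulation."""
    return CrossTab(
        np.array(
            [
                [82, 1628, 489, 38, 1],
                [135, 14947, 34343, 41264, 7579],
            ]
        )
    )
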