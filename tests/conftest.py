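import numpy as np
import pytest

from sentspec.design import GRAMMATICALITY, PLAUSIBILITY, build_task_design


@pytest.fixture(scope="session")
def gram_runs():
    """Default two-run grammaticality design (80 trials, 20 per condition)."""
    return build_task_design(GRAMMATICALITY, seed=101)


@pytest.fixture(scope="session")
def plaus_runs():
    return build_task_design(PLAUSIBILITY, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
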