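import numpy as np
import pytest

import motmem as mm


def _cohort_log(architecture: str, seed: int):
    rng = np.random.default_rng(seed)
    cohort = mm.make_cohort(
        4, mm.ObserverParams(architecture=architecture), jitter=0.1, rng=rng
    )
    return mm.simulate_cohort("exp1b", cohort, seed=seed + 1)


@pytest.fixture(scope="session")
def exclusive_log():
    """Four exclusive-architecture observers on the constant-length design."""
    return _cohort_log("exclusive", 11)


@pytest.fixture(scope="session")
def shared_log():
    return _cohort_log("shared", 12)


@pytest.fixture(scope="session")
def guessing_log():
    return _cohort_log("guessing", 13)
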