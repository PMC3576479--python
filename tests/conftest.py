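import numpy as np
import pytest

from blindadapt import TrialData


def make_trial(outcomes, arms, strata=None, binary=()):
    """Small-trial builder for tests: outcomes is a dict name -> list."""
    n = len(arms)
    if strata is None:
        strata = [1] * n
    return TrialData(
        subject_id=np.array([f"S{i}" for i in range(n)], dtype=object),
        arm=np.array(list(arms), dtype=object),
        stratum=np.array(strata, dtype=int),
        outcomes={k: np.array(v, dtype=float) for k, v in outcomes.items()},
        binary_endpoints=binary,
    )


@pytest.fixture
def worked_binary_trial():
    """The 3-vs-3 binary fixture: all three events in the control arm."""
    return make_trial(
        {"event": [1, 1, 1, 0, 0, 0]},
        arms="CCCTTT",
        binary=("event",),
    )
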