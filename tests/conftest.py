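import numpy as np
import pytest

from gazefuzz.fuzzy import MembershipParams, RampPair


@pytest.fixture
def worked_example_params() -> MembershipParams:
    """Membership ramps reproducing the worked-example degrees.

    Chosen so that f1 = 0.30 -> (muL, muH) = (0.75, 0.25),
    f2 = 0.50 -> (0.00, 1.00) and f3 = 0.45 -> (0.32, 0.68).
    """
    return MembershipParams(
        feature1=RampPair(0.2, 0.6, 0.2, 0.6),
        feature2=RampPair(0.1, 0.5, 0.1, 0.5),
        feature3=RampPair(0.11, 0.61, 0.11, 0.61),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
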