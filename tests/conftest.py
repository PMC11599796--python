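import numpy as np
import pytest

from domsuite.records_io import Assay, MatchRecord, Outcome


@pytest.fixture
def small_matches():
    """Four-animal tube-test match list with a known winner structure."""
    return [
        MatchRecord(Assay.TUBE, "cage0", i, a, b, out)
        for i, (a, b, out) in enumerate(
            [
                ("m0", "m1", Outcome.A_WINS),
                ("m0", "m2", Outcome.A_WINS),
                ("m0", "m3", Outcome.A_WINS),
                ("m1", "m2", Outcome.A_WINS),
                ("m1", "m3", Outcome.A_WINS),
                ("m2", "m3", Outcome.A_WINS),
            ]
        )
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
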