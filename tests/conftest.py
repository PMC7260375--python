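import numpy as np
import pandas as pd
import pytest

from metricselect.data import OBSERVATION_COLUMNS, SubjectRecord


@pytest.fixture
def tiny_subjects():
    return [
        SubjectRecord("S1", "intact", 40.0, "male", "right", False),
        SubjectRecord("S2", "intact", 60.0, "female", "left", True),
        SubjectRecord("P1", "stroke", 55.0, "male", "right", False,
                      {"fma_ue": 50}),
    ]


@pytest.fixture
def tiny_observations():
    rows = []
    for sid, side in (("S1", "left"), ("S1", "right"), ("S2", "left"),
                      ("P1", "right")):
        for rep in (1, 2):
            for peg in (1, 2, 3):
                rows.append((sid, side, "test", rep, peg, "speed",
                             float(10 + rep + peg)))
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
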