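import logging

import numpy as np
import pandas as pd
import pytest

from immunotme.io import ClinicalTable, ExpressionMatrix, GeneSetCollection

logging.getLogger("immunotme").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240816)


@pytest.fixture
def small_expr(rng):
    """A 30-gene x 12-sample normalized expression matrix."""
    vals = rng.lognormal(mean=1.0, sigma=0.5, size=(30, 12))
    return ExpressionMatrix([f"g{i}" for i in range(30)],
                            [f"s{j}" for j in range(12)], vals, "normalized")


@pytest.fixture
def small_sets():
    return GeneSetCollection({
        "setA": [f"g{i}" for i in range(0, 8)],
        "setB": [f"g{i}" for i in range(8, 20)],
    })


def make_clinical(time, event, ids=None, state="tumor"):
    ids = ids if ids is not None else [f"s{i}" for i in range(len(time))]
    states = [state] * len(ids) if isinstance(state, str) else list(state)
    return ClinicalTable(pd.DataFrame({
        "sample_id": ids, "state": states,
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=float),
    }))
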