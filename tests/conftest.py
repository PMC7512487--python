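import numpy as np
import pytest

import afentropy as af
from afentropy.core import MEASURES, compute_all

DATASET_SEED = 42


@pytest.fixture(scope="session")
def dataset_30():
    """Default study conditions: 500 AF-like + 500 NSR-like 30-beat segments."""
    return af.gen_labeled_dataset(500, 500, window=30, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def scores_30(dataset_30):
    """All four measures on the default dataset, plus labels."""
    vals = {m: np.empty(len(dataset_30)) for m in MEASURES}
    for i, seg in enumerate(dataset_30):
        res = compute_all(seg)
        for m in MEASURES:
            vals[m][i] = res[m].value
    labels = np.array([s.label for s in dataset_30])
    return vals, labels


@pytest.fixture(scope="session")
def mixed_segments():
    """100 study-condition segments (50 AF-like, 50 NSR-like), fixed stream."""
    rng = np.random.default_rng(0)
    return [af.gen_af_rr(af.AF_DEFAULTS, rng).intervals for _ in range(50)] + [
        af.gen_nsr_rr(af.NSR_DEFAULTS, rng).intervals for _ in range(50)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
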