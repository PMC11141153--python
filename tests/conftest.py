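import numpy as np
import pandas as pd
import pytest

from atriomics import OmicsMatrix


def make_matrix(values, groups=None, feature_ids=None, dataset_tag="TL",
                value_kind="intensity"):
    """Build a small OmicsMatrix from a 2-D list/array (AF columns first)."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    half = m // 2
    samples = [f"AF{i+1}" for i in range(half)] + \
              [f"sham{i+1}" for i in range(m - half)]
    if groups is None:
        groups = {s: ("AF" if s.startswith("AF") else "sham") for s in samples}
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(n)]
    frame = pd.DataFrame(arr, index=feature_ids, columns=samples)
    return OmicsMatrix(values=frame, groups=groups, dataset_tag=dataset_tag,
                       value_kind=value_kind)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
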