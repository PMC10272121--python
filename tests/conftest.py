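import numpy as np
import pytest

from dynconn.features import FeatureTable
from dynconn.model import TraitModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature_table(values, kind="dcc_variance", seed_id="seed_1"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureTable(
        kind=kind,
        subject_ids=[f"sub-{i + 1:03d}" for i in range(n)],
        edge_ids=[f"{seed_id}__region_{j + 1:03d}" for j in range(p)],
        values=values,
        provenance={"seed_id": seed_id},
    )


def make_model(weights, means=None, sds=None, n_train=50, seed_id="seed_1"):
    weights = np.asarray(weights, dtype=float)
    p = weights.size
    return TraitModel(
        seed_id=seed_id,
        outcome_name="trait",
        edge_ids=[f"{seed_id}__region_{j + 1:03d}" for j in range(p)],
        weights=weights,
        intercept=1.5,
        feature_means=np.zeros(p) if means is None else np.asarray(means, float),
        feature_sds=np.ones(p) if sds is None else np.asarray(sds, float),
        n_train=n_train,
        penalty=0.1,
    )


@pytest.fixture
def toy_table(rng):
    return make_feature_table(rng.random((20, 6)))
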