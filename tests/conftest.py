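import numpy as np
import pytest

from mixnets.data_model import DataClass, FeatureDescriptor, OmicsDataset


def make_features(n_b=0, n_o=0, n_c=0):
    feats = []
    for i in range(n_b):
        feats.append(FeatureDescriptor(f"G{i:03d}-M", f"G{i:03d}", "M",
                                       DataClass.BINARY))
    for i in range(n_o):
        j = n_b + i
        feats.append(FeatureDescriptor(f"G{j:03d}-CN", f"G{j:03d}", "CN",
                                       DataClass.ORDINAL))
    for i in range(n_c):
        j = n_b + n_o + i
        feats.append(FeatureDescriptor(f"G{j:03d}-T", f"G{j:03d}", "T",
                                       DataClass.CONTINUOUS))
    return feats


def make_dataset(values, n_b=0, n_o=0, n_c=None):
    values = np.asarray(values, dtype=float)
    if n_c is None:
        n_c = values.shape[1] - n_b - n_o
    feats = make_features(n_b, n_o, n_c)
    ids = [f"S{i:03d}" for i in range(values.shape[0])]
    return OmicsDataset(ids, feats, values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def continuous_chain_data(rng):
    """N x 3 continuous data with a strong linear chain X0 -> X1 -> X2."""
    n = 500
    x = np.zeros((n, 3))
    x[:, 0] = rng.normal(size=n)
    x[:, 1] = 1.5 * x[:, 0] + rng.normal(size=n)
    x[:, 2] = 1.5 * x[:, 1] + rng.normal(size=n)
    return x
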