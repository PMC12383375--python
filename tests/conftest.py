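import numpy as np
import pytest

from rcmf_eo import LabeledDataset, make_fixture


def toy_dataset(values, labels, **kw) -> LabeledDataset:
    """Build a LabeledDataset from raw arrays with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    return LabeledDataset(
        values=values,
        labels=labels,
        gene_ids=[f"g{i}" for i in range(values.shape[1])],
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        **kw,
    )


@pytest.fixture(scope="session")
def small_fixture():
    return make_fixture("small")


@pytest.fixture(scope="session")
def rcmf_fixture():
    return make_fixture("rcmf")


@pytest.fixture(scope="session")
def wrapper_fixture():
    return make_fixture("wrapper")
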