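import numpy as np
import pytest

from edlcdss import SyntheticSpec, TablePreprocessor, generate_synthetic


@pytest.fixture(scope="session")
def ckd_like_ds():
    """400-row CKD-shaped dataset: 250:150 imbalance, mixed columns,
    scattered missingness."""
    return generate_synthetic(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def preprocessed(ckd_like_ds):
    """Fully numeric [0,1] version of the CKD-like dataset."""
    return TablePreprocessor().fit_transform(ckd_like_ds)


@pytest.fixture(scope="session")
def preprocessed_Xy(preprocessed):
    return preprocessed.X.to_numpy(float), preprocessed.y


@pytest.fixture(scope="session")
def separable_Xy():
    """Small, strongly separated, fully observed fixture for training
    checks (class separation 3, n=300)."""
    ds = generate_synthetic(SyntheticSpec(
        n_positive=150, n_negative=150, d_numeric=6, d_categorical=2,
        class_separation=3.0, missing_rate=0.0, seed=7,
    ))
    p = TablePreprocessor().fit_transform(ds)
    return p.X.to_numpy(float), p.y


@pytest.fixture
def rng():
    return np.random.default_rng(0)
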