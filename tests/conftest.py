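import numpy as np
import pytest

from tmaseg.superpixels import slic
from tmaseg.synthetic import SyntheticParams, generate_dataset, generate_tma
from tmaseg.texture import extract_feature_table


@pytest.fixture(scope="session")
def small_core():
    """One small synthetic core with its exact label image."""
    return generate_tma(SyntheticParams(size=128, seed=7))


@pytest.fixture(scope="session")
def study_dataset():
    """The default 10-core study dataset (size 512, base seed 42)."""
    return generate_dataset(10, base_seed=42)


@pytest.fixture(scope="session")
def study_feature_tables(study_dataset):
    """Labeled per-image feature tables of the study dataset."""
    tables = []
    for i, (img, lbl) in enumerate(study_dataset):
        assignment = slic(img)
        tables.append(extract_feature_table(img, assignment, image_id=i, labels=lbl))
    return tables


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
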