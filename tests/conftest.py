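import numpy as np
import pytest

import qsar_workbench as qw
from qsar_workbench.fixtures import SyntheticSpec, generate_classification_set


@pytest.fixture(scope="session")
def clf_dataset():
    """120-record standardized classification fixture with planted signal,
    10% label noise and 10% salt forms."""
    ds = generate_classification_set(
        SyntheticSpec(120, 7, "classification", noise=0.1, salt_fraction=0.1)
    )
    return qw.standardize(ds, ["desalt", "neutralize", "canonicalize"])


@pytest.fixture(scope="session")
def clf_clusters(clf_dataset):
    # the fragment grammar's baseline Tanimoto is low; 0.25 groups the
    # fixture by scaffold family, giving genuine cluster structure
    return qw.cluster_molecules(clf_dataset, similarity_threshold=0.25)


@pytest.fixture(scope="session")
def reg_dataset():
    ds = qw.generate_regression_set(
        SyntheticSpec(100, 11, "regression", noise=0.3, salt_fraction=0.1)
    )
    return qw.standardize(ds, ["desalt", "neutralize", "canonicalize"])


@pytest.fixture(scope="session")
def molprops_matrix(clf_dataset):
    return qw.compute_block_matrix(clf_dataset, "Molprops")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
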