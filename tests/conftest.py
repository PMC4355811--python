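import numpy as np
import pytest

from gpes import SyntheticSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separable_binary():
    """Well-separated two-class set: 10 informative of 300 genes, shift 5."""
    return make_dataset(
        SyntheticSpec(n_per_class=(30, 30), n_features=300, n_informative=10,
                      shift=5.0, seed=11)
    )


@pytest.fixture(scope="session")
def separable_binary_test():
    """Held-out draw from the same class-conditional distribution."""
    return make_dataset(
        SyntheticSpec(n_per_class=(30, 30), n_features=300, n_informative=10,
                      shift=5.0, seed=97)
    )


@pytest.fixture
def tiny_table(tmp_path):
    """A 4x3 delimited table with two balanced string classes."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "sample_id,label,G1,G2,G3\n"
        "s1,A,1.0,2.0,3.0\n"
        "s2,A,4.0,5.0,6.0\n"
        "s3,B,7.0,8.0,9.0\n"
        "s4,B,10.0,11.0,12.0\n"
    )
    return path
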