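import numpy as np
import pytest

from orievolve import build_ori_reference, mutagenize_library
from orievolve.simulate.eppcr import EppcrModel


@pytest.fixture(scope="session")
def small_ori():
    """A compact amplicon: 120 nt ORF + 30 nt flanks."""
    return build_ori_reference(120, flank=30, seed=11, wt_copy_number=9.5)


@pytest.fixture(scope="session")
def big_ori():
    """The study-scale amplicon: 966 nt ORF + 150 nt flanks."""
    return build_ori_reference(966, flank=150, seed=11, wt_copy_number=9.5)


@pytest.fixture(scope="session")
def small_library(small_ori):
    return mutagenize_library(
        small_ori, 300, EppcrModel(mean_mutations=1.5), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
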