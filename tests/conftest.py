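import numpy as np
import pytest

from bloodecon.core import BetaMatrix, default_hierarchy
from bloodecon.sim import generate_synthetic_reference


def make_beta(values, cpg_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    cpg_ids = cpg_ids or [f"cg{i:03d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return BetaMatrix(cpg_ids, sample_ids, values)


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture(scope="session")
def small_reference(hierarchy):
    """Small noisy synthetic sorted-cell reference shared across tests."""
    return generate_synthetic_reference(
        n_cpgs=2000,
        hierarchy=hierarchy,
        n_diff_per_type=60,
        n_samples_per_type=6,
        noise_sd=0.02,
        seed=7,
    )
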