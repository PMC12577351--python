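import numpy as np
import pandas as pd
import pytest

from rumenblup import SimConfig, simulate_dataset
from rumenblup.design import build_design


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared across read-only tests."""
    cfg = SimConfig(
        n_animals=240, n_snps=600, n_orfs=300, seed=101,
        target_h2=0.30, target_m2=0.20,
    )
    return simulate_dataset(cfg, trait_names=("ADDMI",))


@pytest.fixture(scope="session")
def small_design(small_study):
    return build_design(small_study.phenotypes)


@pytest.fixture()
def toy_S():
    """3-animal, 2-ORF log-abundance toy with hand-computable kernels."""
    return np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_psd(n, rng, jitter=0.0):
    A = rng.standard_normal((n, 2 * n))
    return A @ A.T / (2 * n) + jitter * np.eye(n)
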