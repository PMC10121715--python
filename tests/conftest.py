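import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pfpca

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return pfpca.benchmark_grid()


@pytest.fixture(scope="session")
def mu0(grid):
    return pfpca.benchmark_tuning_curve(grid)


@pytest.fixture(scope="session")
def gain_dataset():
    """One multiplicative-gain validation dataset (B=50, seed fixed)."""
    spec = pfpca.BenchmarkSpec(kind="gain", seed=11)
    return pfpca.build_benchmark(spec)


@pytest.fixture(scope="session")
def gain_fit(gain_dataset):
    """A full two-step fit of the gain dataset, shared across tests.

    M reduced from the reference 10,000 to keep the suite fast; the
    posterior moments at this sample size are accurate to ~2 %.
    """
    counts, truth, true_scores = gain_dataset
    em = pfpca.EMConfig(M=2_000, seed=11)
    decomp, scores, post = pfpca.fit_pfpca(counts, K=3, em_config=em)
    return decomp, scores, post


@pytest.fixture(scope="session")
def em_posterior(gain_dataset):
    counts, _truth, _scores = gain_dataset
    em = pfpca.EMConfig(M=2_000, seed=11)
    post, f_hat, Sigma_hat, log = pfpca.recover_latent_rates(counts, em)
    return post, f_hat, Sigma_hat, log
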