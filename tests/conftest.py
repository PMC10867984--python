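import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecpg import CovariateTable, LocusMatrix, align_samples

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_covariates(rng: np.random.Generator, n: int, m: int) -> CovariateTable:
    return CovariateTable(tuple(f"s{i}" for i in range(n)),
                          tuple(f"c{j}" for j in range(m)),
                          rng.standard_normal((n, m)))


def make_dataset(rng: np.random.Generator, n: int, n_genes: int, n_cpgs: int,
                 m: int):
    samples = tuple(f"s{i}" for i in range(n))
    expr = LocusMatrix(tuple(f"g{i}" for i in range(n_genes)), samples,
                       rng.standard_normal((n_genes, n)))
    meth = LocusMatrix(tuple(f"cg{i}" for i in range(n_cpgs)), samples,
                       rng.random((n_cpgs, n)))
    cov = CovariateTable(samples, tuple(f"c{j}" for j in range(m)),
                         rng.standard_normal((n, m)))
    return align_samples(expr, meth, cov)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_dataset(rng):
    """10 genes x 20 CpGs x 30 samples x 2 covariates."""
    return make_dataset(rng, 30, 10, 20, 2)
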