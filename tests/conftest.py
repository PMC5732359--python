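import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from maternalqg import GeneticArchitecture, simulate_pedigree

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mixed_arch() -> GeneticArchitecture:
    """Architecture with every pathway active and a positive covariance."""
    return GeneticArchitecture(v_ao=1.0, v_adee=1.0, cov_a=0.5, v_eo=1.0, v_edee=1.0)


@pytest.fixture(scope="session")
def neutral_pedigree(mixed_arch):
    """Neutral two-generation pedigree reused across estimation tests."""
    return simulate_pedigree(
        mixed_arch, n_families=3000, seed=20240911, offspring_per_pair=4
    )


def cov_se(var_x: float, var_y: float, cov: float, n: int) -> float:
    """Large-sample standard error of a bivariate-normal sample covariance."""
    return float(np.sqrt((var_x * var_y + cov**2) / n))
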