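import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from phagedepth.synthetic_data import SimConfig, generate_fixture  # noqa: E402


@pytest.fixture(scope="session")
def default_fixture():
    """The full study-design fixture (142 candidates, coverage + catalog)."""
    return generate_fixture(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """A small, fast fixture with every feature planted."""
    return generate_fixture(
        SimConfig(
            seed=7,
            n_contigs=16,
            n_short_contigs=3,
            n_no_structural=2,
            contaminant_count=1,
            n_amg_genes=4,
            contig_len_range=(20_000, 40_000),
            with_sequences=False,
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


from functools import lru_cache  # noqa: E402


@lru_cache(maxsize=32)
def recovery_fixture(seed: int):
    """Scaled-down coverage fixture for multi-seed parameter-recovery suites."""
    return generate_fixture(
        SimConfig(
            seed=seed,
            n_contigs=40,
            n_short_contigs=0,
            n_no_structural=0,
            contaminant_count=0,
            n_amg_genes=5,
            with_catalog=False,
            with_sequences=False,
        )
    )


@lru_cache(maxsize=128)
def catalog_fixture(seed: int, lysogeny_fold: float = 5.0, integrase_inflation: float = 1.0):
    """Catalog-only fixture (no contig coverage) for marker-profile recovery."""
    return generate_fixture(
        SimConfig(
            seed=seed,
            lysogeny_fold=lysogeny_fold,
            integrase_inflation=integrase_inflation,
            n_contigs=4,
            n_short_contigs=0,
            n_no_structural=0,
            contaminant_count=0,
            n_amg_genes=2,
            with_coverage=False,
            with_sequences=False,
        )
    )
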