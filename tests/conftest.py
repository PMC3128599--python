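import pytest
from hypothesis import HealthCheck, settings

from amap.synthetic_data import SimConfig, make_gene_fixture, simulate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TINY_SEGMENTS = (("6", 40, 30), ("6", 100, 12), ("15", 10, 11))


def tiny_config(seed: int = 1, **overrides) -> SimConfig:
    """A fast, down-scaled cohort: same pedigree design, fewer SNPs."""
    kwargs = dict(
        n_snps=4000,
        planted_segments=TINY_SEGMENTS,
        causal=("6", 12),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = tiny_config(seed=1)
    matrix, pedigree, truth = simulate_cohort(cfg)
    return cfg, matrix, pedigree, truth


@pytest.fixture(scope="session")
def gene_fixture():
    return make_gene_fixture(SimConfig(seed=0))
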