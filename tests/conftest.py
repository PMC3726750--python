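import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from estqc import SimConfig, simulate_genome, simulate_references
from estqc.simulate import ContaminantMix

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A fast 2-chromosome study with the default contaminant load."""
    return SimConfig(
        n_chromosomes=2, chrom_length=120_000, n_genes=30, est_count=150,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_config):
    return simulate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_refs(tiny_config):
    return simulate_references(tiny_config)


@pytest.fixture(scope="session")
def clean_run():
    """Error-free, contaminant-free, defect-free study: every genic EST is
    an exact spliced substring of the intact genome."""
    from estqc import derive_assembly, simulate_ests
    from estqc.pipeline import synthetic_align_params

    cfg = SimConfig(
        n_chromosomes=2, chrom_length=120_000, n_genes=40, est_count=120,
        est_error_rate=0.0, drop_fraction=0.0,
        contaminant_mix=ContaminantMix(0, 0, 0, 0, 0), seed=5,
    )
    genome, truth = simulate_genome(cfg)
    assembly = derive_assembly(genome, truth, cfg)
    refs = simulate_references(cfg)
    ests, truth = simulate_ests(genome, truth, refs, cfg)
    return cfg, genome, truth, assembly, ests, synthetic_align_params(cfg)
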