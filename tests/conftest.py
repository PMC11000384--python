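import numpy as np
import pytest
from hypothesis import settings

from mendelburden.synthetic import SimulationConfig, SubpopSpec, simulate_cohort

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_cohort():
    """Small two-subpopulation cohort with known designations.

    PAR-like group with substantial inbreeding and an outbred ADM-like
    reference; allele frequencies skewed common enough that recessive
    genotypes actually occur at n = 550.
    """
    cfg = SimulationConfig(
        seed=42,
        subpops=[SubpopSpec("PAR", 300, 0.03), SubpopSpec("ADM", 250, 0.0)],
        n_genes=25, n_variants=80,
        af_log10_min=-3.0, af_log10_max=-0.7,
        n_known_plp=20, n_novel_candidates=3, n_benign_common=3,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def demo_classified(demo_cohort):
    from mendelburden.catalog import classify_cohort

    _, cohort, _ = demo_cohort
    return classify_cohort(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
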