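import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """20-gene, error-free simulation with its annotation and truth."""
    from paika.synth import TailSimConfig, default_annotation, simulate_tailed_reads

    config = TailSimConfig(
        n_genes=20, reads_per_gene=30, base_error_rate=0.0, frac_no_tail=0.0, seed=3
    )
    annotation = default_annotation(
        config.n_genes, config.gene_body_len, frac_minus=config.frac_reverse, seed=config.seed
    )
    reads, truth = simulate_tailed_reads(config, annotation)
    return reads, truth, annotation
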