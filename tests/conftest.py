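import numpy as np
import pytest

from pqtlmeta import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_study():
    """Two small aligned cohorts with one planted pQTL and one censored analyte."""
    cfg = sim.SimConfig(
        seed=77,
        n1=120,
        n2=100,
        n_variants=12,
        analytes=[
            sim.AnalyteSpec(
                "ANA1", causal=[("rs000003", 0.30)], covariate_frac=0.10,
                gene_chromosome="1", gene_start=20_001, gene_end=25_000,
            ),
            sim.AnalyteSpec("ANA2", censor_quantile=0.30, covariate_frac=0.10),
        ],
    )
    return sim.simulate_study(cfg)
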