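import numpy as np
import pytest

from promlock import (
    DEFAULT_PARAMS,
    TranscriptionModelParams,
    generate_gene_universe,
)


@pytest.fixture(scope="session")
def default_params() -> TranscriptionModelParams:
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def simple_params() -> TranscriptionModelParams:
    """Unit-rate two-step model with an active lock channel."""
    return TranscriptionModelParams(
        k1=1.0, k_minus1=1.0, k2=1.0, k_cc=1.0, k_unlock=1.0, rna_delay=0.0
    )


@pytest.fixture(scope="session")
def gene_universe():
    """Fixture universe: 4452 genes, 306 sensitive, transient 10/70,
    long-term 0/35."""
    return generate_gene_universe(seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
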