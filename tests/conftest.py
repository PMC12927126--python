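import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emsmap

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tiny_config(**overrides):
    """A two-chromosome 400-kb genome that keeps every test fast.

    bp_per_cm is scaled with the physical map so a toy chromosome spans
    ~133 cM, as in the default configuration.
    """
    defaults = dict(
        chromosome_lengths={"chr1": 400_000, "chr2": 400_000},
        n_mutations=400,
        causal=emsmap.CausalSpec("chr1", 200_000),
        bp_per_cm=3_000.0,
        rng_seed=1,
    )
    defaults.update(overrides)
    return emsmap.SimulationConfig(**defaults)


@pytest.fixture
def tiny_config():
    return make_tiny_config()


@pytest.fixture(scope="session")
def tiny_dataset():
    """One shared small simulated dataset (seed 1)."""
    config = make_tiny_config()
    return emsmap.simulate_dataset(config, keep_reference=True)


@pytest.fixture
def toy_gene():
    """Single-exon plus-strand gene: ATG CAG GGC TGG TAA on chr1 at 101..115."""
    return emsmap.GeneModel(
        gene_id="toy1",
        chromosome="chr1",
        strand="+",
        cds_intervals=((101, 115),),
    )


@pytest.fixture
def toy_reference():
    """100 bp of padding, the toy gene CDS, then more padding."""
    pad5 = "A" * 100
    cds = "ATG" + "CAG" + "GGC" + "TGG" + "TAA"
    pad3 = "T" * 100
    return {"chr1": pad5 + cds + pad3}
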