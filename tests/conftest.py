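import numpy as np
import pytest

from craspseq import SimConfig, simulate_library
from craspseq.library_model import VectorLayout, build_reporter_model
from craspseq.simulate import default_reporter


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=5,
        guides_per_gene=4,
        n_intergenic=20,
        n_nontargeting=2,
        cbcs_per_guide=6,
        molecules_per_guide=50,
        duplication_rate=1.5,
        substitution_rate=0.0,
        true_effects={"G0001": 30.0, "G0002": -30.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return simulate_library(small_config)


@pytest.fixture(scope="session")
def reporter():
    return default_reporter()


@pytest.fixture(scope="session")
def layout():
    return VectorLayout(umi_length=10)


@pytest.fixture
def binary_reporter():
    rng = np.random.default_rng(99)
    up = "".join(rng.choice(list("ACGT"), 40))
    alt = "".join(rng.choice(list("ACGT"), 40))
    down = "".join(rng.choice(list("ACGT"), 40))
    return build_reporter_model(
        "toy",
        [
            {"label": "inclusion", "junction_seq": up + alt, "inclusion_like": True},
            {"label": "exclusion", "junction_seq": up + down, "inclusion_like": False},
        ],
        min_overhang=8,
    )
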