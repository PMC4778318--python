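import numpy as np
import pytest

from motiforient import (
    ExpressionConfig,
    ImplantSpec,
    IntervalSpec,
    Motif,
    SyntheticWorldConfig,
    UpstreamRegion,
)
from motiforient.synthetic import generate_world

# Asymmetric consensus with no overlap between its forward pattern and the
# reverse-complement pattern shifted against itself, so implanted hits map
# in their implanted orientation only.
CLEAN_MOTIF = "TTGACCGA"
CLEAN_MOTIF_2 = "CCGTTAGG"


@pytest.fixture(scope="session")
def oriented_world():
    """2000-gene world with one orientation-biased, position-confined motif
    and one orientation-neutral, uniformly placed motif; both drive
    co-expression modules (loading 0.5)."""
    cfg = SyntheticWorldConfig(
        n_genes=2000,
        seed=20240811,
        motif_implants=[
            ImplantSpec(
                Motif("BIASED", CLEAN_MOTIF),
                prob=0.15,
                fw_prob=0.8,
                bin_probs=(0, 0, 0, 0, 0, 0, 0, 0.3, 0.35, 0.35),
            ),
            ImplantSpec(
                Motif("NEUTRAL", CLEAN_MOTIF_2),
                prob=0.15,
                fw_prob=0.5,
                bin_probs=tuple([0.1] * 10),
            ),
        ],
        expression=ExpressionConfig(n_samples=200, loading=0.5, noise_sd=1.0),
    )
    return cfg, generate_world(cfg)


@pytest.fixture
def toy_regions():
    return [
        UpstreamRegion("g1", "ACGTACGTAC"),
        UpstreamRegion("g2", "AAAAACCCCC"),
    ]


@pytest.fixture
def full_interval():
    return IntervalSpec(-500, -1)
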