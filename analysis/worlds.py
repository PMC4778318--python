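"""Shared synthetic-world configurations for the numbered analysis drivers.

Three study conditions, mirroring the questions the pipeline answers:

* ``oriented_world`` — one motif implanted with an 80:20 forward bias,
  confined to the TSS-proximal third of the region, and tied to a
  co-expression module (loading 0.5); one orientation-neutral, uniformly
  placed motif with its own module.  2,000 genes x 500 nt x 200 samples.
* ``asymmetric_world`` — no implants; the proximal 100 nt follow a
  first-order Markov model with P(C|T) inflated to 0.31, creating the
  TC-over-GA strand directionality that the DOR profile should localise.
* ``paired_world_config`` — two motifs co-implanted with a dominant order
  and co-directional orientations, for the pair statistics.
"""

from __future__ import annotations

import numpy as np

from motiforient.catalog import Motif
from motiforient.synthetic import (
    ExpressionConfig,
    ImplantSpec,
    SyntheticWorldConfig,
    WindowModel,
    uniform_window,
)
from motiforient.upstream import IntervalSpec

BIASED = Motif("BIASED", "TTGACCGA")
NEUTRAL = Motif("NEUTRAL", "CCGTTAGG")


def oriented_world(seed: int = 1) -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        n_genes=2000,
        seed=seed,
        motif_implants=[
            ImplantSpec(BIASED, prob=0.15, fw_prob=0.8,
                        bin_probs=(0, 0, 0, 0, 0, 0, 0, 0.3, 0.35, 0.35)),
            ImplantSpec(NEUTRAL, prob=0.15, fw_prob=0.5,
                        bin_probs=tuple([0.1] * 10)),
        ],
        expression=ExpressionConfig(n_samples=200, loading=0.5, noise_sd=1.0),
    )


def asymmetric_world(seed: int = 1) -> SyntheticWorldConfig:
    biased = np.full((4, 4), 0.25)
    biased[3] = [0.25, 0.31, 0.25, 0.19]  # P(C|T) up, P(T|T) down
    return SyntheticWorldConfig(
        n_genes=800,
        seed=seed,
        window_models=[
            uniform_window(IntervalSpec(-500, -101)),
            WindowModel(IntervalSpec(-100, -1), biased, np.full(4, 0.25)),
        ],
    )


def null_world(seed: int = 1) -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        n_genes=150,
        seed=seed,
        expression=ExpressionConfig(n_samples=60, loading=0.0),
    )
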