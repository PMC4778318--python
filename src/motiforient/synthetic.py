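"""Ground-truth synthetic worlds: promoters, implants, expression.

The generator emulates the three data layers the pipeline consumes:

* promoter sequences — per-window first-order Markov models over A/C/G/T,
  so both zero-order skew (e.g. TSS-proximal C over G) and first-order
  directional asymmetry (e.g. an inflated P(C|T) driving the TC/GA
  dinucleotide orientation ratio) can be dialled in per upstream window;
* motif implants — a chosen consensus written into a configurable fraction
  of genes, forward with probability ``fw_prob`` else reverse-complemented,
  at positions drawn from a distribution over the 10 positional-entropy
  bins; implants overwrite sequence, keeping TSS-anchored coordinates;
* expression — a latent-factor model: genes carrying the same implanted
  motif share a standard-normal factor z with loading lambda, plus unit
  Gaussian noise, giving within-module pairwise correlation
  lambda^2 / (lambda^2 + noise_sd^2) in expectation.

Every generated quantity is recorded in a TruthTable so recovery tests can
compare pipeline output against construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import Motif, MotifSet, expand_variants, reverse_complement, write_catalog
from .coexpression import ExpressionMatrix
from .upstream import BASES, IntervalSpec, UpstreamRegion, write_upstream_fasta

__all__ = [
    "WindowModel",
    "ImplantSpec",
    "ExpressionConfig",
    "SyntheticWorldConfig",
    "TruthTable",
    "uniform_window",
    "synth_upstream",
    "implant_motifs",
    "synth_expression",
    "make_fixture",
    "load_fixture",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class WindowModel:
    """First-order Markov model for one upstream window."""

    interval: IntervalSpec
    transition: np.ndarray  # 4x4, rows = previous base, columns = next base
    initial: np.ndarray     # length-4 distribution of the window's first base

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


def uniform_window(interval: IntervalSpec) -> WindowModel:
    return WindowModel(interval, np.full((4, 4), 0.25), np.full(4, 0.25))


@dataclass
class ImplantSpec:
    motif: Motif
    prob: float                  # per-gene implantation probability
    fw_prob: float = 0.5         # forward-orientation probability
    bin_probs: Sequence[float] = tuple([0.1] * 10)  # positional bins, 5'-most first

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0 or not 0.0 <= self.fw_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.isclose(sum(self.bin_probs), 1.0, atol=1e-9):
            raise ValueError("positional bin distribution must sum to 1")


@dataclass
class ExpressionConfig:
    n_samples: int = 200
    loading: float = 0.5         # lambda, shared by all modules unless overridden
    noise_sd: float = 1.0
    per_motif_loading: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticWorldConfig:
    n_genes: int = 2000
    region_length: int = 500
    window_models: list[WindowModel] = field(default_factory=list)
    motif_implants: list[ImplantSpec] = field(default_factory=list)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_models:
            self.window_models = [
                uniform_window(IntervalSpec(-self.region_length, -1))
            ]
        covered = sum(w.interval.width for w in self.window_models)
        if covered != self.region_length:
            raise ValueError(
                f"window models cover {covered} nt, region is {self.region_length}"
            )


@dataclass
class Implant:
    motif_id: str
    variant: str        # concrete sequence written (already reverse-complemented if rc)
    orientation: str    # fw | rc
    start: int          # upstream position of the 5'-most written base


@dataclass
class TruthTable:
    implants: dict[str, list[Implant]] = field(default_factory=dict)
    modules: dict[str, list[str]] = field(default_factory=dict)  # motif -> genes

    def genes_with(self, motif_id: str, orientation: str | None = None) -> set[str]:
        return {
            g for g, imps in self.implants.items()
            if any(
                i.motif_id == motif_id
                and (orientation is None or i.orientation == orientation)
                for i in imps
            )
        }


def _sample_markov(rng: np.random.Generator, model: WindowModel, length: int) -> str:
    cum_init = np.cumsum(model.initial)
    cum_trans = np.cumsum(model.transition, axis=1)
    u = rng.random(length)
    idx = np.empty(length, dtype=np.int64)
    idx[0] = np.searchsorted(cum_init, u[0])
    for i in range(1, length):
        idx[i] = np.searchsorted(cum_trans[idx[i - 1]], u[i])
    return "".join(BASES[i] for i in idx)


def synth_upstream(
    config: SyntheticWorldConfig,
) -> tuple[list[UpstreamRegion], TruthTable]:
    """Generate promoter regions window-by-window, 5'->3'."""
    rng = np.random.default_rng(config.seed)
    windows = sorted(config.window_models, key=lambda w: w.interval.from_pos)
    regions = []
    for g in range(config.n_genes):
        parts = [_sample_markov(rng, w, w.interval.width) for w in windows]
        regions.append(UpstreamRegion(f"G{g:05d}", "".join(parts)))
    return regions, TruthTable()


def implant_motifs(
    regions: Sequence[UpstreamRegion],
    truth: TruthTable,
    config: SyntheticWorldConfig,
    max_tries: int = 20,
) -> tuple[list[UpstreamRegion], TruthTable]:
    """Write motif instances into sequences per the implant specs.

    A concrete variant (uniform over the consensus expansions) overwrites
    the sequence at a start position drawn from the positional-bin
    distribution, forward with probability ``fw_prob`` else as the reverse
    complement.  Sites overlapping earlier implants are re-drawn; a gene
    with no room after ``max_tries`` draws is skipped.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.region_length
    n_bins = 10
    bin_width = L // n_bins
    seqs = {r.gene_id: list(r.seq) for r in regions}
    occupied: dict[str, list[tuple[int, int]]] = {r.gene_id: [] for r in regions}

    for spec in config.motif_implants:
        variants = sorted(expand_variants(spec.motif.consensus))
        mlen = len(spec.motif.consensus)
        if mlen > bin_width:
            raise ValueError(
                f"motif {spec.motif.id} ({mlen} nt) does not fit a {bin_width}-nt bin"
            )
        bin_probs = np.asarray(spec.bin_probs, dtype=float)
        module_genes: list[str] = []
        for r in regions:
            if rng.random() >= spec.prob:
                continue
            placed = False
            for _ in range(max_tries):
                b = int(rng.choice(n_bins, p=bin_probs))
                off0 = b * bin_width + int(rng.integers(0, bin_width - mlen + 1))
                span = (off0, off0 + mlen - 1)
                if any(s <= span[1] and span[0] <= e for s, e in occupied[r.gene_id]):
                    continue
                variant = variants[rng.integers(len(variants))]
                fw = rng.random() < spec.fw_prob
                written = variant if fw else reverse_complement(variant)
                seqs[r.gene_id][off0:off0 + mlen] = list(written)
                occupied[r.gene_id].append(span)
                truth.implants.setdefault(r.gene_id, []).append(
                    Implant(
                        motif_id=spec.motif.id,
                        variant=written,
                        orientation="fw" if fw else "rc",
                        start=off0 - L,
                    )
                )
                module_genes.append(r.gene_id)
                placed = True
                break
            if not placed:
                pass  # gene skipped: no non-overlapping site available
        truth.modules[spec.motif.id] = module_genes

    new_regions = [UpstreamRegion(r.gene_id, "".join(seqs[r.gene_id])) for r in regions]
    return new_regions, truth


def synth_expression(
    truth: TruthTable,
    config: SyntheticWorldConfig,
    gene_ids: Sequence[str],
) -> ExpressionMatrix:
    """Latent-factor expression: x_gs = sum_f lambda_g z_fs + noise."""
    rng = np.random.default_rng(config.seed + 2)
    ec = config.expression
    n_g, n_s = len(gene_ids), ec.n_samples
    X = rng.normal(0.0, ec.noise_sd, size=(n_g, n_s))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for motif_id, genes in truth.modules.items():
        lam = ec.per_motif_loading.get(motif_id, ec.loading)
        if lam == 0 or not genes:
            continue
        z = rng.standard_normal(n_s)
        for g in genes:
            X[gene_index[g]] += lam * z
    df = pd.DataFrame(
        X, index=list(gene_ids), columns=[f"S{j:04d}" for j in range(n_s)]
    )
    return ExpressionMatrix(df)


def _truth_to_json(truth: TruthTable) -> dict:
    return {
        "implants": {
            g: [asdict(i) for i in imps] for g, imps in truth.implants.items()
        },
        "modules": truth.modules,
    }


def _truth_from_json(obj: dict) -> TruthTable:
    return TruthTable(
        implants={
            g: [Implant(**i) for i in imps] for g, imps in obj["implants"].items()
        },
        modules={k: list(v) for k, v in obj["modules"].items()},
    )


def _config_snapshot(config: SyntheticWorldConfig) -> dict:
    return {
        "n_genes": config.n_genes,
        "region_length": config.region_length,
        "seed": config.seed,
        "window_models": [
            {
                "interval": [w.interval.from_pos, w.interval.to_pos],
                "transition": w.transition.tolist(),
                "initial": w.initial.tolist(),
            }
            for w in config.window_models
        ],
        "motif_implants": [
            {
                "motif_id": s.motif.id,
                "consensus": s.motif.consensus,
                "prob": s.prob,
                "fw_prob": s.fw_prob,
                "bin_probs": list(s.bin_probs),
            }
            for s in config.motif_implants
        ],
        "expression": {
            "n_samples": config.expression.n_samples,
            "loading": config.expression.loading,
            "noise_sd": config.expression.noise_sd,
            "per_motif_loading": config.expression.per_motif_loading,
        },
    }


def config_from_snapshot(obj: dict) -> SyntheticWorldConfig:
    return SyntheticWorldConfig(
        n_genes=obj["n_genes"],
        region_length=obj["region_length"],
        seed=obj["seed"],
        window_models=[
            WindowModel(
                IntervalSpec(*w["interval"]),
                np.array(w["transition"]),
                np.array(w["initial"]),
            )
            for w in obj["window_models"]
        ],
        motif_implants=[
            ImplantSpec(
                Motif(s["motif_id"], s["consensus"]),
                s["prob"],
                s["fw_prob"],
                tuple(s["bin_probs"]),
            )
            for s in obj["motif_implants"]
        ],
        expression=ExpressionConfig(**obj["expression"]),
    )


def generate_world(
    config: SyntheticWorldConfig,
) -> tuple[list[UpstreamRegion], TruthTable, ExpressionMatrix]:
    """Sequences -> implants -> expression, all from one config."""
    regions, truth = synth_upstream(config)
    regions, truth = implant_motifs(regions, truth, config)
    expr = synth_expression(truth, config, [r.gene_id for r in regions])
    return regions, truth, expr


def make_fixture(name: str, config: SyntheticWorldConfig, out_dir: str | Path) -> Path:
    """Write a self-contained fixture directory (synthetic data).

    Contains upstream FASTA, motif catalog TSV, expression TSV, truth JSON
    and a config snapshot; re-running with the snapshot reproduces the
    fixture byte-identically.
    """
    target = Path(out_dir) / name
    target.mkdir(parents=True, exist_ok=True)
    regions, truth, expr = generate_world(config)
    write_upstream_fasta(regions, target / "upstream.fasta")
    catalog = MotifSet([s.motif for s in config.motif_implants], provenance=name)
    write_catalog(catalog, target / "motifs.tsv")
    expr.write_tsv(target / "expression.tsv")
    (target / "truth.json").write_text(json.dumps(_truth_to_json(truth), indent=1))
    (target / "config.json").write_text(json.dumps(_config_snapshot(config), indent=1))
    return target


def load_fixture(path: str | Path):
    """(regions, truth, expr, config) from a fixture directory."""
    from .upstream import read_upstream_fasta
    from .coexpression import read_expression_tsv

    p = Path(path)
    regions = read_upstream_fasta(p / "upstream.fasta")
    truth = _truth_from_json(json.loads((p / "truth.json").read_text()))
    expr = read_expression_tsv(p / "expression.tsv")
    config = config_from_snapshot(json.loads((p / "config.json").read_text()))
    return regions, truth, expr, config
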