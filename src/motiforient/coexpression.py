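"""Gene co-expression comparisons between motif-defined gene sets.

The functional read-out of the pipeline: if a motif (or a motif orientation,
or a motif-pair arrangement) matters for regulation, genes sharing it should
be more strongly co-expressed.  Co-expression of a gene set is summarised by
the sample of all pairwise Pearson correlation coefficients of the genes'
expression profiles; two sets are compared by a two-sided Wilcoxon rank-sum
test on the two correlation samples plus Cohen's d,

    d = (mean_a - mean_b) / sqrt((var_a + var_b) / 2).

The rank-sum test treats correlation pairs as independent observations, a
faithful reproduction of the original protocol rather than a statistical
endorsement (pairs sharing a gene are not independent; see docs/methods.md).
"""

from __future__ import annotations


import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import MappingTable
from .upstream import IntervalSpec

__all__ = [
    "ExpressionMatrix",
    "CoexpressionComparison",
    "read_expression_tsv",
    "pairwise_correlations",
    "cohens_d",
    "compare_sets",
    "build_presence_absence_sets",
    "build_orientation_sets",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression, genes x samples."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 samples")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def measurable(self, gene_ids: set[str] | Sequence[str]) -> list[str]:
        present = set(self.values.index)
        return sorted(g for g in set(gene_ids) if g in present)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """TSV with gene ids in the first column and a sample-id header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"non-numeric expression values in {path}")
    return ExpressionMatrix(df)


def pairwise_correlations(
    gene_set: Sequence[str] | set[str],
    expr: ExpressionMatrix,
    pair_cap: int = 500_000,
    seed: int = 0,
) -> np.ndarray:
    """Pairwise Pearson r among a gene set's expression profiles.

    Computes all C(n, 2) coefficients, or a seeded uniform subsample of
    ``pair_cap`` gene pairs when there are more.  Genes absent from the
    matrix are dropped with a log notice.
    """
    genes = expr.measurable(gene_set)
    n_dropped = len(set(gene_set)) - len(genes)
    if n_dropped:
        logger.info("dropped %d genes absent from expression matrix", n_dropped)
    n = len(genes)
    if n < 2:
        raise ValueError(f"need >= 2 measurable genes, have {n}")
    X = expr.values.loc[genes].to_numpy(dtype=float)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= pair_cap:
        C = np.corrcoef(X)
        iu = np.triu_indices(n, k=1)
        return C[iu]
    rng = np.random.default_rng(seed)
    # sample pair indices without replacement from the flattened triangle
    flat = rng.choice(n_pairs, size=pair_cap, replace=False)
    # invert the (i, j) -> k triangular enumeration
    i = (n - 2 - np.floor(
        np.sqrt(-8.0 * flat + 4 * n * (n - 1) - 7) / 2.0 - 0.5
    )).astype(np.int64)
    j = (flat + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2).astype(np.int64)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    return np.einsum("ij,ij->i", Xc[i], Xc[j]) / (norms[i] * norms[j])


def cohens_d(r_a: np.ndarray, r_b: np.ndarray) -> float:
    """Standardized mean difference with the average-variance denominator."""
    a = np.asarray(r_a, dtype=float)
    b = np.asarray(r_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty correlation sample")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    pooled = np.sqrt((va + vb) / 2.0)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class CoexpressionComparison:
    set_a: set[str]
    set_b: set[str]
    r_a: np.ndarray
    r_b: np.ndarray
    mean_r_a: float
    mean_r_b: float
    p_r_diff: float
    cohens_d: float
    n_pairs_a: int
    n_pairs_b: int


def compare_sets(
    set_a: Sequence[str] | set[str],
    set_b: Sequence[str] | set[str],
    expr: ExpressionMatrix,
    pair_cap: int = 500_000,
    seed: int = 0,
) -> CoexpressionComparison:
    """Wilcoxon rank-sum + Cohen's d between two sets' correlation samples.

    The test is exact for small tie-free samples and uses the tie-corrected
    normal approximation otherwise (scipy's Mann-Whitney U, two-sided).
    """
    r_a = pairwise_correlations(set_a, expr, pair_cap=pair_cap, seed=seed)
    r_b = pairwise_correlations(set_b, expr, pair_cap=pair_cap, seed=seed + 1)
    p = float(stats.mannwhitneyu(r_a, r_b, alternative="two-sided").pvalue)
    return CoexpressionComparison(
        set_a=set(set_a),
        set_b=set(set_b),
        r_a=r_a,
        r_b=r_b,
        mean_r_a=float(r_a.mean()),
        mean_r_b=float(r_b.mean()),
        p_r_diff=p,
        cohens_d=cohens_d(r_a, r_b),
        n_pairs_a=r_a.size,
        n_pairs_b=r_b.size,
    )


def build_presence_absence_sets(
    motif_id: str,
    interval: IntervalSpec,
    mapping: MappingTable,
    universe: Sequence[str] | set[str],
    min_neg: int = 100,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """(positive, negative) gene sets for the presence-vs-absence comparison.

    Positive: measurable genes with at least one hit in the interval in
    either orientation.  Negative: a seeded random sample of motif-free
    measurable genes of size max(|positive|, ``min_neg``).
    """
    universe = set(universe)
    positive = mapping.genes_with(motif_id, interval) & universe
    free = sorted(universe - mapping.genes_with(motif_id, interval))
    size = max(len(positive), min_neg)
    if len(free) < size:
        raise ValueError(
            f"motif {motif_id}: only {len(free)} motif-free genes available, "
            f"need {size} for the negative set"
        )
    rng = np.random.default_rng(seed)
    negative = set(rng.choice(free, size=size, replace=False).tolist())
    return positive, negative


def build_orientation_sets(
    motif_id: str, interval: IntervalSpec, mapping: MappingTable
) -> tuple[set[str], set[str]]:
    """(fw-only, rc-only) exclusive gene sets; both-orientation genes are
    excluded from both."""
    fw_only, rc_only, _both = mapping.exclusive_sets(motif_id, interval)
    return fw_only, rc_only
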