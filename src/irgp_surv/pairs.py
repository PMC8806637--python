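"""Construction of candidate immune-related gene pairs (IRGPs).

A gene pair (a, b) scores 1 in a sample when gene a is expressed more
highly than gene b in that same sample, else 0. Because the score
compares two genes within one sample, it is invariant to any strictly
increasing within-sample transform of the expression values — which is
what makes pair signatures portable across sequencing platforms and
normalisation pipelines.

The candidate-building funnel:

1. keep immune genes whose median absolute deviation (MAD) across
   samples exceeds a variability threshold (default 0.5);
2. form all unordered pairs of retained genes (canonical orientation:
   lexicographic by symbol) and score every sample;
3. drop near-constant pairs, where either score class reaches the
   prevalence bound (default 80%) of samples;
4. across platforms, keep only pairs that survive on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import ExpressionCohort

__all__ = [
    "FilterConfig",
    "PairIndicatorMatrix",
    "mad_filter",
    "pair_indicator",
    "build_pairs",
    "prevalence_filter",
    "intersect_pairs",
    "read_pair_matrix",
    "write_pair_matrix",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate-pair funnel.

    mad_threshold
        Genes with MAD strictly above this pass the variability screen.
        MAD is the bare median absolute deviation, without the 1.4826
        normal-consistency constant; set ``mad_scale_constant`` to True
        to apply it.
    prevalence_bound
        A pair is kept only when the majority score class occupies
        strictly less than this fraction of samples.
    mad_on_log2
        Compute MAD on a log2 scale even for linear-scale cohorts
        (indicators themselves are scale-free either way).
    """

    mad_threshold: float = 0.5
    prevalence_bound: float = 0.8
    mad_scale_constant: bool = False
    mad_on_log2: bool = True

    def __post_init__(self) -> None:
        if self.mad_threshold < 0:
            raise ValueError("mad_threshold must be >= 0")
        if not 0.5 < self.prevalence_bound <= 1.0:
            raise ValueError("prevalence_bound must lie in (0.5, 1]")


@dataclass
class PairIndicatorMatrix:
    """Binary pairs x samples matrix of gene-pair scores."""

    pairs: list[Pair]
    values: np.ndarray  # uint8, shape (n_pairs, n_samples)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("values shape does not match pairs x samples")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("pair indicators must be 0 or 1")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs")
        if any(a == b for a, b in self.pairs):
            raise ValueError("a pair must join two distinct genes")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{a}|{b}" for a, b in self.pairs]
        return pd.DataFrame(self.values, index=idx, columns=self.sample_ids)

    def subset_pairs(self, pairs) -> "PairIndicatorMatrix":
        pos = {p: i for i, p in enumerate(self.pairs)}
        rows = [pos[p] for p in pairs]
        return PairIndicatorMatrix(
            pairs=list(pairs), values=self.values[rows], sample_ids=self.sample_ids
        )

    def subset_samples(self, sample_ids) -> "PairIndicatorMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        return PairIndicatorMatrix(
            pairs=list(self.pairs), values=self.values[:, cols], sample_ids=list(sample_ids)
        )


def mad_filter(
    cohort: ExpressionCohort, immune_genes, config: FilterConfig = FilterConfig()
) -> list[str]:
    """Immune genes present in the cohort with MAD above the threshold.

    MAD is median(|x - median(x)|) across samples, computed per gene.
    """
    immune_genes = list(immune_genes)
    if not immune_genes:
        raise ValueError("immune gene list is empty")
    present = [g for g in immune_genes if g in cohort.values.index]
    if not present:
        raise ValueError(f"no immune genes found in cohort {cohort.platform!r}")
    x = cohort.values.loc[present].to_numpy(dtype=float)
    if config.mad_on_log2 and not cohort.log_scale:
        if (x < 0).any():
            raise ValueError("negative values on a linear-scale cohort")
        x = np.log2(x + 1.0)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1)
    if config.mad_scale_constant:
        mad = mad * 1.4826
    kept = [g for g, m in zip(present, mad) if m > config.mad_threshold]
    if not kept:
        raise ValueError(
            f"no genes exceed MAD threshold {config.mad_threshold} on "
            f"{cohort.platform!r}; consider lowering the threshold"
        )
    return kept


def pair_indicator(expr_a: float, expr_b: float) -> int:
    """1 when the first gene's expression strictly exceeds the second's."""
    if not (np.isfinite(expr_a) and np.isfinite(expr_b)):
        raise ValueError("pair indicator requires finite expression values")
    return int(expr_a > expr_b)


def build_pairs(cohort: ExpressionCohort, genes) -> PairIndicatorMatrix:
    """Score all unordered pairs of ``genes`` in every sample.

    Pairs are oriented lexicographically by symbol, so (a, b) with
    a < b and value 1 iff expr(a) > expr(b).
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("need at least two genes to build pairs")
    missing = [g for g in genes if g not in cohort.values.index]
    if missing:
        raise KeyError(f"genes absent from cohort: {missing[:5]}")
    expr = cohort.values.loc[genes].to_numpy(dtype=float)
    pair_list = list(combinations(genes, 2))
    pos = {g: i for i, g in enumerate(genes)}
    ia = np.fromiter((pos[a] for a, _ in pair_list), dtype=int)
    ib = np.fromiter((pos[b] for _, b in pair_list), dtype=int)
    values = (expr[ia] > expr[ib]).astype(np.uint8)
    return PairIndicatorMatrix(pairs=pair_list, values=values, sample_ids=cohort.sample_ids)


def prevalence_filter(
    m: PairIndicatorMatrix, config: FilterConfig = FilterConfig()
) -> PairIndicatorMatrix:
    """Drop pairs whose majority score class reaches the prevalence bound."""
    if m.n_pairs == 0:
        raise ValueError("empty pair matrix")
    frac_ones = m.values.mean(axis=1)
    majority = np.maximum(frac_ones, 1.0 - frac_ones)
    keep = majority < config.prevalence_bound
    if not keep.any():
        raise ValueError("no pairs survive the prevalence filter")
    kept_pairs = [p for p, k in zip(m.pairs, keep) if k]
    return PairIndicatorMatrix(
        pairs=kept_pairs, values=m.values[keep], sample_ids=m.sample_ids
    )


def intersect_pairs(matrices) -> list[Pair]:
    """Pairs retained on every platform, in the first matrix's order."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one pair matrix")
    common = set(matrices[0].pairs)
    for m in matrices[1:]:
        common &= set(m.pairs)
    if not common:
        raise ValueError("no pairs shared across all platforms")
    return [p for p in matrices[0].pairs if p in common]


def write_pair_matrix(m: PairIndicatorMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "pair"
    df.to_csv(path, sep="\t")


def read_pair_matrix(path) -> PairIndicatorMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    pairs = [tuple(p.split("|", 1)) for p in df.index]
    return PairIndicatorMatrix(
        pairs=pairs,
        values=df.to_numpy(dtype=np.uint8),
        sample_ids=[str(c) for c in df.columns],
    )
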