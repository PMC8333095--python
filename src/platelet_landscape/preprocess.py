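"""Depth QC, size-factor normalization, variance stabilization, expression filter.

The normalization follows the median-of-ratios scheme: a reference
pseudo-sample is formed from the per-gene geometric mean across samples
(restricted to genes with no zero count), and each sample's size factor is
the median of its count-to-reference ratios.  Counts are then placed on a
log2-like variance-stabilized scale via a shifted-log transform
``log2(count / factor + pseudocount)``, which is deterministic and
monotone, and approaches plain log2 of normalized counts for well-expressed
genes.  Genes whose mean transformed value is below a threshold (default 4)
in every sample group are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "resolve_groups",
    "filter_samples_by_depth",
    "size_factors",
    "vst",
    "filter_low_expression",
    "preprocess_counts",
]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Variance-stabilized expression values plus the size factors behind them."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # (n_genes, n_samples), float, log2-like scale
    size_factors: np.ndarray  # (n_samples,), > 0
    pseudocount: float = 1.0
    transform: str = "shifted-log2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        factors = np.asarray(self.size_factors, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match labels")
        if factors.shape != (len(self.sample_ids),):
            raise ValidationError("one size factor per sample required")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite normalized values")
        if not np.all(factors > 0):
            raise ValidationError("size factors must be strictly positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "size_factors", factors)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def linearized(self) -> np.ndarray:
        """Invert the shifted-log transform back to normalized counts."""
        return np.maximum(2.0 ** self.values - self.pseudocount, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def resolve_groups(
    sample_ids: Sequence[str], groups: Mapping[str, str] | pd.Series
) -> pd.Series:
    """Align a sample -> group mapping to a sample-ID order, validating coverage."""
    if isinstance(groups, pd.Series):
        mapping = groups.to_dict()
    else:
        mapping = dict(groups)
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValidationError(f"group labels missing for samples: {missing[:10]}")
    return pd.Series([mapping[s] for s in sample_ids], index=list(sample_ids), dtype=object)


def filter_samples_by_depth(counts: CountMatrix, min_reads: int = 100_000) -> CountMatrix:
    """Drop samples whose total read count is strictly below ``min_reads``.

    A sample with exactly ``min_reads`` reads is kept.  Removals are logged
    with sample IDs and totals; the gene set is unchanged.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = counts.column_sums()
    keep = totals >= min_reads
    if not keep.any():
        raise ValidationError("no samples pass depth filter")
    if not keep.all():
        removed = [
            (counts.sample_ids[i], int(totals[i])) for i in np.flatnonzero(~keep)
        ]
        logger.info("depth filter removed %d samples: %s", len(removed), removed)
    kept_ids = [s for s, k in zip(counts.sample_ids, keep) if k]
    return CountMatrix(counts.gene_ids, kept_ids, counts.counts[:, keep])


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    Reference genes are those with a strictly positive count in every
    sample; each sample's factor is the median over reference genes of
    count / (geometric mean of that gene across samples).
    """
    mat = counts.counts.astype(float)
    zero_free = (mat > 0).all(axis=1)
    if not zero_free.any():
        raise ValidationError("no reference genes for size factors")
    ref = mat[zero_free]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geo, axis=0))
    if not np.all(factors > 0):
        raise ValidationError("nonpositive size factor computed")
    return factors


def vst(
    counts: CountMatrix, factors: np.ndarray, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Shifted-log variance-stabilizing transform: log2(count/factor + pseudocount)."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValidationError("one size factor per sample required")
    if not np.all(factors > 0):
        raise ValidationError("size factors must be strictly positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.log2(counts.counts / factors[np.newaxis, :] + pseudocount)
    return NormalizedMatrix(
        counts.gene_ids, counts.sample_ids, values, factors, pseudocount=pseudocount
    )


def _group_means(
    values: np.ndarray, groups: pd.Series
) -> tuple[np.ndarray, list[str]]:
    levels = list(dict.fromkeys(groups))
    means = np.empty((values.shape[0], len(levels)))
    for j, level in enumerate(levels):
        mask = (groups == level).to_numpy()
        if not mask.any():
            raise ValidationError(f"empty group {level!r}")
        means[:, j] = values[:, mask].mean(axis=1)
    return means, levels


def filter_low_expression(
    norm: NormalizedMatrix,
    groups: Mapping[str, str] | pd.Series,
    threshold: float = 4.0,
) -> NormalizedMatrix:
    """Remove genes whose mean transformed value is < threshold in every group.

    The criterion is strict: a gene with mean exactly at the threshold in
    some group is kept.  Retained genes are unchanged, so the operation is
    idempotent.
    """
    grp = resolve_groups(norm.sample_ids, groups)
    means, _ = _group_means(norm.values, grp)
    keep = (means >= threshold).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "low-expression filter removed %d of %d genes", n_dropped, norm.n_genes
        )
    kept_ids = [g for g, k in zip(norm.gene_ids, keep) if k]
    return NormalizedMatrix(
        kept_ids,
        norm.sample_ids,
        norm.values[keep],
        norm.size_factors,
        pseudocount=norm.pseudocount,
        transform=norm.transform,
    )


def preprocess_counts(
    counts: CountMatrix,
    groups: Mapping[str, str] | pd.Series,
    *,
    min_reads: int = 100_000,
    low_expr_threshold: float = 4.0,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Full deterministic chain: depth filter -> size factors -> VST -> expression filter."""
    kept = filter_samples_by_depth(counts, min_reads=min_reads)
    factors = size_factors(kept)
    norm = vst(kept, factors, pseudocount=pseudocount)
    grp = resolve_groups(norm.sample_ids, groups)
    return filter_low_expression(norm, grp, threshold=low_expr_threshold)
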