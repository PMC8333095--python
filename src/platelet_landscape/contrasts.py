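"""Per-gene group contrasts: fold changes, Welch t-tests with BH FDR,
Pearson age correlation, and top-N ranking overlap."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import ValidationError
from .preprocess import NormalizedMatrix, resolve_groups

logger = logging.getLogger(__name__)

__all__ = [
    "fold_change",
    "group_ttest",
    "bh_adjust",
    "age_correlation",
    "top_n_overlap",
]

#: |r| beyond which an age correlation is flagged as notable.
NOTABLE_R = 0.3


def _two_group_masks(
    norm: NormalizedMatrix,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
) -> tuple[np.ndarray, np.ndarray]:
    grp = resolve_groups(norm.sample_ids, groups)
    mask_a = (grp == group_a).to_numpy()
    mask_b = (grp == group_b).to_numpy()
    if not mask_a.any():
        raise ValidationError(f"group {group_a!r} is empty")
    if not mask_b.any():
        raise ValidationError(f"group {group_b!r} is empty")
    return mask_a, mask_b


def fold_change(
    norm: NormalizedMatrix,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    mode: str = "linear",
) -> pd.Series:
    """Mean-based fold change of group A over group B, per gene.

    ``mode='linear'`` (default) takes the ratio of arithmetic group means of
    linearized normalized expression; ``mode='log'`` exponentiates the
    difference of group means on the log2 scale.  A zero group-B mean yields
    +inf rather than an error.
    """
    mask_a, mask_b = _two_group_masks(norm, groups, group_a, group_b)
    if mode == "linear":
        lin = norm.linearized()
        mean_a = lin[:, mask_a].mean(axis=1)
        mean_b = lin[:, mask_b].mean(axis=1)
    elif mode == "log":
        mean_a = 2.0 ** norm.values[:, mask_a].mean(axis=1)
        mean_b = 2.0 ** norm.values[:, mask_b].mean(axis=1)
    else:
        raise ValueError(f"unknown fold-change mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
    fc = np.where(mean_b == 0, np.where(mean_a == 0, 1.0, np.inf), fc)
    return pd.Series(fc, index=list(norm.gene_ids), name="fc")


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_ttest(
    norm: NormalizedMatrix,
    groups: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    fc_mode: str = "linear",
) -> pd.DataFrame:
    """Two-sided Welch t-test per gene on transformed values, with BH FDR.

    Degenerate genes (zero variance in both groups) get p = 1 when the group
    means agree and p = 0 with a warning flag when they differ; the flag
    column records the convention used.
    """
    mask_a, mask_b = _two_group_masks(norm, groups, group_a, group_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("each group needs >= 2 samples for a t-test")
    xa = norm.values[:, mask_a]
    xb = norm.values[:, mask_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)

    flags = np.full(norm.n_genes, "", dtype=object)
    degenerate = (xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)
    equal_means = np.isclose(xa.mean(axis=1), xb.mean(axis=1))
    eq = degenerate & equal_means
    ne = degenerate & ~equal_means
    p[eq] = 1.0
    t_stat[eq] = 0.0
    if ne.any():
        logger.warning(
            "%d genes have zero variance in both groups with unequal means; "
            "p set to 0 by convention",
            int(ne.sum()),
        )
        p[ne] = 0.0
        t_stat[ne] = np.where(xa.mean(axis=1)[ne] > xb.mean(axis=1)[ne], np.inf, -np.inf)
    flags[eq] = "degenerate_equal"
    flags[ne] = "degenerate_unequal"

    q = bh_adjust(p)
    fc = fold_change(norm, groups, group_a, group_b, mode=fc_mode)
    return pd.DataFrame(
        {
            "gene": list(norm.gene_ids),
            "fc": fc.to_numpy(),
            "t_stat": t_stat,
            "p_value": p,
            "q_value": q,
            "flag": flags,
        }
    ).set_index("gene")


def age_correlation(
    norm: NormalizedMatrix, ages: Sequence[float] | pd.Series
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with donor age.

    Genes with constant expression have no defined correlation; they are
    flagged missing and excluded from the BH family size rather than being
    reported as zero.  Genes with |r| > 0.3 are flagged notable.
    """
    if isinstance(ages, pd.Series):
        ages = ages.reindex(list(norm.sample_ids)).to_numpy()
    ages = np.asarray(ages, dtype=float)
    n = norm.n_samples
    if ages.shape != (n,):
        raise ValidationError("one age per sample required")
    if n < 3:
        raise ValidationError("need >= 3 samples for correlation")
    if np.ptp(ages) == 0:
        raise ValidationError("ages are all equal; correlation undefined")

    x = norm.values
    xc = x - x.mean(axis=1, keepdims=True)
    ac = ages - ages.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sa = np.sqrt((ac**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ ac) / (sx * sa)
    constant = sx == 0
    r = np.clip(r, -1.0, 1.0)
    r[constant] = np.nan

    p = np.full(norm.n_genes, np.nan)
    ok = ~constant
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[ok] * np.sqrt((n - 2) / np.maximum(1.0 - r[ok] ** 2, 0.0))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    perfect = ok & (np.abs(r) == 1.0)
    p[perfect] = 0.0

    q = np.full(norm.n_genes, np.nan)
    q[ok] = bh_adjust(p[ok])
    return pd.DataFrame(
        {
            "gene": list(norm.gene_ids),
            "r": r,
            "p_value": p,
            "q_value": q,
            "notable": (np.abs(r) > NOTABLE_R) & ok,
            "missing": constant,
        }
    ).set_index("gene")


def top_n_overlap(
    ranking_a: Sequence[str], ranking_b: Sequence[str], n: int = 1000
) -> float:
    """Fraction of shared genes between the top-n prefixes of two rankings."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    if len(ranking_a) < n or len(ranking_b) < n:
        raise ValueError(
            f"n={n} exceeds ranking length ({len(ranking_a)}, {len(ranking_b)})"
        )
    return len(set(ranking_a[:n]) & set(ranking_b[:n])) / n
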