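"""Ward D2 hierarchical clustering of sample vectors and cluster contrasts.

Samples are clustered on Euclidean distances between their transformed
expression vectors.  The Ward D2 criterion operates on squared distances
through the Lance-Williams recurrence and reports square-root merge
heights, so merge heights are nondecreasing.  The study-level use is a
two-cluster cut followed by a fold-change-thresholded contrast between the
clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .contrasts import group_ttest
from .io_tables import ValidationError
from .preprocess import NormalizedMatrix, resolve_groups

logger = logging.getLogger(__name__)

__all__ = ["LinkageTree", "ward_d2_linkage", "cut_tree", "cluster_contrast", "ClusterContrast"]


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history in SciPy's 4-column linkage encoding."""

    merges: np.ndarray  # (n-1, 4): left, right, height, cluster size
    leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        merges = np.asarray(self.merges, dtype=float)
        if merges.shape != (len(self.leaves) - 1, 4):
            raise ValidationError("linkage must have n-1 merges for n leaves")
        object.__setattr__(self, "merges", merges)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        )


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    if dist.shape[0] < 2:
        raise ValidationError("need >= 2 samples")
    if not np.allclose(dist, dist.T, rtol=1e-10, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValidationError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    return dist


def ward_d2_linkage(dist: np.ndarray, sample_ids: list[str] | None = None) -> LinkageTree:
    """Ward D2 linkage from a precomputed distance matrix.

    Heights follow the square-root convention: merging singletons i, j
    occurs at d(i, j), and subsequent heights obey the Lance-Williams
    update on squared distances.  On Euclidean input this matches the
    ward.D2 convention of the standard R implementation.
    """
    dist = _validate_distance_matrix(dist)
    n = dist.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if len(sample_ids) != n:
        raise ValidationError("sample_ids length must match distance matrix")
    condensed = squareform(dist, checks=False)
    merges = hierarchy.linkage(condensed, method="ward")
    return LinkageTree(merges, tuple(sample_ids))


def cut_tree(tree: LinkageTree, k: int) -> pd.Series:
    """Cut the linkage into k clusters; labels 1..k ordered by first leaf occurrence."""
    n = len(tree.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return pd.Series(labels, index=list(tree.leaves), name="cluster")


@dataclass(frozen=True)
class ClusterContrast:
    """Fold-change-thresholded contrast between two sample clusters."""

    genes: tuple[str, ...]  # genes at >= fc_threshold (either direction)
    table: pd.DataFrame  # full per-gene contrast (fc is hot over cold)
    frac_below_twofold: float
    n_threefold: int
    n_fourfold: int
    hot_cluster: int  # cluster with the higher mean over the contrast gene set
    fc_threshold: float


def cluster_contrast(
    norm: NormalizedMatrix,
    assignment: Mapping[str, int] | pd.Series,
    fc_threshold: float = 4.0,
) -> ClusterContrast:
    """Genes separating two clusters at a fold-change threshold, with summaries.

    Returns the genes whose mean-based fold change between the clusters is
    >= fc_threshold or <= 1/fc_threshold together with the full contrast
    table, the fraction of genes below twofold, and the counts at three-
    and fourfold.  Fold changes are reported with the "hot" cluster (the
    one with the higher mean over the selected gene set) in the numerator.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    grp = resolve_groups(norm.sample_ids, assignment)
    levels = sorted(set(grp))
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 clusters required, got {levels}")
    for level in levels:
        if (grp == level).sum() < 2:
            raise ValidationError(f"cluster {level!r} has < 2 samples")

    grp_str = grp.astype(str)
    a, b = str(levels[0]), str(levels[1])
    table = group_ttest(norm, grp_str, a, b)
    fc = table["fc"].to_numpy()
    with np.errstate(divide="ignore"):
        folded = np.maximum(fc, 1.0 / fc)  # direction-free effect size

    selected = folded >= fc_threshold
    genes = tuple(g for g, s in zip(norm.gene_ids, selected) if s)

    # Orient the contrast so the cluster upregulated in the selected set is
    # the numerator ("hot"); with an empty selection keep the first cluster.
    if len(genes) and np.median(fc[selected]) < 1.0:
        hot = int(levels[1])
        table = group_ttest(norm, grp_str, b, a)
    else:
        hot = int(levels[0])

    return ClusterContrast(
        genes=genes,
        table=table,
        frac_below_twofold=float((folded < 2.0).mean()),
        n_threefold=int((folded >= 3.0).sum()),
        n_fourfold=int((folded >= 4.0).sum()),
        hot_cluster=hot,
        fc_threshold=float(fc_threshold),
    )
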