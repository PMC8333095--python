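"""Multivariate sample-vector variability tests.

Each donor's transcriptome is treated as a single vector in gene space and
groups of donors are compared as point clouds, using three complementary
two-sample tests:

* ``ks_mst_test`` — difference in multivariate location: samples are ranked
  by a deterministic depth-first traversal of the minimum spanning tree
  (MST) of the between-sample distance graph, and a Kolmogorov-Smirnov
  statistic compares the two groups' cumulative membership along that
  ranking (the Friedman-Rafsky "radial" variant).
* ``ww_runs_test`` — difference in multivariate spread/distribution: the
  multivariate generalization of the Wald-Wolfowitz runs test, whose
  statistic is one plus the number of MST edges joining differently
  labelled samples; few mixed edges mean separated groups.
* ``similarity_permutation_test`` — difference in within-group tightness:
  each group's similarity is the median of reciprocals of all within-group
  pairwise Euclidean distances, and the group difference is tested against
  its permutation distribution.

All p-values come from relabelling permutations with group sizes fixed.
When the label space is small enough the tests enumerate every labelling
and report the exact p-value; otherwise they sample ``n_perm`` labellings
and use the add-one estimator (b + 1) / (n_perm + 1), which can never be
exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_tables import ValidationError
from .preprocess import NormalizedMatrix, resolve_groups

logger = logging.getLogger(__name__)

__all__ = [
    "MstGraph",
    "MvTestResult",
    "SimilarityResult",
    "euclidean_distance_matrix",
    "minimum_spanning_tree",
    "mst_ks_ranking",
    "ww_runs_test",
    "ks_mst_test",
    "group_similarity",
    "similarity_permutation_test",
    "adjust_alpha",
    "run_table1_battery",
    "AGE_DIVISIONS",
]

#: Labellings up to this count are enumerated exhaustively instead of sampled.
MAX_EXACT_LABELINGS = 20_000


@dataclass(frozen=True)
class MstGraph:
    """Minimum spanning tree over sample vectors."""

    nodes: tuple[str, ...]
    edges: np.ndarray  # (n-1, 2) int indices into nodes, u < v
    weights: np.ndarray  # (n-1,) nonnegative

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        for (u, v), w in zip(self.edges, self.weights):
            g.add_edge(int(u), int(v), weight=float(w))
        return g


@dataclass(frozen=True)
class MvTestResult:
    """Outcome of one multivariate two-sample permutation test."""

    test_name: str  # ks_mst | ww_runs | similarity
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    exact: bool = False


@dataclass(frozen=True)
class SimilarityResult:
    """Within-group similarity comparison (median reciprocal distance)."""

    similarity_per_group: dict[str, float]
    observed_diff: float
    p_value: float
    n_perm: int
    seed: int
    exact: bool = False


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


def euclidean_distance_matrix(norm: NormalizedMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample vectors over all genes."""
    from scipy.spatial.distance import pdist, squareform

    if norm.n_samples < 2:
        raise ValidationError("need >= 2 samples")
    dist = squareform(pdist(norm.values.T, metric="euclidean"))
    ids = list(norm.sample_ids)
    return pd.DataFrame(dist, index=ids, columns=ids)


def _as_dist_and_ids(
    dist: pd.DataFrame | np.ndarray, sample_ids: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, pd.DataFrame):
        ids = [str(s) for s in dist.index]
        mat = dist.to_numpy()
    else:
        mat = np.asarray(dist, dtype=float)
        ids = (
            [str(s) for s in sample_ids]
            if sample_ids is not None
            else [str(i) for i in range(mat.shape[0])]
        )
    return _validate_distance_matrix(mat), ids


def minimum_spanning_tree(
    dist: pd.DataFrame | np.ndarray, sample_ids: Sequence[str] | None = None
) -> MstGraph:
    """MST of the complete between-sample distance graph (Kruskal).

    Edges are inserted in lexicographic node-pair order, so equal-weight
    ties resolve deterministically to the smallest pair.
    """
    mat, ids = _as_dist_and_ids(dist, sample_ids)
    n = mat.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=float(mat[i, j]))
    tree = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted((min(u, v), max(u, v)) for u, v in tree.edges)
    weights = np.array([mat[u, v] for u, v in edges])
    return MstGraph(tuple(ids), np.array(edges, dtype=int), weights)


def mst_ks_ranking(mst: MstGraph) -> np.ndarray:
    """Deterministic node ranking for the MST-KS statistic.

    The tree is rooted at a node of maximal (hop-count) eccentricity,
    breaking ties by smallest index, and ranked by depth-first preorder
    with children visited in decreasing subtree-height order, ties again
    to the smallest index.
    """
    n = len(mst.nodes)
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in mst.edges:
        adj[int(u)].append(int(v))
        adj[int(v)].append(int(u))

    tree = mst.to_networkx()
    ecc = nx.eccentricity(tree)
    root = min(range(n), key=lambda i: (-ecc[i], i))

    # subtree heights (in edges) via post-order from the root
    parent = np.full(n, -1, dtype=int)
    order: list[int] = []
    stack = [root]
    seen = np.zeros(n, dtype=bool)
    seen[root] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    height = np.zeros(n, dtype=int)
    for u in reversed(order):
        if parent[u] >= 0:
            height[parent[u]] = max(height[parent[u]], height[u] + 1)

    ranking: list[int] = []
    stack = [root]
    visited = np.zeros(n, dtype=bool)
    visited[root] = True
    while stack:
        u = stack.pop()
        ranking.append(u)
        children = [v for v in adj[u] if not visited[v]]
        # reversed so the largest-height / smallest-index child pops first
        children.sort(key=lambda v: (-height[v], v), reverse=True)
        for v in children:
            visited[v] = True
            stack.append(v)
    return np.array(ranking, dtype=int)


def _resolve_two_groups(
    ids: list[str], labels: Mapping[str, str] | pd.Series | Sequence[str]
) -> tuple[np.ndarray, str, str]:
    """Boolean membership of group A (first level in sorted order)."""
    if isinstance(labels, (pd.Series, Mapping)):
        lab = resolve_groups(ids, labels).to_numpy()
    else:
        lab = np.asarray(list(labels), dtype=object)
        if lab.shape != (len(ids),):
            raise ValidationError("one label per sample required")
    levels = sorted(set(lab))
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {levels}")
    return lab == levels[0], str(levels[0]), str(levels[1])


def _canonical_order(ids: list[str]) -> np.ndarray:
    return np.argsort(np.array(ids, dtype=object))


def _label_matrix(
    n: int, n_a: int, n_perm: int, seed: int
) -> tuple[np.ndarray, bool]:
    """Boolean (m, n) labelling matrix: exhaustive if feasible, else sampled."""
    total = math.comb(n, n_a)
    if total <= MAX_EXACT_LABELINGS:
        mat = np.zeros((total, n), dtype=bool)
        for i, comb in enumerate(combinations(range(n), n_a)):
            mat[i, list(comb)] = True
        return mat, True
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_perm, n), dtype=bool)
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    rows = np.repeat(np.arange(n_perm), n_a)
    mat[rows, picks.ravel()] = True
    return mat, False


def _ww_statistic(
    labels_a: np.ndarray, edges: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Run count R = mixed MST edges + 1, plus the total mixed-edge weight.

    R is the reported statistic.  The weight is used only as a tie-break
    when counting permutation exceedances: R is a small integer with heavy
    ties, and among labellings with equal R the one whose between-group
    edges are longer is the stronger separation (distant clouds connect
    through long bridge edges).  The continuous secondary keeps the
    permutation test near its nominal level.
    """
    mixed = labels_a[..., edges[:, 0]] != labels_a[..., edges[:, 1]]
    return mixed.sum(axis=-1) + 1, mixed @ weights


def _ks_statistic(
    labels_a: np.ndarray, ranking: np.ndarray, n_a: int, n_b: int
) -> tuple[np.ndarray, np.ndarray]:
    """Prefix discrepancy of cumulative group membership along the ranking.

    Returns the max discrepancy D (the reported statistic) and the mean
    prefix discrepancy, used only as a tie-break when counting permutation
    exceedances: D lives on a coarse grid (multiples of ~1/min(n_a, n_b)),
    and ranking tied labellings by the continuous secondary criterion keeps
    the permutation test close to its nominal level instead of lumping
    whole atoms into the p-value.
    """
    a = labels_a[..., ranking]
    cum_a = np.cumsum(a, axis=-1) / n_a
    cum_b = np.cumsum(~a, axis=-1) / n_b
    disc = np.abs(cum_a - cum_b)
    return disc.max(axis=-1), disc.mean(axis=-1)


def _lex_geq(
    primary: np.ndarray, secondary: np.ndarray, obs_primary: float, obs_secondary: float
) -> np.ndarray:
    tol = 1e-12
    tied = np.abs(primary - obs_primary) <= tol
    return (primary > obs_primary + tol) | (tied & (secondary >= obs_secondary - tol))


def ww_runs_test(
    dist: pd.DataFrame | np.ndarray,
    labels: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> MvTestResult:
    """Multivariate Wald-Wolfowitz runs test on the MST.

    The statistic is the run count R (mixed MST edges + 1); small values
    indicate group separation, so the p-value is the one-sided permutation
    probability of R' <= R.
    """
    mat, ids = _as_dist_and_ids(dist, sample_ids)
    is_a, _, _ = _resolve_two_groups(ids, labels)
    order = _canonical_order(ids)
    mat = mat[np.ix_(order, order)]
    is_a = is_a[order]
    n = mat.shape[0]
    n_a = int(is_a.sum())
    if n_a < 2 or n - n_a < 2:
        raise ValidationError("both groups need >= 2 samples")

    mst = minimum_spanning_tree(mat)
    obs, obs_w = _ww_statistic(is_a, mst.edges, mst.weights)
    obs, obs_w = int(obs), float(obs_w)
    perms, exact = _label_matrix(n, n_a, n_perm, seed)
    r_perm, w_perm = _ww_statistic(perms, mst.edges, mst.weights)
    tol = 1e-12
    exceed = (r_perm < obs) | ((r_perm == obs) & (w_perm >= obs_w - tol))
    if exact:
        p = float(exceed.sum() / len(perms))
    else:
        p = (int(exceed.sum()) + 1) / (n_perm + 1)
    return MvTestResult("ww_runs", float(obs), p, len(perms), seed, exact)


def ks_mst_test(
    dist: pd.DataFrame | np.ndarray,
    labels: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> MvTestResult:
    """MST-KS two-sample test of multivariate means.

    Samples are ranked by the deterministic MST traversal of
    :func:`mst_ks_ranking`; the statistic D is the maximal prefix
    discrepancy between the groups' cumulative membership fractions, and
    the p-value is the one-sided permutation probability of D' >= D.
    """
    mat, ids = _as_dist_and_ids(dist, sample_ids)
    is_a, _, _ = _resolve_two_groups(ids, labels)
    order = _canonical_order(ids)
    mat = mat[np.ix_(order, order)]
    is_a = is_a[order]
    n = mat.shape[0]
    n_a = int(is_a.sum())
    if n_a < 1 or n - n_a < 1:
        raise ValidationError("both groups must be nonempty")

    mst = minimum_spanning_tree(mat)
    ranking = mst_ks_ranking(mst)
    obs, obs_mean = _ks_statistic(is_a, ranking, n_a, n - n_a)
    obs, obs_mean = float(obs), float(obs_mean)
    perms, exact = _label_matrix(n, n_a, n_perm, seed)
    d_perm, m_perm = _ks_statistic(perms, ranking, n_a, n - n_a)
    exceed = _lex_geq(d_perm, m_perm, obs, obs_mean)
    if exact:
        p = float(exceed.sum() / len(perms))
    else:
        p = (int(exceed.sum()) + 1) / (n_perm + 1)
    return MvTestResult("ks_mst", obs, p, len(perms), seed, exact)


def group_similarity(
    dist: pd.DataFrame | np.ndarray,
    members: Sequence[str] | Sequence[int],
    sample_ids: Sequence[str] | None = None,
) -> float:
    """Within-group similarity: median of 1/d over all member pairs.

    Duplicate vectors (zero pairwise distance) make the reciprocal
    undefined and are a hard error naming the offending pair.
    """
    mat, ids = _as_dist_and_ids(dist, sample_ids)
    if len(members) and isinstance(members[0], str):
        idx = np.array([ids.index(m) for m in members], dtype=int)
    else:
        idx = np.asarray(members, dtype=int)
    if len(idx) < 2:
        raise ValidationError("need >= 2 group members")
    sub = mat[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    pairs = sub[iu]
    if np.any(pairs == 0):
        k = int(np.flatnonzero(pairs == 0)[0])
        u, v = iu[0][k], iu[1][k]
        raise ValidationError(
            f"zero within-group distance between {ids[idx[u]]!r} and "
            f"{ids[idx[v]]!r}; reciprocal similarity undefined"
        )
    return float(np.median(1.0 / pairs))


def similarity_permutation_test(
    dist: pd.DataFrame | np.ndarray,
    labels: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> SimilarityResult:
    """Permutation test on the difference of within-group median similarities.

    Two-sided: the p-value is the permutation probability of
    |diff'| >= |observed diff| under random relabelling with group sizes
    fixed.
    """
    mat, ids = _as_dist_and_ids(dist, sample_ids)
    is_a, level_a, level_b = _resolve_two_groups(ids, labels)
    order = _canonical_order(ids)
    mat = mat[np.ix_(order, order)]
    is_a = is_a[order]
    ids_sorted = [ids[i] for i in order]
    n = mat.shape[0]
    n_a = int(is_a.sum())
    if n_a < 2 or n - n_a < 2:
        raise ValidationError("both groups need >= 2 samples")

    sim_a = group_similarity(mat, np.flatnonzero(is_a), ids_sorted)
    sim_b = group_similarity(mat, np.flatnonzero(~is_a), ids_sorted)
    observed = sim_a - sim_b

    iu, iv = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        recip = 1.0 / mat[iu, iv]

    perms, exact = _label_matrix(n, n_a, n_perm, seed)
    diffs = np.empty(len(perms))
    for i in range(len(perms)):
        a = perms[i]
        within_a = a[iu] & a[iv]
        within_b = ~a[iu] & ~a[iv]
        diffs[i] = np.median(recip[within_a]) - np.median(recip[within_b])
    if exact:
        p = float((np.abs(diffs) >= abs(observed)).sum() / len(perms))
    else:
        b = int((np.abs(diffs) >= abs(observed) - 1e-15).sum())
        p = (b + 1) / (n_perm + 1)
    return SimilarityResult(
        {level_a: sim_a, level_b: sim_b}, observed, p, len(perms), seed, exact
    )


def adjust_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


# Age groupings used when scanning donor age as a variability factor:
# decade-style bins, a three-way division, and a median split.
AGE_DIVISIONS: dict[str, tuple[float, ...]] = {
    "age_division_1": (30.0, 40.0, 50.0, 60.0),
    "age_division_2": (40.0, 60.0),
    "age_median": (42.5,),
}


def _bin_ages(ages: pd.Series, edges: tuple[float, ...]) -> pd.Series:
    """Label ages by half-open bins (<= first edge, (e_i, e_{i+1}], > last edge)."""
    labels = []
    for a in ages:
        placed = None
        for i, e in enumerate(edges):
            if a <= e:
                if i == 0:
                    placed = f"<={e:g}"
                else:
                    placed = f"{edges[i - 1]:g}-{e:g}"
                break
        if placed is None:
            placed = f">{edges[-1]:g}"
        labels.append(placed)
    return pd.Series(labels, index=ages.index, dtype=object)


def run_table1_battery(
    norm: NormalizedMatrix,
    samples: pd.DataFrame,
    cluster: Mapping[str, int] | pd.Series | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    age_divisions: Mapping[str, tuple[float, ...]] | None = None,
    bonferroni_factors: frozenset[str] = frozenset({"libsize_batch"}),
) -> pd.DataFrame:
    """Run all three vector tests for every factor and pairwise comparison.

    Factors: sex, the age divisions, storage group, cluster assignment (if
    given), and library-size batch.  The per-comparison threshold is alpha,
    Bonferroni-divided by the number of pairwise comparisons for factors in
    ``bonferroni_factors`` (by default the three library-size pairs, giving
    0.05 / 3 = 0.0167).  Factor levels with fewer than 2 samples are
    skipped with a warning.
    """
    ids = list(norm.sample_ids)
    dist = euclidean_distance_matrix(norm)
    meta = samples.set_index("sample_id").loc[ids]
    if age_divisions is None:
        age_divisions = AGE_DIVISIONS

    factors: dict[str, pd.Series] = {"sex": meta["sex"]}
    for name, edges in age_divisions.items():
        factors[name] = _bin_ages(meta["age_years"], tuple(edges))
    factors["storage_group"] = meta["storage_group"]
    if cluster is not None:
        factors["cluster"] = resolve_groups(ids, cluster).astype(str)
    factors["libsize_batch"] = meta["libsize_batch"].astype(str)

    rows = []
    comp_index = 0
    for factor, labels in factors.items():
        counts = labels.value_counts()
        usable = sorted(counts[counts >= 2].index)
        skipped = sorted(set(labels) - set(usable))
        if skipped:
            logger.warning("factor %s: levels %s have < 2 samples; skipped", factor, skipped)
        pairs = list(combinations(usable, 2))
        m = len(pairs) if factor in bonferroni_factors else 1
        threshold = adjust_alpha(alpha, m) if pairs else alpha
        for a, b in pairs:
            mask = labels.isin([a, b])
            sub_ids = [s for s in ids if mask[s]]
            sub = dist.loc[sub_ids, sub_ids]
            sub_labels = labels[sub_ids]
            seeds = [
                int(np.random.SeedSequence([seed, comp_index, t]).generate_state(1)[0] % 2**31)
                for t in range(3)
            ]
            comp_index += 1
            try:
                ks = ks_mst_test(sub, sub_labels, n_perm=n_perm, seed=seeds[0])
                ww = ww_runs_test(sub, sub_labels, n_perm=n_perm, seed=seeds[1])
                sim = similarity_permutation_test(sub, sub_labels, n_perm=n_perm, seed=seeds[2])
            except ValidationError as err:
                logger.warning("factor %s %s vs %s skipped: %s", factor, a, b, err)
                continue
            rows.append(
                {
                    "factor": factor,
                    "comparison": f"{a} vs {b}",
                    "p_ks": ks.p_value,
                    "p_ww": ww.p_value,
                    "p_similarity": sim.p_value,
                    "threshold": threshold,
                    "sig_ks": ks.p_value < threshold,
                    "sig_ww": ww.p_value < threshold,
                    "sig_similarity": sim.p_value < threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "factor",
            "comparison",
            "p_ks",
            "p_ww",
            "p_similarity",
            "threshold",
            "sig_ks",
            "sig_ww",
            "sig_similarity",
        ],
    )
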