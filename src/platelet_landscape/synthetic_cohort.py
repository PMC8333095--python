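"""Negative-binomial synthetic platelet RNA-seq cohorts with a truth record.

The generator emulates the statistical structure the analysis assumes in a
healthy-donor cohort: 204 donors (119 female / 85 male), ages truncated-
normal with mean 42.11 and SD 13.89 within [18, 86], a mean library size of
~811,858 reads, roughly 3,954 well-expressed transcripts spanning several
orders of magnitude plus a low-expression tail that the expression filter
removes, and three planted effects — a sex-linked gene (target fold change
2.10 in males), an age-correlated gene (target Pearson r 0.409 on the
transformed scale), and a two-cluster block of 224 genes at >= 4-fold
difference of which exactly 6 exceed 10-fold.

Counts are drawn from a gene x sample negative-binomial model
``NB(mean = baseline * size_factor * effect, dispersion)`` with log-normal
per-sample depth factors.  Every planted quantity is echoed in a
:class:`TruthRecord` so downstream recovery is testable without external
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import io_tables
from .io_tables import CountMatrix

__all__ = [
    "SexEffect",
    "AgeEffect",
    "ClusterBlock",
    "CohortConfig",
    "TruthRecord",
    "Cohort",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SexEffect:
    """Multiplicative up-regulation of one gene in male donors."""

    fold_change: float = 2.10
    gene_index: int | None = None  # None: auto-pick a well-expressed gene


@dataclass(frozen=True)
class AgeEffect:
    """One gene whose log2 mean rises linearly with age.

    The slope is calibrated analytically from the gene's baseline mean and
    the dispersion so the expected Pearson correlation on the transformed
    scale matches ``target_r``.
    """

    target_r: float = 0.409
    gene_index: int | None = None


@dataclass(frozen=True)
class ClusterBlock:
    """Block of genes up-regulated in cluster-2 samples.

    ``n_extreme`` genes exceed ``extreme_fc`` (10-fold); the remainder sit
    between ``min_fc`` and ``extreme_fc``.  Per-gene fold changes are drawn
    log-uniformly with a margin inside those bounds so that planted and
    unplanted genes stay separable under sampling noise.
    """

    n_genes: int = 224
    min_fc: float = 4.0
    n_extreme: int = 6
    extreme_fc: float = 10.0


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level parameters; the defaults are the study conditions."""

    n_samples: int = 204
    n_female: int = 119
    age_mean: float = 42.11
    age_sd: float = 13.89
    age_range: tuple[float, float] = (18.0, 86.0)
    mean_library_size: float = 811_858.0
    n_genes_retained_target: int = 3954
    n_genes_low: int = 1000  # low-expression tail removed by the filter
    dispersion: float = 0.05
    depth_log_sd: float = 0.35  # log-normal spread of per-sample depth
    sex_effect: SexEffect | None = field(default_factory=SexEffect)
    age_effect: AgeEffect | None = field(default_factory=AgeEffect)
    cluster_block: ClusterBlock | None = field(default_factory=ClusterBlock)
    storage_shift: float | None = None  # optional ge12h multiplicative shift
    storage_lt12h_frac: float = 0.8
    n_unit_secondary: int = 9  # donors from the secondary collection site
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_female <= self.n_samples:
            raise ValueError("n_female must lie in [0, n_samples]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.cluster_block is not None:
            cb = self.cluster_block
            if cb.n_extreme > cb.n_genes:
                raise ValueError("n_extreme exceeds cluster-block size")
            if cb.min_fc < 1 or cb.extreme_fc <= cb.min_fc:
                raise ValueError("require 1 <= min_fc < extreme_fc")

    @classmethod
    def null(cls, n_samples: int = 40, n_genes: int = 300, seed: int = 0) -> "CohortConfig":
        """All effects off: groups are exchangeable, for calibration studies."""
        return cls(
            n_samples=n_samples,
            n_female=n_samples // 2,
            n_genes_retained_target=n_genes,
            n_genes_low=0,
            sex_effect=None,
            age_effect=None,
            cluster_block=None,
            storage_shift=None,
            seed=seed,
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of the generated cohort, for recovery tests."""

    baseline_means: np.ndarray  # per-gene NB mean at unit depth factor
    gene_ids: tuple[str, ...]
    sex_gene: str | None
    sex_fc: float | None
    age_gene: str | None
    age_slope_log2: float | None  # log2 units per year of age
    age_target_r: float | None
    cluster_genes: tuple[str, ...]
    cluster_fcs: np.ndarray  # aligned to cluster_genes
    cluster_labels: pd.Series  # sample_id -> 1 or 2
    expected_library_size: pd.Series  # sample_id -> expected total reads
    config: CohortConfig

    @property
    def extreme_cluster_genes(self) -> tuple[str, ...]:
        thr = self.config.cluster_block.extreme_fc if self.config.cluster_block else 10.0
        return tuple(
            g for g, f in zip(self.cluster_genes, self.cluster_fcs) if f > thr
        )


class Cohort(NamedTuple):
    counts: CountMatrix
    samples: pd.DataFrame
    truth: TruthRecord


# Shape of the baseline abundance distribution: well-expressed genes have
# log2 mean counts 4.3 + Exponential(scale) before library scaling; the
# scale sets how heavy the high-expression tail is (a handful of genes end
# up above log2 mean 12 at the default cohort size).
_BASE_LOG2_FLOOR = 4.3
_BASE_LOG2_SCALE = 1.3
# Cap on the exponential abundance tail (log2 units above the floor): even
# the most abundant transcript holds a few percent of the library, never
# most of it.
_BASE_LOG2_CAP = 10.4
# Low-expression tail: absolute mean counts kept safely below the
# mean-log2 < 4 expression filter even after group-mean sampling noise.
_LOW_LOG2_RANGE = (-3.0, 3.2)
# Candidate abundance percentiles for planted genes among the main genes:
# expressed well enough that group means are stable, but not the top tail.
_PLANT_PCT_BAND = (0.70, 0.97)
# Safety margin keeping drawn cluster fold changes clear of the min_fc and
# extreme_fc classification boundaries under sampling noise.
_FC_MARGIN = 1.12


def _vst_noise_sd(
    mu: float, dispersion: float, depth_log_sd: float, pseudocount: float = 1.0
) -> float:
    """Exact SD of the transformed value log2(count/depth + pseudocount).

    The count is NB(mean = mu * depth, dispersion) and the depth factor is
    log-normal with mean 1; the depth integral uses Gauss-Hermite
    quadrature and the count moments are summed over the NB pmf.  Used to
    calibrate the planted age slope analytically.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(15)
    weights = weights / weights.sum()
    r = 1.0 / dispersion
    ey = ey2 = 0.0
    for z, w in zip(nodes, weights):
        d = math.exp(-depth_log_sd**2 / 2 + depth_log_sd * z)
        m = mu * d
        kmax = int(m + 12 * math.sqrt(m + dispersion * m * m)) + 10
        k = np.arange(kmax + 1)
        pmf = stats.nbinom.pmf(k, r, r / (r + m))
        y = np.log2(k / d + pseudocount)
        ey += w * float(pmf @ y)
        ey2 += w * float(pmf @ (y * y))
    return math.sqrt(max(ey2 - ey**2, 0.0))


def _truncnorm_ages(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd,
        size=config.n_samples, random_state=rng,
    )


def generate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Draw one cohort: counts, sample table, and truth record.

    Deterministic given ``config.seed``: the same configuration yields
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_main = config.n_genes_retained_target
    n_low = config.n_genes_low
    n_genes = n_main + n_low

    # --- donors ---------------------------------------------------------
    sample_ids = [f"D{i + 1:04d}" for i in range(n)]
    sex = np.array(["female"] * config.n_female + ["male"] * (n - config.n_female))
    sex = sex[rng.permutation(n)]
    ages = _truncnorm_ages(config, rng)
    cluster = np.ones(n, dtype=int)
    cluster[rng.permutation(n)[: n // 2]] = 2
    storage = np.where(
        rng.random(n) < config.storage_lt12h_frac, "lt12h", "ge12h"
    )
    n_secondary = min(config.n_unit_secondary, n)
    unit = np.array(["VUmc"] * n, dtype=object)
    unit[rng.permutation(n)[:n_secondary]] = "AMC"

    # --- gene baselines -------------------------------------------------
    # Main genes carry essentially the whole library; the low tail has
    # absolute mean counts below the expression filter regardless of scale.
    log2_main = _BASE_LOG2_FLOOR + np.minimum(
        rng.exponential(_BASE_LOG2_SCALE, size=n_main), _BASE_LOG2_CAP
    )
    main = 2.0**log2_main
    main *= config.mean_library_size / main.sum()
    low = 2.0 ** rng.uniform(*_LOW_LOG2_RANGE, size=n_low)
    baseline = np.concatenate([main, low])
    gene_ids = tuple(f"GENE{i + 1:05d}" for i in range(n_genes))

    # --- planted effects ------------------------------------------------
    order = np.argsort(main, kind="stable")
    band = order[int(_PLANT_PCT_BAND[0] * n_main) : int(_PLANT_PCT_BAND[1] * n_main)]
    n_needed = (
        (1 if config.sex_effect else 0)
        + (1 if config.age_effect else 0)
        + (config.cluster_block.n_genes if config.cluster_block else 0)
    )
    if n_needed > len(band):
        raise ValueError(
            f"config plants {n_needed} genes but only {len(band)} candidates "
            "lie in the well-expressed band"
        )
    picks = rng.choice(band, size=n_needed, replace=False) if n_needed else np.array([], int)
    cursor = 0

    effect = np.ones((n_genes, n), dtype=float)

    sex_gene = sex_fc = None
    if config.sex_effect is not None:
        gi = config.sex_effect.gene_index
        if gi is None:
            gi = int(picks[cursor])
            cursor += 1
        effect[gi, sex == "male"] *= config.sex_effect.fold_change
        sex_gene, sex_fc = gene_ids[gi], config.sex_effect.fold_change

    age_gi: int | None = None
    if config.age_effect is not None:
        age_gi = config.age_effect.gene_index
        if age_gi is None:
            age_gi = int(picks[cursor])
            cursor += 1

    cluster_genes: tuple[str, ...] = ()
    cluster_fcs = np.array([])
    if config.cluster_block is not None:
        cb = config.cluster_block
        gis = picks[cursor : cursor + cb.n_genes]
        cursor += cb.n_genes
        lo = math.log(cb.min_fc * _FC_MARGIN)
        hi = math.log(cb.extreme_fc / _FC_MARGIN)
        fcs = np.exp(rng.uniform(lo, hi, size=cb.n_genes - cb.n_extreme))
        ext = np.exp(
            rng.uniform(
                math.log(cb.extreme_fc * _FC_MARGIN),
                math.log(cb.extreme_fc * 2.2),
                size=cb.n_extreme,
            )
        )
        fcs = np.concatenate([fcs, ext])
        effect[np.ix_(gis, cluster == 2)] *= fcs[:, np.newaxis]
        cluster_genes = tuple(gene_ids[i] for i in gis)
        cluster_fcs = fcs

    if config.storage_shift is not None:
        # Applied to half the transcriptome: a truly global shift would be
        # indistinguishable from depth and absorbed by the size factors.
        half = rng.permutation(n_genes)[: n_genes // 2]
        effect[np.ix_(half, storage == "ge12h")] *= config.storage_shift

    # --- counts ---------------------------------------------------------
    # Planted effects add reads; rescale so the cohort-wide expected
    # library size stays at the configured mean.
    expected_per_sample = (baseline[:, np.newaxis] * effect).sum(axis=0)
    scale = config.mean_library_size / expected_per_sample.mean()
    baseline = baseline * scale

    # The age slope is calibrated on the final baseline mean so the
    # expected Pearson correlation on the transformed scale hits target_r.
    age_gene = age_slope = age_target = None
    if config.age_effect is not None:
        r = config.age_effect.target_r
        sigma = _vst_noise_sd(
            float(baseline[age_gi]), config.dispersion, config.depth_log_sd
        )
        lo, hi = config.age_range
        sd_age = stats.truncnorm.std(
            (lo - config.age_mean) / config.age_sd,
            (hi - config.age_mean) / config.age_sd,
            loc=config.age_mean,
            scale=config.age_sd,
        )
        slope = (sigma / sd_age) * r / math.sqrt(1.0 - r**2)
        effect[age_gi, :] *= 2.0 ** (slope * (ages - config.age_mean))
        age_gene, age_slope, age_target = gene_ids[age_gi], slope, r

    depth = rng.lognormal(-config.depth_log_sd**2 / 2, config.depth_log_sd, size=n)
    depth /= depth.mean()  # depth factors are relative; centre the cohort
    mu = baseline[:, np.newaxis] * effect * depth[np.newaxis, :]
    r_nb = 1.0 / config.dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))

    totals = counts.sum(axis=0)
    batch = pd.qcut(totals, 3, labels=[1, 2, 3]).astype(int)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sex,
            "age_years": np.round(ages, 2),
            "storage_group": storage,
            "collection_unit": unit,
            "libsize_batch": np.asarray(batch),
            "total_reads": totals.astype(np.int64),
        }
    )
    truth = TruthRecord(
        baseline_means=baseline,
        gene_ids=gene_ids,
        sex_gene=sex_gene,
        sex_fc=sex_fc,
        age_gene=age_gene,
        age_slope_log2=age_slope,
        age_target_r=age_target,
        cluster_genes=cluster_genes,
        cluster_fcs=cluster_fcs,
        cluster_labels=pd.Series(cluster, index=sample_ids, name="cluster"),
        expected_library_size=pd.Series(
            mu.sum(axis=0), index=sample_ids, name="expected_library_size"
        ),
        config=config,
    )
    return Cohort(CountMatrix(gene_ids, sample_ids, counts), samples, truth)


def _config_items(config: CohortConfig) -> list[tuple[str, str]]:
    flat = []
    for key, val in asdict(config).items():
        flat.append((key, repr(val)))
    return flat


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write counts, sample table, annotation stub, and truth record.

    The annotation stub maps each synthetic gene ID to itself at level 1
    with status 'known', so the cohort round-trips through the same
    loaders as real data.  The truth record is a sectioned text file:
    ``[config]`` key-value lines (including the seed), a ``[genes]`` TSV of
    planted roles and effects, and a ``[samples]`` TSV of cluster labels.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.txt",
    }
    io_tables.write_counts(cohort.counts, paths["counts"])
    io_tables.write_sample_table(cohort.samples, paths["samples"])
    annotation = pd.DataFrame(
        {
            "gene_id": list(cohort.counts.gene_ids),
            "gene_name": list(cohort.counts.gene_ids),
            "level": 1,
            "status": "known",
        }
    )
    io_tables.write_gene_annotation(annotation, paths["annotation"])

    truth = cohort.truth
    role = {g: "none" for g in truth.gene_ids}
    fc = {g: 1.0 for g in truth.gene_ids}
    if truth.sex_gene:
        role[truth.sex_gene] = "sex"
        fc[truth.sex_gene] = truth.sex_fc
    if truth.age_gene:
        role[truth.age_gene] = "age"
    for g, f in zip(truth.cluster_genes, truth.cluster_fcs):
        role[g] = "cluster_block"
        fc[g] = float(f)

    with open(paths["truth"], "w") as fh:
        fh.write("[config]\n")
        for key, val in _config_items(truth.config):
            fh.write(f"{key}\t{val}\n")
        if truth.age_slope_log2 is not None:
            fh.write(f"age_slope_log2\t{truth.age_slope_log2!r}\n")
        fh.write("\n[genes]\n")
        fh.write("gene_id\tbaseline_mean\trole\teffect_fc\n")
        for g, m in zip(truth.gene_ids, truth.baseline_means):
            fh.write(f"{g}\t{m:.10g}\t{role[g]}\t{fc[g]:.10g}\n")
        fh.write("\n[samples]\n")
        fh.write("sample_id\tcluster\texpected_library_size\n")
        for s in truth.cluster_labels.index:
            fh.write(
                f"{s}\t{truth.cluster_labels[s]}\t"
                f"{truth.expected_library_size[s]:.10g}\n"
            )
    return paths
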