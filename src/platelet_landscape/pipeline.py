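"""End-to-end orchestration: QC, normalization, contrasts, clustering, battery.

``run_pipeline`` executes the full analysis on either files on disk or a
freshly simulated cohort and writes every result as TSV plus a run log
(config echo, seed, package versions, per-stage record counts).  A rerun
with the same configuration and seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, contrasts, io_tables, preprocess, vector_stats
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    # either file inputs ...
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    # ... or simulation
    simulate: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # thresholds
    min_reads: int = 100_000
    low_expr_threshold: float = 4.0
    fc_report_bands: tuple[float, ...] = (1.5, 2.0, 3.0, 4.0, 10.0)
    r_band: float = 0.3
    alpha: float = 0.05
    cluster_fc_threshold: float = 4.0
    median_age: float | None = None  # None: cohort median
    # permutation settings
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if list(self.fc_report_bands) != sorted(self.fc_report_bands):
            raise ValueError("fc_report_bands must be sorted ascending")
        if self.min_reads < 1 or self.low_expr_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return inner

    return wrap


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kwargs)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the result bundle; returns output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log_lines: list[str] = [
        f"platelet-landscape {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        "config:",
    ]
    cfg_echo = dataclasses.asdict(config)
    for key, val in cfg_echo.items():
        log_lines.append(f"  {key} = {val!r}")

    # --- load or simulate ----------------------------------------------
    @_stage("input")
    def load():
        if config.simulate:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = generate_cohort(cohort_cfg)
            sim_paths = write_cohort(cohort, out / "cohort")
            paths.update({f"cohort_{k}": v for k, v in sim_paths.items()})
            return cohort.counts, cohort.samples
        if not (config.counts_path and config.samples_path):
            raise ValueError("counts_path and samples_path required unless simulating")
        fmt = "mtx" if str(config.counts_path).endswith(".mtx") else "tsv"
        counts = io_tables.read_counts(config.counts_path, format=fmt)
        if config.annotation_path:
            ann = io_tables.read_gene_annotation(config.annotation_path)
            counts = io_tables.collapse_gene_ids(counts, ann)
        samples = io_tables.read_sample_table(config.samples_path)
        return counts, samples

    counts, samples = load()
    log_lines.append(f"input: {counts.n_genes} genes x {counts.n_samples} samples")

    # --- preprocess -----------------------------------------------------
    @_stage("depth_filter")
    def depth():
        totals = counts.column_sums()
        report = pd.DataFrame(
            {
                "sample_id": list(counts.sample_ids),
                "total_reads": totals,
                "kept": totals >= config.min_reads,
            }
        )
        _write(report, out / "depth_filter.tsv", index=False)
        paths["depth_filter"] = out / "depth_filter.tsv"
        return preprocess.filter_samples_by_depth(counts, min_reads=config.min_reads)

    counts_kept = depth()
    samples = samples[samples["sample_id"].isin(counts_kept.sample_ids)].reset_index(drop=True)
    log_lines.append(f"depth filter: {counts_kept.n_samples} samples kept")

    @_stage("normalize")
    def normalize():
        factors = preprocess.size_factors(counts_kept)
        norm_full = preprocess.vst(counts_kept, factors)
        sex_groups = samples.set_index("sample_id")["sex"]
        return preprocess.filter_low_expression(
            norm_full, sex_groups, threshold=config.low_expr_threshold
        )

    norm = normalize()
    log_lines.append(f"expression filter: {norm.n_genes} genes retained")
    _write(norm.to_frame(), out / "normalized.tsv", index_label="gene")
    paths["normalized"] = out / "normalized.tsv"
    _write(
        pd.DataFrame(
            {"sample_id": list(norm.sample_ids), "size_factor": norm.size_factors}
        ),
        out / "size_factors.tsv",
        index=False,
    )
    paths["size_factors"] = out / "size_factors.tsv"

    meta = samples.set_index("sample_id").loc[list(norm.sample_ids)]

    # --- contrasts ------------------------------------------------------
    @_stage("contrasts")
    def run_contrasts():
        sex_table = contrasts.group_ttest(norm, meta["sex"], "male", "female")
        _write(sex_table, out / "contrast_sex.tsv")
        paths["contrast_sex"] = out / "contrast_sex.tsv"

        median_age = (
            config.median_age
            if config.median_age is not None
            else float(meta["age_years"].median())
        )
        age_groups = pd.Series(
            np.where(meta["age_years"] > median_age, "older", "younger"),
            index=meta.index,
        )
        if (age_groups == "older").sum() >= 2 and (age_groups == "younger").sum() >= 2:
            age_table = contrasts.group_ttest(norm, age_groups, "older", "younger")
            _write(age_table, out / "contrast_age_median.tsv")
            paths["contrast_age_median"] = out / "contrast_age_median.tsv"

        corr = contrasts.age_correlation(norm, meta["age_years"])
        _write(corr, out / "age_correlation.tsv")
        paths["age_correlation"] = out / "age_correlation.tsv"
        return median_age

    median_age = run_contrasts()
    log_lines.append(f"contrasts: median age split at {median_age:g}")

    # --- clustering -----------------------------------------------------
    @_stage("clustering")
    def run_clustering():
        dist = vector_stats.euclidean_distance_matrix(norm)
        tree = clustering.ward_d2_linkage(dist.to_numpy(), list(norm.sample_ids))
        _write(tree.to_frame(), out / "linkage.tsv", index=False)
        paths["linkage"] = out / "linkage.tsv"
        assignment = clustering.cut_tree(tree, 2)
        _write(assignment.to_frame(), out / "clusters.tsv", index_label="sample_id")
        paths["clusters"] = out / "clusters.tsv"
        contrast = clustering.cluster_contrast(
            norm, assignment, fc_threshold=config.cluster_fc_threshold
        )
        _write(contrast.table, out / "cluster_contrast.tsv")
        paths["cluster_contrast"] = out / "cluster_contrast.tsv"
        summary = pd.DataFrame(
            {
                "metric": [
                    "n_selected",
                    "frac_below_twofold",
                    "n_threefold",
                    "n_fourfold",
                    "hot_cluster",
                ],
                "value": [
                    len(contrast.genes),
                    contrast.frac_below_twofold,
                    contrast.n_threefold,
                    contrast.n_fourfold,
                    contrast.hot_cluster,
                ],
            }
        )
        _write(summary, out / "cluster_summary.tsv", index=False)
        paths["cluster_summary"] = out / "cluster_summary.tsv"
        # heatmap-ready export: contrast genes x samples, cluster-ordered
        if contrast.genes:
            sample_order = assignment.sort_values(kind="stable").index
            heat = norm.to_frame().loc[list(contrast.genes), sample_order]
            _write(heat, out / "heatmap_matrix.tsv", index_label="gene")
            paths["heatmap_matrix"] = out / "heatmap_matrix.tsv"
        return assignment, contrast

    assignment, contrast = run_clustering()
    log_lines.append(
        f"clustering: {len(contrast.genes)} genes at >= "
        f"{config.cluster_fc_threshold:g}-fold between clusters"
    )

    # --- vector-test battery -------------------------------------------
    @_stage("battery")
    def run_battery():
        battery = vector_stats.run_table1_battery(
            norm,
            samples,
            cluster=assignment,
            n_perm=config.n_perm,
            seed=config.seed,
            alpha=config.alpha,
        )
        _write(battery, out / "battery.tsv", index=False)
        paths["battery"] = out / "battery.tsv"
        return battery

    battery = run_battery()
    log_lines.append(f"battery: {len(battery)} pairwise comparisons")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = out / "run_log.txt"
    return paths
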