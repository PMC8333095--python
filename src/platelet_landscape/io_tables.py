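"""Reading and writing of count matrices, sample metadata and gene annotation.

The pipeline consumes a gene x sample matrix of spliced-read counts (as
produced upstream by an HTSeq-style counter), a per-sample covariate table,
and a reduced four-column gene annotation mapping stable gene IDs to gene
names.  Two matrix formats are supported: plain TSV (header row of sample
IDs, first column of gene IDs) and MatrixMarket coordinate format with
sidecar one-column label files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_gene_annotation",
    "write_gene_annotation",
    "collapse_gene_ids",
    "read_sample_table",
    "write_sample_table",
    "SEX_LEVELS",
    "STORAGE_LEVELS",
    "LIBSIZE_BATCHES",
    "SAMPLE_COLUMNS",
]

SEX_LEVELS = ("female", "male")
STORAGE_LEVELS = ("lt12h", "ge12h")
LIBSIZE_BATCHES = (1, 2, 3)
SAMPLE_COLUMNS = (
    "sample_id",
    "sex",
    "age_years",
    "storage_group",
    "collection_unit",
    "libsize_batch",
    "total_reads",
)
ANNOTATION_COLUMNS = ("gene_id", "gene_name", "level", "status")


class ValidationError(ValueError):
    """Raised when an input table violates the expected schema."""


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample read-count matrix with unique labels."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_genes, n_samples), integer, >= 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dups = _find_duplicates(self.gene_ids)
        if dups:
            raise ValidationError(f"duplicate gene IDs: {dups}")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if not np.issubdtype(counts.dtype, np.integer):
            frac = counts != np.floor(counts)
            if frac.any():
                g, s = np.argwhere(frac)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}: {counts[g, s]}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            g, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}: {counts[g, s]}"
            )
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.gene_ids, tuple(sample_ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def _read_label_file(path: Path) -> list[str]:
    labels = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not labels:
        raise ValidationError(f"empty label file: {path}")
    return labels


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(path.suffix + ".rows"), path.with_suffix(path.suffix + ".cols")


def read_counts(
    path: str | Path,
    format: str = "tsv",
    *,
    row_labels: str | Path | None = None,
    col_labels: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket coordinate format.

    TSV: tab-delimited, UTF-8, header row of sample IDs, first column of
    gene IDs, no quoting.  MatrixMarket: integer coordinate ``.mtx`` with
    sidecar one-column label files (rows = genes); defaults are
    ``<path>.rows`` / ``<path>.cols``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        dups = _find_duplicates(sample_ids)
        if dups:
            raise ValidationError(f"duplicate sample IDs in header: {dups}")
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        gene_ids = [str(g) for g in df.index]
        return CountMatrix(gene_ids, sample_ids, df.to_numpy())
    if format == "mtx":
        rows_p, cols_p = _sidecar_paths(path)
        if row_labels is not None:
            rows_p = Path(row_labels)
        if col_labels is not None:
            cols_p = Path(col_labels)
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_label_file(rows_p)
        samples = _read_label_file(cols_p)
        return CountMatrix(genes, samples, np.asarray(mat))
    raise ValueError(f"unknown count-matrix format: {format!r}")


def write_counts(counts: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a count matrix; MatrixMarket output emits sidecar label files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        counts.to_frame().to_csv(path, sep="\t", index_label="gene_id")
        return
    if format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(counts.counts), field="integer")
        rows_p, cols_p = _sidecar_paths(path)
        rows_p.write_text("\n".join(counts.gene_ids) + "\n")
        cols_p.write_text("\n".join(counts.sample_ids) + "\n")
        return
    raise ValueError(f"unknown count-matrix format: {format!r}")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read the reduced gene annotation table.

    Columns: gene_id, gene_name, level (small positive integer, level 1 =
    highest-confidence record), status ('known' or 'other').
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "gene_name": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    dups = _find_duplicates(df["gene_id"])
    if dups:
        raise ValidationError(f"duplicate gene IDs in annotation: {dups}")
    if (df["level"] < 1).any():
        raise ValidationError("annotation level must be a positive integer")
    bad = sorted(set(df["status"]) - {"known", "other"})
    if bad:
        raise ValidationError(f"unknown annotation status values: {bad}")
    return df.loc[:, list(ANNOTATION_COLUMNS)]


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annotation.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def collapse_gene_ids(counts: CountMatrix, annotation: pd.DataFrame) -> CountMatrix:
    """Collapse stable gene IDs to gene names.

    Rows whose annotation status is not 'known' are dropped.  When two IDs
    map to the same gene name, only the row whose record has level 1 is
    retained (rows are selected, never summed).  A name shared by several
    IDs where none or more than one has level 1 is an error: the source
    data defines no tie-break for that case.
    """
    ann = annotation.set_index("gene_id")
    missing = [g for g in counts.gene_ids if g not in ann.index]
    if missing:
        raise ValidationError(f"gene IDs absent from annotation: {missing[:10]}")

    known = [g for g in counts.gene_ids if ann.at[g, "status"] == "known"]
    by_name: dict[str, list[str]] = {}
    for g in known:
        by_name.setdefault(str(ann.at[g, "gene_name"]), []).append(g)

    chosen: dict[str, str] = {}
    for name, ids in by_name.items():
        if len(ids) == 1:
            chosen[name] = ids[0]
            continue
        level1 = [g for g in ids if int(ann.at[g, "level"]) == 1]
        if len(level1) != 1:
            raise ValidationError(
                f"gene name {name!r} maps to IDs {ids} with "
                f"{len(level1)} level-1 records; cannot resolve collision"
            )
        chosen[name] = level1[0]

    keep_ids = set(chosen.values())
    out_names: list[str] = []
    rows: list[int] = []
    for i, g in enumerate(counts.gene_ids):
        if g in keep_ids:
            out_names.append(str(ann.at[g, "gene_name"]))
            rows.append(i)
    n_dropped = counts.n_genes - len(rows)
    if n_dropped:
        logger.info("collapse_gene_ids dropped %d of %d rows", n_dropped, counts.n_genes)
    return CountMatrix(out_names, counts.sample_ids, counts.counts[rows])


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample covariate table (CSV or TSV).

    Required columns: sample_id, sex {female, male}, age_years in [0, 130],
    storage_group {lt12h, ge12h}, collection_unit, libsize_batch {1, 2, 3},
    total_reads (nonnegative integer).  The controlled vocabularies are
    strict: tokens such as "F" are rejected rather than guessed at.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "collection_unit": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    if df["sample_id"].isna().any():
        raise ValidationError("missing sample_id in sample table")
    dups = _find_duplicates(df["sample_id"])
    if dups:
        raise ValidationError(f"duplicate sample IDs: {dups}")
    bad = sorted(set(df["sex"]) - set(SEX_LEVELS))
    if bad:
        raise ValidationError(f"unknown sex tokens {bad}; expected {SEX_LEVELS}")
    bad = sorted(set(df["storage_group"]) - set(STORAGE_LEVELS))
    if bad:
        raise ValidationError(f"unknown storage tokens {bad}; expected {STORAGE_LEVELS}")
    ages = pd.to_numeric(df["age_years"], errors="coerce")
    if ages.isna().any():
        raise ValidationError("non-numeric age_years value")
    if ((ages < 0) | (ages > 130)).any():
        bad_ids = df.loc[(ages < 0) | (ages > 130), "sample_id"].tolist()
        raise ValidationError(f"age_years outside [0, 130] for samples {bad_ids}")
    df["age_years"] = ages.astype(float)
    batches = pd.to_numeric(df["libsize_batch"], errors="coerce")
    if batches.isna().any() or not set(batches.astype(int)) <= set(LIBSIZE_BATCHES):
        raise ValidationError(f"libsize_batch must be one of {LIBSIZE_BATCHES}")
    df["libsize_batch"] = batches.astype(int)
    reads = pd.to_numeric(df["total_reads"], errors="coerce")
    if reads.isna().any() or (reads < 0).any() or (reads != reads.astype(int)).any():
        raise ValidationError("total_reads must be nonnegative integers")
    df["total_reads"] = reads.astype(np.int64)
    return df.loc[:, list(SAMPLE_COLUMNS)].reset_index(drop=True)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    samples.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, sep=sep, index=False)
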