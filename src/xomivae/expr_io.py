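"""Expression-matrix I/O, validation, filtering, imputation and normalization.

The pipeline mirrors standard pan-cancer expression pre-processing: drop
Y-chromosome genes, drop genes with zero expression everywhere, drop genes
missing in more than a fraction of samples, mean-impute the remaining
missing entries, then min-max normalize each gene to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "FilterReport",
    "NormalizationRecord",
    "read_expression",
    "read_annotation",
    "read_labels",
    "read_gene_set",
    "write_gene_set",
    "filter_genes",
    "impute_missing",
    "normalize_unit_interval",
    "apply_normalization",
    "preprocess",
]


@dataclass
class ExpressionMatrix:
    """A sample x gene matrix of non-negative expression values.

    ``values`` holds floats with ``NaN`` marking missing entries. Optional
    per-sample ``class_labels`` (e.g. tumour type) and ``phenotypes``
    (named categorical covariates such as sex) ride along and are preserved
    by every subsetting operation.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    class_labels: np.ndarray | None = None
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n_s, n_g = self.values.shape
        if n_s != len(self.sample_ids):
            raise ValueError(
                f"row count {n_s} != number of sample ids {len(self.sample_ids)}")
        if n_g != len(self.gene_ids):
            raise ValueError(
                f"column count {n_g} != number of gene ids {len(self.gene_ids)}")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} id: {dupes[0]!r}")
        neg = np.argwhere(np.nan_to_num(self.values, nan=0.0) < 0)
        if len(neg):
            i, j = neg[0]
            raise ValueError(
                f"negative expression value {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}")
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels, dtype=object)
            if len(self.class_labels) != n_s:
                raise ValueError("class_labels length mismatch")
        if self.phenotypes is not None and len(self.phenotypes) != n_s:
            raise ValueError("phenotypes length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def subset_genes(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        """Subset by boolean mask, integer indices, or gene-id list."""
        if len(keep) and isinstance(keep[0], str):
            idx = [self.gene_index(g) for g in keep]
        else:
            keep = np.asarray(keep)
            idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            class_labels=None if self.class_labels is None else self.class_labels[idx],
            phenotypes=None if self.phenotypes is None else self.phenotypes.iloc[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def write_tsv(self, path: str | Path, orientation: str = "genes-in-columns") -> None:
        df = self.to_frame()
        if orientation == "genes-in-rows":
            df = df.T
        elif orientation != "genes-in-columns":
            raise ValueError(f"unknown orientation {orientation!r}")
        df.to_csv(path, sep="\t")


@dataclass
class GeneAnnotation:
    """gene_id -> chromosome label; unannotated lookups return None."""

    chromosome: dict[str, str]

    def chrom(self, gene_id: str) -> str | None:
        return self.chromosome.get(gene_id)

    def is_chr_y(self, gene_id: str) -> bool:
        return self.chromosome.get(gene_id) == "chrY"


@dataclass
class FilterReport:
    """Which genes each filtering rule removed, plus annotation gaps.

    A gene matching several rules is counted once, under the first matching
    rule in the order Y -> all-zero -> missingness.
    """

    removed_y: list[str] = field(default_factory=list)
    removed_zero: list[str] = field(default_factory=list)
    removed_na: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    unannotated: list[str] = field(default_factory=list)

    @property
    def n_original(self) -> int:
        return (len(self.removed_y) + len(self.removed_zero)
                + len(self.removed_na) + len(self.retained))

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "chrY") for g in self.removed_y]
        rows += [(g, "all_zero") for g in self.removed_zero]
        rows += [(g, "high_missingness") for g in self.removed_na]
        rows += [(g, "retained") for g in self.retained]
        df = pd.DataFrame(rows, columns=["gene_id", "status"])
        df["unannotated"] = df["gene_id"].isin(set(self.unannotated))
        return df


@dataclass
class NormalizationRecord:
    """Per-gene (min, max) of the training data; replays the transform."""

    gene_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {g: [float(lo), float(hi)] for g, lo, hi in
                   zip(self.gene_ids, self.mins, self.maxs)}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationRecord":
        payload = json.loads(Path(path).read_text())
        genes = list(payload)
        arr = np.array([payload[g] for g in genes], dtype=float)
        return cls(genes, arr[:, 0], arr[:, 1])


def _split_table(path: str | Path) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    rows = [ln.split(delim) for ln in lines]
    widths = {len(r) for r in rows[1:]}
    if len(widths) > 1:
        raise ValueError(f"{path}: ragged rows (field counts {sorted(widths)})")
    return rows[0], rows[1:]


def read_expression(path: str | Path,
                    orientation: str = "genes-in-columns") -> ExpressionMatrix:
    """Read a delimited expression table (TSV, or CSV by extension).

    ``orientation`` declares whether genes run along columns (rows are
    samples) or along rows. Empty cells and the literal strings NA/NaN
    parse as missing.
    """
    header, body = _split_table(path)
    # header may or may not carry a corner label for the id column
    col_ids = header[1:] if len(header) == len(body[0]) else header
    row_ids = [r[0] for r in body]
    cells = [r[1:] for r in body]
    na = {"", "na", "nan", "n/a", "null"}
    values = np.array(
        [[np.nan if c.strip().lower() in na else float(c) for c in row]
         for row in cells], dtype=float)
    if orientation == "genes-in-rows":
        values = values.T
        gene_ids, sample_ids = row_ids, col_ids
    elif orientation == "genes-in-columns":
        gene_ids, sample_ids = col_ids, row_ids
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(values, gene_ids=gene_ids, sample_ids=sample_ids)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Two-column table: gene_id <tab> chromosome."""
    header, body = _split_table(path)
    rows = [header] + body if len(header) == 2 and header[1].startswith("chr") else body
    return GeneAnnotation({r[0]: r[1] for r in rows})


def read_labels(path: str | Path) -> pd.Series:
    """Two-column table: sample_id <tab> label (header optional)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln)
    return out


def write_gene_set(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


def filter_genes(m: ExpressionMatrix, ann: GeneAnnotation,
                 na_fraction_max: float = 0.1,
                 ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop chrY genes, all-zero genes, and genes missing in more than
    ``na_fraction_max`` of samples (strict inequality: a gene missing in
    exactly that fraction is kept). Unannotated genes are retained and
    flagged in the report, never silently dropped.
    """
    if not 0.0 <= na_fraction_max <= 1.0:
        raise ValueError("na_fraction_max must be in [0, 1]")
    report = FilterReport()
    keep = np.ones(m.n_genes, dtype=bool)
    missing = np.isnan(m.values)
    na_frac = missing.mean(axis=0)
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        all_zero = (n_obs > 0) & (np.nansum(np.abs(m.values), axis=0) == 0)
    for j, g in enumerate(m.gene_ids):
        if ann.chrom(g) is None:
            report.unannotated.append(g)
        if ann.is_chr_y(g):
            report.removed_y.append(g)
            keep[j] = False
        elif all_zero[j]:
            report.removed_zero.append(g)
            keep[j] = False
        elif na_frac[j] > na_fraction_max or n_obs[j] == 0:
            report.removed_na.append(g)
            keep[j] = False
        else:
            report.retained.append(g)
    if not keep.any():
        raise ValueError("all genes removed by filtering")
    return m.subset_genes(keep), report


def impute_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing value by the mean of that gene's observed values."""
    missing = np.isnan(m.values)
    if not missing.any():
        return m
    n_obs = (~missing).sum(axis=0)
    dead = np.flatnonzero(n_obs == 0)
    if len(dead):
        raise ValueError(
            f"gene {m.gene_ids[dead[0]]!r} has no observed values; "
            "filter before imputing")
    means = np.nanmean(m.values, axis=0)
    values = np.where(missing, means[np.newaxis, :], m.values)
    return replace(m, values=values)


def normalize_unit_interval(
        m: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationRecord]:
    """Min-max scale each gene to [0, 1]; constant genes map to 0.

    The returned record replays the identical transform on new samples.
    """
    if np.isnan(m.values).any():
        raise ValueError("matrix has missing values; impute before normalizing")
    mins = m.values.min(axis=0)
    maxs = m.values.max(axis=0)
    record = NormalizationRecord(list(m.gene_ids), mins, maxs)
    return apply_normalization(m, record), record


def apply_normalization(m: ExpressionMatrix,
                        record: NormalizationRecord) -> ExpressionMatrix:
    if list(m.gene_ids) != list(record.gene_ids):
        raise ValueError("gene ids do not match the normalization record")
    span = record.maxs - record.mins
    safe = np.where(span > 0, span, 1.0)
    values = (m.values - record.mins) / safe
    values[:, span == 0] = 0.0
    return replace(m, values=values)


def preprocess(m: ExpressionMatrix, ann: GeneAnnotation,
               na_fraction_max: float = 0.1,
               ) -> tuple[ExpressionMatrix, FilterReport, NormalizationRecord]:
    """filter -> impute -> normalize, the full pre-processing pipeline."""
    filtered, report = filter_genes(m, ann, na_fraction_max)
    complete = impute_missing(filtered)
    normalized, record = normalize_unit_interval(complete)
    return normalized, report, record
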