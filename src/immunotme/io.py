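"""Readers, writers and validated containers for the formats the pipeline touches.

Bulk and single-cell expression travel as :class:`ExpressionMatrix`
(genes in rows, following the convention of the public expression portals),
gene sets as :class:`GeneSetCollection` (GMT), and sample phenotypes as
:class:`ClinicalTable`. All readers validate on construction and refuse,
rather than repair, malformed input: duplicate identifiers are an error,
not a merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

VALID_UNITS = ("counts", "normalized", "lognorm")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample (or gene-by-cell) numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers (samples or cell barcodes).
    values : ndarray of shape (n_genes, n_samples)
        Expression values. Must be nonnegative and integral (within 1e-9)
        when ``unit == "counts"``.
    unit : {"counts", "normalized", "lognorm"}
        Declared measurement scale. The pipeline never guesses the unit of
        an input file; the caller declares it.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.unit == "counts":
            if np.any(self.values < 0):
                raise ValueError("negative values under unit=counts")
            if np.max(np.abs(self.values - np.round(self.values))) > 1e-9:
                raise ValueError("non-integral values under unit=counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str = "normalized") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), unit)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows], self.unit)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols], self.unit)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. an LM22-style marker collection or GMT pathways."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if not all(isinstance(g, str) for g in genes):
                raise ValueError(f"gene set {name!r} has non-string members")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample phenotype: tumor/control state, optional immunoactivity
    group, and optional right-censored survival (time > 0, event in {0,1})."""

    table: pd.DataFrame
    time_unit: str = "months"

    REQUIRED = ("sample_id", "state")

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        bad_state = set(df["state"]) - {"tumor", "control"}
        if bad_state:
            raise ValueError(f"unknown state value(s): {sorted(bad_state)}")
        if "group" in df.columns:
            bad = set(df["group"].dropna()) - {"low", "moderate", "high"}
            if bad:
                raise ValueError(f"unknown group value(s): {sorted(bad)}")
        if "time" in df.columns:
            times = df["time"].dropna()
            if (times <= 0).any():
                row = df.index[df["time"] <= 0][0]
                raise ValueError(f"nonpositive survival time at row {row} "
                                 f"(sample {df.loc[row, 'sample_id']!r})")
            if "event" not in df.columns:
                raise ValueError("time column present without event column")
            events = df["event"].dropna()
            if not set(np.asarray(events, dtype=float)) <= {0.0, 1.0}:
                raise ValueError("event values must be 0 or 1")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def state_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["state"]

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        df = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return ClinicalTable(df, self.time_unit)


# ---------------------------------------------------------------------------
# Expression IO
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "tsv", unit: str = "normalized",
                    genes_path: str | Path | None = None,
                    cells_path: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (genes x samples, header row of
    sample ids, first column of gene ids) or a MatrixMarket triplet.

    MTX input requires companion ``genes_path`` and ``cells_path`` line lists.
    Duplicate gene rows are rejected, never silently merged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.isna().any().any():
            raise ValueError(f"{path}: ragged or missing values")
        return ExpressionMatrix(list(df.index.astype(str)),
                                list(df.columns.astype(str)),
                                df.to_numpy(dtype=float), unit)
    if format == "mtx-triplet":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx-triplet format requires genes_path and cells_path")
        mat = scipy.io.mmread(str(path))
        genes = Path(genes_path).read_text().split()
        cells = Path(cells_path).read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        return ExpressionMatrix(genes, cells, dense, unit)
    raise ValueError(f"unknown format {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv",
                     genes_path: str | Path | None = None,
                     cells_path: str | Path | None = None) -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        expr.to_frame().to_csv(path, sep=sep)
        return
    if format == "mtx-triplet":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx-triplet format requires genes_path and cells_path")
        sparse = scipy.sparse.coo_matrix(expr.values)
        scipy.io.mmwrite(str(path), sparse)
        Path(genes_path).write_text("\n".join(expr.gene_ids) + "\n")
        Path(cells_path).write_text("\n".join(expr.sample_ids) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a set are deduplicated (order preserved) with a
    logged warning; duplicate set names are an error. An empty file yields an
    empty collection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.warning("set %r: %d duplicate gene(s) removed",
                           name, len(genes) - len(deduped))
        sets[name] = deduped
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path, time_unit: str = "months",
                  column_map: dict[str, str] | None = None) -> ClinicalTable:
    """Read a TSV clinical table. ``column_map`` renames file headers to the
    canonical ``sample_id / state / group / time / event`` names."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    return ClinicalTable(df, time_unit=time_unit)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)
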