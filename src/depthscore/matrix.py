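"""Expression matrices, sample labels, and gene sets: containers and file I/O.

The on-disk conventions are the ones common in bulk-transcriptomics pipelines:
a delimited gene-by-sample table (header row = sample ids, first column =
gene ids), a two-column sample/label table, and GMT gene-set files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleLabels",
    "GeneSet",
    "read_expression",
    "write_expression",
    "log2_normalize",
    "read_gmt",
    "read_labels",
]

Scale = Literal["raw", "log2"]

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """A genes-by-samples expression table.

    Parameters
    ----------
    data
        DataFrame with gene ids as the index and sample ids as the columns.
        All entries must be finite.
    scale
        ``"raw"`` for non-negative linear-scale values (RSEM/TPM-like) or
        ``"log2"`` after the log2(x+1) transform. The tag exists to keep a
        matrix from being log-transformed twice.
    """

    data: pd.DataFrame
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2:
            raise ValueError("expression matrix needs at least 2 genes")
        if self.data.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 sample")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[gi]!r}, sample {self.data.columns[si]!r}"
            )
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def m(self) -> int:
        """Number of genes."""
        return self.data.shape[0]

    @property
    def s(self) -> int:
        """Number of samples."""
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SampleLabels:
    """Partition of samples into tumor and normal groups."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.assignments.values()} - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected tumor/normal")
        self.assignments = dict(self.assignments)
        if not self.tumor_ids:
            raise ValueError("at least one tumor sample is required")

    @property
    def tumor_ids(self) -> list[str]:
        return [s for s, lab in self.assignments.items() if lab == TUMOR]

    @property
    def normal_ids(self) -> list[str]:
        return [s for s, lab in self.assignments.items() if lab == NORMAL]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = set(self.assignments) - set(expr.sample_ids)
        if missing:
            raise ValueError(
                f"labeled samples absent from the expression matrix: {sorted(missing)}"
            )


@dataclass
class GeneSet:
    """A named marker-gene list (one GMT record)."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        if len(seen) < len(self.genes):
            warnings.warn(
                f"gene set {self.name!r}: duplicate genes dropped", stacklevel=2
            )
        self.genes = tuple(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    genes_in_rows: bool = True,
    scale: Scale = "raw",
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The delimiter is inferred from the extension (``.csv`` → comma,
    everything else → tab) unless given. Duplicate gene rows are collapsed
    by the per-sample maximum; duplicate sample ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path, delimiter)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if genes_in_rows and len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if not genes_in_rows:
        df = df.T
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate sample ids {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[gi, si]!r} at "
            f"row {df.index[gi]!r}, column {df.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[gi]!r}, "
            f"column {df.columns[si]!r}"
        )
    numeric.index = numeric.index.astype(str).str.strip()
    numeric.columns = numeric.columns.astype(str).str.strip()
    if numeric.index.duplicated().any():
        numeric = numeric.groupby(level=0, sort=False).max()
    return ExpressionMatrix(numeric, scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write a genes-by-samples table (12 significant digits, UTF-8)."""
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    expr.data.to_csv(path, sep=sep, float_format="%.12g", index_label="gene_id")


def log2_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the log2(x+1) transform to a raw-scale matrix.

    Refuses already-transformed input (guarding against double
    transformation) and negative raw values.
    """
    if expr.scale == "log2":
        raise ValueError("matrix is already log2-scale; refusing to transform twice")
    values = expr.values
    if (values < 0).any():
        gi, si = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative raw expression value at gene {expr.gene_ids[gi]!r}, "
            f"sample {expr.sample_ids[si]!r}"
        )
    out = pd.DataFrame(
        np.log2(values + 1.0), index=expr.data.index, columns=expr.data.columns
    )
    return ExpressionMatrix(out, scale="log2")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated line per set (name, description, genes...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = (f.strip() for f in fields)
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=desc, genes=tuple(genes)))
    return sets


_LABEL_ALIASES = {TUMOR: TUMOR, NORMAL: NORMAL}


def read_labels(path: str | Path, delimiter: str | None = None) -> SampleLabels:
    """Read a two-column sample/label table (labels tumor/normal, case-insensitive).

    A header line is skipped automatically when its second field is not a
    valid label token.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path, delimiter)
    assignments: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sample_id, label = fields[0], fields[1].lower()
            if label not in _LABEL_ALIASES:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}:{lineno}: unknown label {fields[1]!r} "
                    "(expected tumor or normal)"
                )
            if sample_id in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample_id!r}")
            assignments[sample_id] = _LABEL_ALIASES[label]
    if not assignments:
        raise ValueError(f"{path}: no labeled samples")
    return SampleLabels(assignments)
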