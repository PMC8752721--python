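"""Data containers and file I/O.

The pipeline exchanges four kinds of tables, all plain TSV:

* expression matrix — first column ``gene_id``, remaining columns sample IDs;
* sample metadata — columns ``sample_id`` and ``group`` (extra columns kept);
* network edge list — columns ``regulator``, ``target``, ``weight``;
* regulator list — plain text, one ID per line, ``#`` comments allowed.

Gene and sample identifiers are opaque strings; no symbol mapping is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionData",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "load_regulators",
    "read_network_tsv",
    "write_network_tsv",
]


@dataclass
class ExpressionData:
    """A genes x samples expression matrix with sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix; index = gene IDs, columns = sample IDs.
    annotations : pandas.DataFrame
        Per-sample table indexed by sample ID; must contain a ``group``
        column (group label or time point).
    kind : {"counts", "continuous"}
        ``counts`` marks non-negative integer RNA-seq counts;
        ``continuous`` marks (log-scale) microarray/proteomics intensities.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    kind: Literal["counts", "continuous"] = "continuous"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if "group" not in self.annotations.columns:
            raise ValueError("annotations must contain a 'group' column")
        if not self.values.columns.equals(self.annotations.index):
            missing = set(self.values.columns) ^ set(self.annotations.index)
            raise ValueError(
                f"sample IDs of matrix and annotations disagree: {sorted(missing)}"
            )
        if self.kind not in ("counts", "continuous"):
            raise ValueError(f"unknown data kind: {self.kind!r}")
        if self.kind == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts data contains negative entries")
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    "non-integral count "
                    f"({self.values.index[bad[0]]}, {self.values.columns[bad[1]]})"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.annotations["group"]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionData":
        sample_ids = list(sample_ids)
        return ExpressionData(
            values=self.values.loc[:, sample_ids],
            annotations=self.annotations.loc[sample_ids],
            kind=self.kind,
        )

    def log2_cpm_like(self) -> "ExpressionData":
        """Return a continuous log2(x+1) view (convenience for counts)."""
        return ExpressionData(
            values=np.log2(self.values + 1.0),
            annotations=self.annotations,
            kind="continuous",
        )


def read_expression(path: str | Path, kind: str = "continuous") -> ExpressionData:
    """Read an expression TSV (``gene_id`` first column, samples as header).

    Raises ``ValueError`` with a distinct message for an empty file,
    a malformed header, ragged rows, duplicate gene IDs, or (for counts)
    negative / non-integral entries.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty expression file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"malformed expression TSV {path}: {exc}") from exc
    if df.columns[0] != "gene_id":
        raise ValueError(
            f"malformed header in {path}: first column must be 'gene_id', "
            f"got {df.columns[0]!r}"
        )
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dups}")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"non-numeric expression values in {path}")
    # placeholder single-group annotations; callers attach real metadata
    ann = pd.DataFrame({"group": ["?"] * df.shape[1]}, index=df.columns)
    return ExpressionData(values=df, annotations=ann, kind=kind)  # type: ignore[arg-type]


def write_expression(data: ExpressionData, path: str | Path) -> None:
    out = data.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError(
            f"metadata {path} must have 'sample_id' and 'group' columns, "
            f"got {meta.columns.tolist()}"
        )
    return meta.set_index("sample_id")


def write_metadata(data: ExpressionData, path: str | Path) -> None:
    out = data.annotations.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def attach_metadata(expr: ExpressionData, meta: pd.DataFrame) -> ExpressionData:
    """Align a metadata table to an expression matrix's samples."""
    missing = [s for s in expr.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return ExpressionData(
        values=expr.values,
        annotations=meta.loc[expr.sample_ids],
        kind=expr.kind,
    )


def load_regulators(path: str | Path | None = None) -> list[str]:
    """Load a regulator ID list (one per line, ``#`` comments allowed).

    ``path=None`` loads the bundled default list of human transcription
    factor symbols (a user-replaceable stand-in; supply your own list for
    real analyses).
    """
    if path is None:
        text = (
            resources.files("keyreg.data").joinpath("regulators_default.txt").read_text()
        )
    else:
        text = Path(path).read_text()
    seen: dict[str, None] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            seen.setdefault(line)
    regs = list(seen)
    if not regs:
        raise ValueError("regulator list is empty after parsing")
    return regs


def read_network_tsv(path: str | Path) -> pd.DataFrame:
    """Read an edge-list TSV with columns regulator / target / weight."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    required = {"regulator", "target", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"network TSV {path} must have columns {sorted(required)}, "
            f"got {df.columns.tolist()}"
        )
    return df[["regulator", "target", "weight"]]


def write_network_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.6g")
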