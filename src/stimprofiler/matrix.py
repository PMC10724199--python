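"""Core data containers: expression matrices and sample metadata tables.

An :class:`ExpressionMatrix` is a dense gene x sample table tagged with a
*layer* describing its scale (``raw_counts``, ``fpkm``, ``relative`` or
``centralized``).  Layer transitions happen only through the operations in
:mod:`stimprofiler.preprocess`, which append to the provenance log.

Sample metadata travels as a plain :class:`pandas.DataFrame` (one row per
sample) validated by :func:`validate_samples`; QC flags accumulate in the
``qc_flags`` column as a ``;``-joined string so the table stays TSV-round-
trippable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("raw_counts", "fpkm", "relative", "centralized")

SAMPLE_COLUMNS = (
    "sample_id",
    "donor_id",
    "group",
    "cell_type",
    "condition",
    "activity_score",
    "activity_class",
    "qc_flags",
)

GROUPS = ("HD", "pSS", "SLE")
CELL_TYPES = ("Th", "CTL", "NK", "B")
CONDITIONS = ("steady", "aCD3", "PBS")


@dataclass
class ExpressionMatrix:
    """Dense gene x sample expression table with a layer tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    layer
        One of ``raw_counts``, ``fpkm``, ``relative``, ``centralized``.
    provenance
        Free-text log of the operations that produced this layer.
    """

    values: pd.DataFrame
    layer: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.layer in ("raw_counts", "fpkm") and (arr < 0).any():
            raise ValueError(f"negative values not allowed on layer {self.layer!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given genes and/or samples."""
        values = self.values
        if genes is not None:
            values = values.loc[list(genes)]
        if samples is not None:
            values = values[list(samples)]
        return ExpressionMatrix(values, self.layer, list(self.provenance))

    def derive(self, values: pd.DataFrame, layer: str, note: str) -> "ExpressionMatrix":
        """Create a derived matrix on a (possibly new) layer, logging ``note``."""
        return ExpressionMatrix(values, layer, list(self.provenance) + [note])

    def to_tsv(self, path: str | Path, gene_column: str = "gene_id") -> None:
        out = self.values.copy()
        out.index.name = gene_column
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, layer: str, gene_column: str = "gene_id"
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=gene_column)
        values.index.name = None
        return cls(values, layer, [f"read {layer} matrix from {path}"])


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample metadata table.

    Requires the columns of :data:`SAMPLE_COLUMNS` (``activity_score``,
    ``activity_class`` and ``qc_flags`` may be missing and are added empty).
    Enforces at most one sample per (donor, cell type, condition).
    """
    samples = samples.copy()
    for col in ("activity_score", "activity_class", "qc_flags"):
        if col not in samples.columns:
            samples[col] = "" if col != "activity_score" else np.nan
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    key = samples[["donor_id", "cell_type", "condition"]]
    if key.duplicated().any():
        dupes = samples.loc[key.duplicated(), "sample_id"].tolist()
        raise ValueError(f"more than one sample per donor/cell-type/condition: {dupes}")
    samples["qc_flags"] = samples["qc_flags"].fillna("").astype(str)
    return samples


def add_flag(samples: pd.DataFrame, sample_ids: Iterable[str], flag: str) -> pd.DataFrame:
    """Return a copy of ``samples`` with ``flag`` appended for ``sample_ids``."""
    samples = samples.copy()
    ids = set(sample_ids)
    mask = samples["sample_id"].isin(ids)

    def _append(flags: str) -> str:
        parts = [f for f in flags.split(";") if f]
        if flag not in parts:
            parts.append(flag)
        return ";".join(parts)

    samples.loc[mask, "qc_flags"] = samples.loc[mask, "qc_flags"].map(_append)
    return samples


def passed_qc(samples: pd.DataFrame) -> pd.DataFrame:
    """Rows with an empty QC flag list."""
    return samples[samples["qc_flags"].fillna("") == ""]


def flags_of(samples: pd.DataFrame, sample_id: str) -> list[str]:
    row = samples.loc[samples["sample_id"] == sample_id, "qc_flags"]
    if row.empty:
        raise KeyError(sample_id)
    return [f for f in str(row.iloc[0]).split(";") if f]


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"qc_flags": str})
    return validate_samples(samples)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    validate_samples(samples).to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["gene_id"], table["length"].astype(float)))


def write_gene_lengths(lengths: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(lengths.keys()), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)
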