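"""Tabular input/output for paired Ribo-Seq / RNA-seq analyses.

Everything the pipeline reads or writes is a plain, diffable text table:

* count matrix — TSV/CSV, header row of sample ids, first column gene ids;
* sample sheet — TSV with columns ``sample_id, cell_type, assay, replicate``;
* gene effective lengths — two-column TSV ``gene_id, length`` (nucleotides);
* gene classes — GMT (set name, description, then member ids, tab-separated).

All readers validate aggressively: counts must be non-negative integers,
gene ids unique, and the matrix columns must match the sample sheet exactly.
Fractional counts (e.g. multimapping-weighted) are rejected rather than
rounded so that downstream contracts stay exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger("translatome")

ASSAYS = ("ribo", "rna")

SAMPLE_SHEET_COLUMNS = ("sample_id", "cell_type", "assay", "replicate")


class FormatError(ValueError):
    """A file could not be parsed (bad field, bad number, short line)."""


class ValidationError(ValueError):
    """A parsed table violates a structural invariant."""


class ConsistencyError(ValidationError):
    """Two tables that must agree (e.g. matrix columns vs sample sheet) do not."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per library.

    Columns: ``sample_id`` (unique), ``cell_type`` (e.g. ``"B"``/``"T"``),
    ``assay`` (``"ribo"`` or ``"rna"``), ``replicate`` (positive integer).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in sample sheet")
        bad = sorted(set(t["assay"]) - set(ASSAYS))
        if bad:
            raise ValidationError(f"unknown assay values {bad}; expected {ASSAYS}")
        reps = pd.to_numeric(t["replicate"], errors="coerce")
        if reps.isna().any() or (reps <= 0).any() or (reps != reps.round()).any():
            raise ValidationError("replicate must be a positive integer")
        object.__setattr__(self, "table", t.assign(replicate=reps.astype(int)).reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def select(self, cell_type: str | None = None, assay: str | None = None) -> list[str]:
        """Sample ids matching the given cell type and/or assay, sheet order."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if cell_type is not None:
            mask &= t["cell_type"] == cell_type
        if assay is not None:
            mask &= t["assay"] == assay
        return list(t.loc[mask, "sample_id"])

    def replicates(self, cell_type: str, assay: str) -> dict[int, str]:
        """Map replicate index -> sample_id for one (cell_type, assay) group."""
        t = self.table
        sub = t[(t["cell_type"] == cell_type) & (t["assay"] == assay)]
        if sub["replicate"].duplicated().any():
            raise ValidationError(
                f"duplicate replicate index in group ({cell_type}, {assay})"
            )
        return dict(zip(sub["replicate"], sub["sample_id"]))

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        try:
            t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_type": str, "assay": str})
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"cannot parse sample sheet {path}: {exc}") from exc
        return cls(t)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample counts with attached sample metadata.

    ``counts`` is indexed by gene id; its columns are ordered exactly as the
    sample sheet rows.
    """

    counts: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in count matrix")
        if list(c.columns) != self.samples.sample_ids:
            raise ConsistencyError(
                "count matrix columns do not match sample sheet order"
            )
        if (c.to_numpy() < 0).any():
            raise ValidationError("negative count in count matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.sort_index()
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


def read_counts(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a gene x sample count table and validate it against a sample sheet.

    Column order in the file is irrelevant: columns are harmonized to sheet
    order. Counts must be non-negative and exactly integral.
    """
    sheet = SampleSheet.read(sample_sheet_path)
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0)
    raw.index = raw.index.astype(str)

    matrix_samples = list(raw.columns)
    sheet_samples = sheet.sample_ids
    for s in matrix_samples:
        if s not in sheet_samples:
            raise ConsistencyError(f"matrix sample {s!r} absent from sample sheet")
    for s in sheet_samples:
        if s not in matrix_samples:
            raise ConsistencyError(f"sheet sample {s!r} absent from count matrix")

    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        g, s = _first_bad_cell(numeric.isna())
        raise FormatError(f"non-numeric count at gene {g!r}, sample {s!r}")
    if (numeric < 0).any().any():
        g, s = _first_bad_cell(numeric < 0)
        raise FormatError(f"negative count at gene {g!r}, sample {s!r}")
    frac = numeric != numeric.round()
    if frac.any().any():
        g, s = _first_bad_cell(frac)
        raise FormatError(f"non-integral count at gene {g!r}, sample {s!r}")

    counts = numeric.round().astype(np.int64)[sheet_samples]
    return CountMatrix(counts=counts, samples=sheet)


def _first_bad_cell(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return str(gene), str(sample)


# ---------------------------------------------------------------------------
# Gene lengths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLengthTable:
    """Effective gene lengths in nucleotides, indexed by gene id."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        s = self.lengths
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in length table")
        if (s <= 0).any():
            bad = s.index[s <= 0][0]
            raise ValidationError(f"non-positive length for gene {bad!r}")
        object.__setattr__(self, "lengths", s.astype(np.int64).rename("effective_length"))

    def covers(self, gene_ids: Iterable[str]) -> None:
        missing = [g for g in gene_ids if g not in self.lengths.index]
        if missing:
            raise ValidationError(f"no effective length for gene {missing[0]!r}")

    def to_frame(self) -> pd.DataFrame:
        out = self.lengths.sort_index().reset_index()
        out.columns = ["gene_id", "length"]
        return out


def read_lengths(path: str | Path) -> GeneLengthTable:
    """Read a two-column TSV of gene_id, effective length."""
    t = pd.read_csv(path, sep="\t")
    if t.shape[1] < 2:
        raise FormatError(f"length table {path} needs two columns (gene_id, length)")
    ids = t.iloc[:, 0].astype(str)
    vals = pd.to_numeric(t.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise FormatError(f"non-numeric length at row {row + 2} of {path}")
    return GeneLengthTable(pd.Series(vals.values, index=ids.values))


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered named gene sets, as read from (or written to) a GMT file."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"set key {name!r} != set name {gs.name!r}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gs in self:
                fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members.

    Members are deduplicated within a set (first occurrence wins); set order
    is preserved.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} of {path} has {len(fields)} fields; need >= 3"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(f"duplicate set name {name!r} in {path}")
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m, None)
            sets[name] = GeneSet(name=name, description=desc, members=tuple(seen))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Generic result writing
# ---------------------------------------------------------------------------

def write_results(table, path: str | Path) -> None:
    """Write any tabular result as a TSV with a fixed rendering contract.

    Accepts either a pandas DataFrame or any result object exposing
    ``to_frame()``. Floats are rendered with 6 significant digits; the row
    order is whatever the result type documents (each ``to_frame`` sorts
    deterministically).
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
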