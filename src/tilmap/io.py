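"""Reading and writing per-cell tables.

Cells live in flat CSV tables, one row per cell, with positions in
micrometers (image convention: origin top-left, x rightward, y downward)
and a phenotype label drawn from a fixed, ordered set of cell types.  Two
input dialects are supported:

* a single *combined* CSV with a phenotype column, and
* a set of *per-type* CSVs (one file per cell type, the CytoMAP input
  convention) where the filename stem declares the phenotype.

Region-annotated tables (input columns plus ``region_id`` and
``compartment``) can be written back out for re-import into a viewer such
as QuPath, and round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CELL_TYPES",
    "CellTypeSet",
    "CellTable",
    "SchemaError",
    "ValidationError",
    "read_cells",
    "write_cells_with_regions",
    "qupath_schema",
]

#: Canonical phenotype order used for every feature vector downstream.
DEFAULT_CELL_TYPES = (
    "CD8+TIM3- T cell",
    "CD8+TIM3+ T cell",
    "TIM3+CD8- macrophage",
    "epithelial",
    "stromal",
    "smudge",
)

#: Core columns of the combined-CSV dialect, in canonical order.
CORE_COLUMNS = ("case_id", "cell_id", "x_um", "y_um", "phenotype")


class SchemaError(ValueError):
    """A required column could not be resolved in an input file."""


class ValidationError(ValueError):
    """Input rows violate the cell-table contract."""


def _canon(name: str) -> str:
    """Case-insensitive, whitespace-trimmed phenotype key."""
    return re.sub(r"\s+", " ", str(name).strip()).lower()


@dataclass(frozen=True)
class CellTypeSet:
    """Ordered set of phenotype names.

    The order is significant: it fixes the column order of every
    neighborhood-composition vector and clustering centroid downstream.
    Matching against raw labels is case-insensitive after whitespace
    normalization, because exported class names vary in capitalization.
    """

    names: tuple[str, ...] = DEFAULT_CELL_TYPES

    def __post_init__(self) -> None:
        if len(set(_canon(n) for n in self.names)) != len(self.names):
            raise ValueError("cell type names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        try:
            return self._lookup[_canon(name)]
        except KeyError:
            raise KeyError(f"unknown cell type: {name!r}") from None

    def canonical(self, name: str) -> str:
        """Map a raw label to its canonical spelling."""
        return self.names[self.index(name)]

    def __contains__(self, name: str) -> bool:
        return _canon(name) in self._lookup

    @property
    def _lookup(self) -> dict[str, int]:
        return {_canon(n): i for i, n in enumerate(self.names)}


@dataclass
class CellTable:
    """Positioned, phenotyped single cells grouped by case.

    Parameters
    ----------
    df
        One row per cell with at least the columns ``case_id``, ``cell_id``,
        ``x_um``, ``y_um``, ``phenotype``.  Extra columns (e.g. per-channel
        mean intensities) are carried through untouched.
    cell_types
        The declared phenotype vocabulary; every row's phenotype must be a
        member.  Units are micrometers throughout.
    """

    df: pd.DataFrame
    cell_types: CellTypeSet = field(default_factory=CellTypeSet)

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cell table missing columns: {missing}")
        df = self.df
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = np.where(~np.isfinite(xy).all(axis=1))[0]
            raise ValidationError(f"non-finite coordinates at rows {bad[:10].tolist()}")
        unknown = sorted(
            {p for p in df["phenotype"].unique() if p not in self.cell_types}
        )
        if unknown:
            raise ValidationError(f"unknown phenotype values: {unknown}")
        # canonicalize spelling so downstream comparisons are exact
        df["phenotype"] = [self.cell_types.canonical(p) for p in df["phenotype"]]
        df["case_id"] = df["case_id"].astype(str)
        df["cell_id"] = df["cell_id"].astype(str)
        if df["cell_id"].duplicated().any():
            dups = df.loc[df["cell_id"].duplicated(), "cell_id"].head(5).tolist()
            raise ValidationError(f"duplicate cell_id values: {dups}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def case_ids(self) -> list[str]:
        """Case identifiers in first-appearance order."""
        return list(dict.fromkeys(self.df["case_id"]))

    def case(self, case_id: str) -> "CellTable":
        sub = self.df[self.df["case_id"] == case_id].reset_index(drop=True)
        return CellTable(sub.copy(), self.cell_types)

    def xy(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    def type_counts(self) -> pd.Series:
        """Cell counts per phenotype, in canonical order (zeros included)."""
        counts = self.df["phenotype"].value_counts()
        return counts.reindex(list(self.cell_types), fill_value=0)

    def equals(self, other: "CellTable") -> bool:
        """Field-wise equality on core columns (order-sensitive)."""
        a = self.df[list(CORE_COLUMNS)].reset_index(drop=True)
        b = other.df[list(CORE_COLUMNS)].reset_index(drop=True)
        return a.equals(b)


#: Default column-name map for the combined dialect.  Keys are canonical
#: names, values are lists of accepted raw headers (first match wins).
DEFAULT_SCHEMA: dict[str, list[str]] = {
    "case_id": ["case_id", "case", "Image", "Parent"],
    "cell_id": ["cell_id", "Object ID", "id"],
    "x_um": ["x_um", "x", "Centroid X µm", "Centroid X um"],
    "y_um": ["y_um", "y", "Centroid Y µm", "Centroid Y um"],
    "phenotype": ["phenotype", "Class", "class", "cell_type"],
}


def qupath_schema() -> dict[str, list[str]]:
    """Schema map accepting QuPath detection-export headers."""
    return {k: list(v) for k, v in DEFAULT_SCHEMA.items()}


def _resolve_columns(
    columns: Sequence[str], schema: Mapping[str, Sequence[str]], required: Iterable[str]
) -> dict[str, str]:
    out: dict[str, str] = {}
    for canon in required:
        candidates = schema.get(canon, [canon])
        found = next((c for c in candidates if c in columns), None)
        if found is None:
            raise SchemaError(
                f"cannot resolve column {canon!r}; tried {list(candidates)}, "
                f"file has {list(columns)}"
            )
        out[canon] = found
    return out


def _coerce_coords(df: pd.DataFrame, path) -> pd.DataFrame:
    # element-wise float() is correctly rounded, so repr-serialized
    # coordinates round-trip bit-stably
    for col in ("x_um", "y_um"):
        values = np.empty(len(df), dtype=float)
        bad = []
        for i, v in enumerate(df[col]):
            try:
                values[i] = float(v)
            except (TypeError, ValueError):
                bad.append(i)
        if bad:
            raise ValidationError(
                f"{path}: non-numeric coordinate in column {col!r} at rows {bad[:10]}"
            )
        df[col] = values
    return df


def read_cells(
    paths: str | Path | Sequence[str | Path],
    schema: Mapping[str, Sequence[str]] | None = None,
    cell_types: CellTypeSet | None = None,
) -> CellTable:
    """Read a cell table from a combined CSV or a set of per-type CSVs.

    A single path is read as the combined dialect (phenotype column
    required).  A list of paths is read as the per-type dialect: each
    file's phenotype is its filename stem, matched case-insensitively
    against ``cell_types``.  Row order is preserved within each file.

    Parameters
    ----------
    paths
        One combined CSV path, or a list of per-type CSV paths.
    schema
        Column-name map ``canonical -> accepted raw headers``; defaults to
        :data:`DEFAULT_SCHEMA` (which accepts QuPath headers).
    cell_types
        Phenotype vocabulary; defaults to the six-type panel.
    """
    cell_types = cell_types or CellTypeSet()
    schema = schema or DEFAULT_SCHEMA

    if isinstance(paths, (str, Path)):
        path = Path(paths)
        raw = pd.read_csv(path, dtype=str)
        colmap = _resolve_columns(raw.columns, schema, CORE_COLUMNS)
        df = raw.rename(columns={v: k for k, v in colmap.items()})
        extra = [c for c in df.columns if c not in CORE_COLUMNS]
        df = df[list(CORE_COLUMNS) + extra]
        df = _coerce_coords(df, path)
        for c in extra:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError):
                pass
        return CellTable(df, cell_types)

    frames = []
    required = [c for c in CORE_COLUMNS if c != "phenotype"]
    for p in paths:
        p = Path(p)
        if p.stem not in cell_types:
            raise ValidationError(
                f"{p.name}: filename stem {p.stem!r} is not a declared cell type"
            )
        phenotype = cell_types.canonical(p.stem)
        raw = pd.read_csv(p, dtype=str)
        colmap = _resolve_columns(raw.columns, schema, required)
        df = raw.rename(columns={v: k for k, v in colmap.items()})
        df = _coerce_coords(df[required].copy(), p)
        df["phenotype"] = phenotype
        frames.append(df[list(c for c in CORE_COLUMNS if c in df.columns)])
    if not frames:
        raise ValidationError("no input files given")
    df = pd.concat(frames, ignore_index=True)[list(CORE_COLUMNS)]
    return CellTable(df, cell_types)


def write_cells(table: CellTable, path: str | Path) -> Path:
    """Write a combined-dialect CSV with full-precision coordinates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.df.copy()
    for col in ("x_um", "y_um"):
        df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, index=False)
    return path


def write_cells_with_regions(table: CellTable, assignment, path: str | Path) -> Path:
    """Write a region-annotated CSV for viewer re-import.

    Appends an integer 1-based ``region_id`` and a ``compartment`` string
    to the original columns.  Coordinates are serialized with ``repr`` so
    :func:`read_cells` on the output round-trips positions bit-stably.

    Raises
    ------
    ValidationError
        If the assignment does not cover exactly the cells in ``table``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    adf = assignment.df.set_index("cell_id")
    missing = set(table.df["cell_id"]) - set(adf.index)
    extra = set(adf.index) - set(table.df["cell_id"])
    if missing or extra:
        raise ValidationError(
            f"assignment/table cell-ID mismatch: {len(missing)} cells unassigned, "
            f"{len(extra)} assignments without a cell"
        )
    df = table.df.copy()
    df["region_id"] = adf.loc[df["cell_id"], "region_id"].to_numpy(dtype=int)
    df["compartment"] = adf.loc[df["cell_id"], "compartment"].to_numpy()
    for col in ("x_um", "y_um"):
        df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, index=False)
    return path
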