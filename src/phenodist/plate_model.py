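"""Domain types and CSV I/O for plate maps, cell-level feature tables and batches.

A 96-well plate is addressed by row letter (A-H) and 1-based column (1-12),
e.g. ``"A1"``.  All tabular artifacts are plain CSV with a header row.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ROWS = tuple("ABCDEFGH")
COLUMNS = tuple(range(1, 13))

#: Recognised treatment roles for a well.
ROLES = ("vehicle", "test", "cytotoxic_control", "negative_control")

_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")


class PlateModelError(ValueError):
    """Raised for malformed plate maps or cell tables."""


def well_name(row: str, column: int) -> str:
    """Canonical well label, e.g. ``well_name("A", 1) == "A1"``."""
    return f"{row}{column}"


def parse_well(well: str) -> tuple[str, int]:
    """Split a well label into (row letter, column number); validates bounds."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise PlateModelError(f"malformed well label {well!r}")
    row, column = m.group(1), int(m.group(2))
    if column not in COLUMNS:
        raise PlateModelError(f"well {well!r}: column {column} outside 1-12")
    return row, column


@dataclass(frozen=True)
class WellMeta:
    """Identity and treatment of a single well."""

    plate_id: str
    row: str
    column: int
    chemical: str
    concentration: float
    role: str

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise PlateModelError(
                f"well row {self.row!r} not in A-H (plate {self.plate_id})"
            )
        if self.column not in COLUMNS:
            raise PlateModelError(
                f"well column {self.column} outside 1-12 (plate {self.plate_id})"
            )
        if self.role not in ROLES:
            raise PlateModelError(
                f"unknown role {self.role!r} for well "
                f"{self.plate_id}:{self.well}; expected one of {ROLES}"
            )
        if self.concentration < 0:
            raise PlateModelError(
                f"negative concentration for well {self.plate_id}:{self.well}"
            )

    @property
    def well(self) -> str:
        return well_name(self.row, self.column)


class PlateMap:
    """Collection of :class:`WellMeta`, unique on (plate_id, row, column)."""

    def __init__(self, wells: Iterable[WellMeta]):
        self._wells: dict[tuple[str, str], WellMeta] = {}
        for w in wells:
            key = (w.plate_id, w.well)
            if key in self._wells:
                raise PlateModelError(
                    f"duplicate well {w.plate_id}:{w.well} in plate map"
                )
            self._wells[key] = w

    def __len__(self) -> int:
        return len(self._wells)

    def __iter__(self):
        return iter(self._wells.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._wells

    def get(self, plate_id: str, well: str) -> WellMeta:
        return self._wells[(plate_id, well)]

    @property
    def plate_ids(self) -> list[str]:
        out: list[str] = []
        for w in self._wells.values():
            if w.plate_id not in out:
                out.append(w.plate_id)
        return out

    def wells_with_role(self, role: str) -> list[WellMeta]:
        return [w for w in self._wells.values() if w.role == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plate_id": [w.plate_id for w in self],
                "row": [w.row for w in self],
                "column": [w.column for w in self],
                "chemical": [w.chemical for w in self],
                "concentration": [w.concentration for w in self],
                "role": [w.role for w in self],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CellFeatureTable:
    """Long-format cell-level data: one row per segmented cell.

    ``data`` holds columns ``plate_id``, ``well`` followed by the feature
    columns listed in ``feature_names`` (order preserved from the source file).
    """

    data: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        expected = ["plate_id", "well", *self.feature_names]
        if list(self.data.columns) != expected:
            raise PlateModelError("cell table columns do not match feature list")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class FeatureCatalog:
    """Mapping feature name -> category name; categories partition features."""

    mapping: Mapping[str, str]

    def categories(self) -> list[str]:
        seen: list[str] = []
        for cat in self.mapping.values():
            if cat not in seen:
                seen.append(cat)
        return seen

    def features_in(self, category: str) -> list[str]:
        return [f for f, c in self.mapping.items() if c == category]

    def validate_covers(self, feature_names: Iterable[str]) -> None:
        missing = [f for f in feature_names if f not in self.mapping]
        if missing:
            raise PlateModelError(
                f"{len(missing)} feature(s) missing from catalog, e.g. {missing[:5]}"
            )

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"feature_name": list(self.mapping), "category": list(self.mapping.values())}
        ).to_csv(path, index=False)


@dataclass
class Batch:
    """Merged cell tables + plate map for one experiment, analyzed together."""

    cells: CellFeatureTable
    platemap: PlateMap
    batch_id: str = "batch"

    @property
    def feature_names(self) -> list[str]:
        return self.cells.feature_names

    def subset_wells(self, keys: set[tuple[str, str]]) -> "Batch":
        """Batch restricted to the given (plate_id, well) keys."""
        df = self.cells.data
        flat = df["plate_id"].str.cat(df["well"], sep=":")
        mask = flat.isin({f"{p}:{w}" for p, w in keys}).to_numpy()
        kept_meta = [w for w in self.platemap if (w.plate_id, w.well) in keys]
        return Batch(
            CellFeatureTable(df.loc[mask].reset_index(drop=True), self.feature_names),
            PlateMap(kept_meta),
            self.batch_id,
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

PLATEMAP_COLUMNS = ["plate_id", "row", "column", "chemical", "concentration", "role"]


def read_platemap(path: str | Path) -> PlateMap:
    """Read a plate-map CSV (plate_id,row,column,chemical,concentration,role)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "row": str, "chemical": str})
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateModelError(f"plate map {path}: missing columns {missing}")
    wells = []
    for rec in df.itertuples(index=False):
        row = str(rec.row).strip()
        try:
            column = int(rec.column)
        except (TypeError, ValueError) as exc:
            raise PlateModelError(
                f"plate map {path}: non-integer column {rec.column!r}"
            ) from exc
        wells.append(
            WellMeta(
                plate_id=str(rec.plate_id),
                row=row,
                column=column,
                chemical=str(rec.chemical),
                concentration=float(rec.concentration),
                role=str(rec.role),
            )
        )
    return PlateMap(wells)


def read_feature_catalog(path: str | Path) -> FeatureCatalog:
    df = pd.read_csv(path, dtype=str)
    if not {"feature_name", "category"}.issubset(df.columns):
        raise PlateModelError(
            f"feature catalog {path}: need columns feature_name,category"
        )
    dupes = df["feature_name"][df["feature_name"].duplicated()]
    if len(dupes):
        raise PlateModelError(
            f"feature catalog {path}: duplicate feature(s) {sorted(set(dupes))[:5]}"
        )
    return FeatureCatalog(dict(zip(df["feature_name"], df["category"])))


def read_cell_table(path: str | Path, platemap: PlateMap) -> CellFeatureTable:
    """Read a long-format cell table and cross-reference wells against the map.

    Cells with any missing feature value are dropped (count logged); cells in
    wells absent from the plate map are a hard error.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str},
                     float_precision="round_trip")
    if df.empty:
        raise PlateModelError(f"cell table {path}: no cells")
    for col in ("plate_id", "well"):
        if col not in df.columns:
            raise PlateModelError(f"cell table {path}: missing column {col!r}")
    feature_names = [c for c in df.columns if c not in ("plate_id", "well")]
    if not feature_names:
        raise PlateModelError(f"cell table {path}: no feature columns")
    for w in df["well"].unique():
        parse_well(w)  # validates label shape/bounds
    keys = set(zip(df["plate_id"], df["well"]))
    unmapped = [k for k in keys if k not in platemap]
    if unmapped:
        raise PlateModelError(
            f"cell table {path}: wells not in plate map: {sorted(unmapped)[:5]}"
        )
    feats = df[feature_names].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        # source NaN vs unparsable text are treated the same: the cell is dropped
        raw_na = df[feature_names].isna().any(axis=1)
        if (bad & ~raw_na).any():
            idx = int(df.index[bad & ~raw_na][0])
            raise PlateModelError(
                f"cell table {path}: non-numeric feature value at row {idx}"
            )
        logger.info("dropped %d cell(s) with missing feature values", n_bad)
        df = df.loc[~bad].reset_index(drop=True)
        feats = feats.loc[~bad].reset_index(drop=True)
    if df.empty:
        raise PlateModelError(f"cell table {path}: no complete cells")
    out = pd.concat([df[["plate_id", "well"]], feats.astype(float)], axis=1)
    return CellFeatureTable(out, feature_names)


def merge_batch(
    tables: list[CellFeatureTable],
    platemap: PlateMap,
    batch_id: str = "batch",
) -> Batch:
    """Merge per-plate cell tables into one batch; feature sets must agree."""
    if not tables:
        raise PlateModelError("merge_batch: no tables given")
    ref = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != ref:
            extra = set(t.feature_names) ^ set(ref)
            raise PlateModelError(
                f"merge_batch: feature sets differ, symmetric difference {sorted(extra)}"
            )
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return Batch(CellFeatureTable(data, list(ref)), platemap, batch_id)
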