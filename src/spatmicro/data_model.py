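"""Domain tables, readers/writers, and validation.

All tables are plain :class:`pandas.DataFrame` objects with documented
schemas; the functions here validate them against a taxon panel and the
field-of-view (FoV) geometry and convert between on-disk formats.

Schemas
-------
CellTable
    One row per segmented bacterial cell: ``image_id`` (str), ``x_um`` and
    ``y_um`` (continuous µm, image-local frame with origin at the FoV
    corner), ``taxon_id`` (small int), optionally ``taxon_name``.
ImageMetadata
    One row per image: ``image_id``, ``mouse_id``, ``tissue``
    (cecum/colon), ``treatment`` (water/ampicillin/vancomycin), ``day``
    (int), ``section``, ``fov``, ``fov_width_um``, ``fov_height_um``.
TaxonPanel
    ``taxon_id``, ``taxon_name``, ``is_catchall`` (bool; at most one
    pan-bacterial catch-all entry).
AbundanceMatrix
    Wide integer count matrix, index = ``image_id``, columns = taxon ids.

Coordinates are never compared across images: every FoV is an independent
observation window.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_COLUMNS",
    "META_COLUMNS",
    "TISSUES",
    "TREATMENTS",
    "DEFAULT_FOV_UM",
    "SchemaError",
    "ValidationError",
    "make_panel",
    "validate_panel",
    "validate_cells",
    "read_cell_table",
    "write_cell_table",
    "read_metadata",
    "write_metadata",
    "read_panel",
    "write_panel",
    "tabulate_abundance",
]

CELL_COLUMNS = ["image_id", "x_um", "y_um", "taxon_id"]
META_COLUMNS = [
    "image_id",
    "mouse_id",
    "tissue",
    "treatment",
    "day",
    "section",
    "fov",
    "fov_width_um",
    "fov_height_um",
]
TISSUES = ("cecum", "colon")
TREATMENTS = ("water", "ampicillin", "vancomycin")
DEFAULT_FOV_UM = (135.0, 135.0)


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong dtype."""


class ValidationError(ValueError):
    """Table contents violate an invariant (bounds, panel membership)."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def make_panel(taxon_ids: Iterable[int], names: Iterable[str] | None = None,
               catchall_id: int | None = None) -> pd.DataFrame:
    """Build a TaxonPanel from ids (and optional names / catch-all id)."""
    ids = list(taxon_ids)
    if names is None:
        names = [f"taxon_{t}" for t in ids]
    panel = pd.DataFrame({
        "taxon_id": pd.array(ids, dtype="int64"),
        "taxon_name": list(names),
        "is_catchall": [t == catchall_id for t in ids],
    })
    validate_panel(panel)
    return panel


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    _require_columns(panel, ["taxon_id", "taxon_name"], "TaxonPanel")
    if "is_catchall" not in panel.columns:
        panel = panel.assign(is_catchall=False)
    if panel["taxon_id"].duplicated().any():
        dupes = panel.loc[panel["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise ValidationError(f"duplicate taxon_id in panel: {dupes}")
    if int(panel["is_catchall"].sum()) > 1:
        raise ValidationError("panel may contain at most one catch-all entry")
    return panel


def validate_cells(
    cells: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    fov_um: tuple[float, float] = DEFAULT_FOV_UM,
) -> pd.DataFrame:
    """Validate a CellTable: schema, coordinate bounds, panel membership.

    Duplicate ``(image_id, x_um, y_um, taxon_id)`` rows are dropped.
    Raises :class:`ValidationError` listing offending rows on failure.
    """
    _require_columns(cells, CELL_COLUMNS, "CellTable")
    cells = cells.copy()
    cells["x_um"] = cells["x_um"].astype(float)
    cells["y_um"] = cells["y_um"].astype(float)
    cells["taxon_id"] = cells["taxon_id"].astype(np.int64)

    w, h = fov_um
    bad = (
        (cells["x_um"] < 0) | (cells["x_um"] > w)
        | (cells["y_um"] < 0) | (cells["y_um"] > h)
    )
    if bad.any():
        rows = cells.index[bad].tolist()[:20]
        raise ValidationError(
            f"{int(bad.sum())} cell(s) outside the {w}x{h} um FoV extent "
            f"(first offending rows: {rows})"
        )
    if panel is not None:
        known = set(panel["taxon_id"].astype(int))
        unknown = sorted(set(cells["taxon_id"]) - known)
        if unknown:
            raise ValidationError(f"taxon ids not in panel: {unknown}")
    return cells.drop_duplicates(subset=CELL_COLUMNS).reset_index(drop=True)


# ---------------------------------------------------------------- I/O

def _read_any(path: str) -> pd.DataFrame:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tsv", ".txt"):
        return pd.read_csv(path, sep="\t")
    if ext == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write_any(df: pd.DataFrame, path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tsv", ".txt"):
        df.to_csv(path, sep="\t", index=False)
    elif ext == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_cell_table(path: str, panel: pd.DataFrame | None = None,
                    fov_um: tuple[float, float] = DEFAULT_FOV_UM) -> pd.DataFrame:
    """Read and validate a cell table from CSV/TSV/parquet."""
    return validate_cells(_read_any(path), panel=panel, fov_um=fov_um)


def write_cell_table(cells: pd.DataFrame, path: str) -> None:
    _write_any(cells[ [c for c in cells.columns] ], path)


def read_metadata(path: str) -> pd.DataFrame:
    meta = _read_any(path)
    _require_columns(meta, META_COLUMNS, "ImageMetadata")
    bad_tissue = set(meta["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(f"unknown tissue values: {sorted(bad_tissue)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    _write_any(meta, path)


def read_panel(path: str) -> pd.DataFrame:
    return validate_panel(_read_any(path))


def write_panel(panel: pd.DataFrame, path: str) -> None:
    _write_any(panel, path)


# ------------------------------------------------------ abundance matrix

def tabulate_abundance(
    cells: pd.DataFrame,
    meta: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    include_catchall: bool = True,
) -> pd.DataFrame:
    """Tabulate per-image cell counts into an AbundanceMatrix.

    Every image listed in ``meta`` gets a row; images with no cells get an
    all-zero row. Row sums equal the number of cells per image. When
    ``include_catchall`` is False, cells carrying the panel's catch-all
    (pan-bacterial) label are dropped before counting.
    """
    _require_columns(meta, ["image_id"], "ImageMetadata")
    orphans = sorted(set(cells["image_id"]) - set(meta["image_id"])) if len(cells) else []
    if orphans:
        raise ValidationError(f"cells reference images absent from metadata: {orphans}")

    if panel is not None and not include_catchall:
        catchall = set(panel.loc[panel["is_catchall"].astype(bool), "taxon_id"].astype(int))
        cells = cells[~cells["taxon_id"].isin(catchall)]

    if panel is not None:
        columns = sorted(panel["taxon_id"].astype(int))
        if not include_catchall:
            catchall = set(panel.loc[panel["is_catchall"].astype(bool), "taxon_id"].astype(int))
            columns = [t for t in columns if t not in catchall]
    else:
        columns = sorted(set(cells["taxon_id"].astype(int)))

    mat = (
        cells.groupby(["image_id", "taxon_id"]).size().unstack(fill_value=0)
        if len(cells)
        else pd.DataFrame(index=pd.Index([], name="image_id"))
    )
    mat = mat.reindex(index=list(meta["image_id"]), columns=columns, fill_value=0)
    mat.index.name = "image_id"
    mat.columns.name = "taxon_id"
    return mat.astype(np.int64)
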