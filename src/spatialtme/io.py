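"""Data model and file formats.

The single-cell object is a :class:`CellTable`: a pandas DataFrame of
segmented, phenotyped cells (one row per cell, centroid coordinates in µm)
plus per-ROI metadata and the declared cell-type vocabulary. Microanatomical
compartments (tumour parenchyma vs intratumoural stroma; tumour / capsule /
adjacent liver at the invasive margin) come as :class:`RegionMask` label
rasters at 1 µm²/pixel, the native resolution of imaging mass cytometry.

Coordinate convention: origin at the raster top-left, x rightward along
columns, y downward along rows, units µm; pixel (i, j) covers the half-open
square [j, j+1) × [i, i+1) µm at pixel size 1, so centroid→pixel lookup is
floor-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .params import ParameterError

__all__ = [
    "COMPARTMENTS",
    "UNASSIGNED",
    "Cell",
    "CellTable",
    "RegionMask",
    "SchemaError",
    "read_cell_table",
    "write_cell_table",
    "read_region_mask",
    "write_region_mask",
    "arcsinh_transform",
    "percentile_normalise",
]

UNASSIGNED = "unassigned"
COMPARTMENTS = (UNASSIGNED, "parenchyma", "stroma", "tumour", "capsule", "adjacent_liver")

#: Canonical column names of the internal cell table.
CELL_COLUMNS = ["cell_id", "roi_id", "patient_id", "x", "y", "cell_type", "compartment"]


class SchemaError(ValueError):
    """A required column or vocabulary entry is missing or malformed."""


@dataclass(frozen=True)
class Cell:
    """One segmented cell; a convenience record view of a CellTable row."""

    cell_id: str
    roi_id: str
    patient_id: str
    x: float
    y: float
    cell_type: str
    compartment: str = UNASSIGNED
    subsets: frozenset = frozenset()


@dataclass
class CellTable:
    """Phenotyped single cells of one cohort, grouped by ROI and patient.

    Parameters
    ----------
    cells : pandas.DataFrame
        One row per cell with at least ``cell_id, roi_id, patient_id, x, y,
        cell_type``; ``compartment`` is added (``unassigned``) if missing.
        Extra columns are kept: boolean columns listed in ``subset_columns``
        are marker-gated subset flags (e.g. a PD-1+ flag on CD8 T-cells),
        anything else rides along (e.g. channel intensities).
    roi_meta : pandas.DataFrame
        One row per ROI: ``roi_id, patient_id, roi_kind, roi_area_um2,
        pixel_size_um``.
    type_vocabulary : list of str
        The declared, ordered cell-type vocabulary.
    immune_types : list of str
        Subset of the vocabulary treated as immune cells.
    """

    cells: pd.DataFrame
    roi_meta: pd.DataFrame
    type_vocabulary: list = field(default_factory=list)
    immune_types: list = field(default_factory=list)
    subset_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        cells = self.cells.copy()
        for col in ("cell_id", "roi_id", "patient_id", "x", "y", "cell_type"):
            if col not in cells.columns:
                raise SchemaError(f"cell table missing required column {col!r}")
        if "compartment" not in cells.columns:
            cells["compartment"] = UNASSIGNED
        cells["x"] = pd.to_numeric(cells["x"])
        cells["y"] = pd.to_numeric(cells["y"])
        xy = cells[["x", "y"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise SchemaError(f"non-finite coordinate at row {bad}")
        self.cells = cells.reset_index(drop=True)
        if not self.type_vocabulary:
            self.type_vocabulary = sorted(cells["cell_type"].unique())
        unknown = set(cells["cell_type"]) - set(self.type_vocabulary)
        if unknown:
            raise SchemaError(
                f"cell types outside declared vocabulary: {sorted(unknown)}"
            )
        if not set(self.immune_types) <= set(self.type_vocabulary):
            raise SchemaError("immune_types must be a subset of type_vocabulary")
        meta = self.roi_meta.copy()
        if "roi_id" not in meta.columns:
            raise SchemaError("roi_meta missing 'roi_id'")
        meta = meta.set_index("roi_id", drop=False)
        missing = set(cells["roi_id"]) - set(meta.index)
        if missing:
            raise SchemaError(f"ROIs without metadata: {sorted(missing)}")
        if "roi_area_um2" in meta.columns and (meta["roi_area_um2"] <= 0).any():
            raise SchemaError("roi_area_um2 must be positive")
        self.roi_meta = meta

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def roi_ids(self) -> list:
        return list(self.roi_meta["roi_id"])

    def roi(self, roi_id) -> pd.DataFrame:
        """Cells of one ROI, in table order."""
        return self.cells[self.cells["roi_id"] == roi_id]

    def roi_area_mm2(self, roi_id) -> float:
        return float(self.roi_meta.loc[roi_id, "roi_area_um2"]) / 1e6

    def immune_cells(self) -> pd.DataFrame:
        return self.cells[self.cells["cell_type"].isin(self.immune_types)]

    def with_cells(self, cells: pd.DataFrame) -> "CellTable":
        return CellTable(
            cells=cells,
            roi_meta=self.roi_meta.reset_index(drop=True),
            type_vocabulary=list(self.type_vocabulary),
            immune_types=list(self.immune_types),
            subset_columns=list(self.subset_columns),
        )


@dataclass
class RegionMask:
    """Compartment label raster of one ROI (integer labels, 0 = background).

    ``semantics`` maps every nonzero label to a compartment name; pixel size
    defaults to 1 µm/pixel.
    """

    labels: np.ndarray
    semantics: Mapping[int, str]
    roi_id: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"mask must be a 2D raster, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("mask raster must be integer-typed")
        self.labels = labels
        present = set(np.unique(labels)) - {0}
        unknown = present - set(int(k) for k in self.semantics)
        if unknown:
            raise ValueError(
                f"mask labels without semantics: {sorted(int(v) for v in unknown)}"
            )

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def compartment_at(self, x: float, y: float) -> str | None:
        """Compartment name at a centroid, or None if out of raster bounds.

        A centroid exactly on the right/bottom edge belongs to the last pixel.
        """
        h, w = self.labels.shape
        px = self.pixel_size_um
        j = int(np.floor(x / px))
        i = int(np.floor(y / px))
        if x == w * px:
            j = w - 1
        if y == h * px:
            i = h - 1
        if not (0 <= i < h and 0 <= j < w):
            return None
        label = int(self.labels[i, j])
        if label == 0:
            return UNASSIGNED
        return self.semantics[label]


# ---------------------------------------------------------------------------
# Readers / writers


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    roi_meta: pd.DataFrame | None = None,
    type_vocabulary: Sequence[str] | None = None,
    immune_types: Sequence[str] | None = None,
    subset_columns: Sequence[str] | None = None,
    sep: str = ",",
) -> CellTable:
    """Read a delimited cell table.

    ``schema`` maps canonical names (``cell_id, roi_id, patient_id, x, y,
    cell_type``) to the file's column names; identity mapping by default.
    Missing ROI metadata is reconstructed with a degenerate area from the
    coordinate bounding box — adequate for round-trips, not for densities.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, sep=sep)
    rename = {}
    for canonical in ("cell_id", "roi_id", "patient_id", "x", "y", "cell_type"):
        source = schema.get(canonical, canonical)
        if source not in df.columns:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path}"
            )
        rename[source] = canonical
    df = df.rename(columns=rename)
    for col in ("x", "y"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.index[bad.isna() & df[col].notna()][0])
            raise SchemaError(f"non-numeric {col!r} at row {row}") from exc
    if roi_meta is None:
        groups = df.groupby("roi_id", sort=True)
        records = []
        for roi_id, sub in groups:
            w = float(sub["x"].max()) + 1.0 if len(sub) else 1.0
            h = float(sub["y"].max()) + 1.0 if len(sub) else 1.0
            records.append(
                {
                    "roi_id": roi_id,
                    "patient_id": sub["patient_id"].iloc[0],
                    "roi_kind": "tumour",
                    "roi_area_um2": w * h,
                    "pixel_size_um": 1.0,
                }
            )
        roi_meta = pd.DataFrame(
            records,
            columns=["roi_id", "patient_id", "roi_kind", "roi_area_um2", "pixel_size_um"],
        )
    return CellTable(
        cells=df,
        roi_meta=roi_meta,
        type_vocabulary=list(type_vocabulary or []),
        immune_types=list(immune_types or []),
        subset_columns=list(subset_columns or []),
    )


def write_cell_table(table: CellTable, path: str | Path, sep: str = ",") -> None:
    """Write the cell table with a deterministic column order."""
    ordered = CELL_COLUMNS + [
        c for c in table.cells.columns if c not in CELL_COLUMNS
    ]
    table.cells.to_csv(path, sep=sep, index=False, columns=ordered)


def read_region_mask(
    path: str | Path, semantics: Mapping[int, str], roi_id: str = "",
    pixel_size_um: float = 1.0,
) -> RegionMask:
    """Read a single-channel integer TIFF label raster."""
    raster = tifffile.imread(path)
    if raster.ndim != 2:
        raise ValueError(
            f"expected a single-channel mask, got shape {raster.shape} in {path}"
        )
    if not np.issubdtype(raster.dtype, np.integer):
        raise ValueError(f"mask raster must be integer-typed, got {raster.dtype}")
    return RegionMask(
        labels=raster.astype(np.uint16),
        semantics=dict(semantics),
        roi_id=roi_id or Path(path).stem,
        pixel_size_um=pixel_size_um,
    )


def write_region_mask(mask: RegionMask, path: str | Path) -> None:
    """Write the raster as 16-bit single-channel TIFF (bit-exact round-trip)."""
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# Channel transforms


def arcsinh_transform(values, cofactor: float = 0.5) -> np.ndarray:
    """Inverse-hyperbolic-sine transform ``asinh(v / cofactor)``.

    The standard variance-stabilising transform for mass-cytometry channel
    intensities; strictly monotone, linear near zero and logarithmic for
    large signals.
    """
    if not cofactor > 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor!r}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def percentile_normalise(
    channel,
    p_low: float = 0.0,
    p_high: float = 99.0,
    floor: float = 0.0,
) -> np.ndarray:
    """Percentile-based channel normalisation to [0, 1] with noise floor.

    Values are clipped to the [``p_low``, ``p_high``] percentile window of
    the input, affinely rescaled to [0, 1], and rescaled values below
    ``floor`` are zeroed (background removal). A degenerate percentile
    window (constant input, or ``p_low == p_high``) yields all zeros.
    Optimal percentiles and floors are channel-specific and supplied per
    channel by the caller.
    """
    if not (0 <= p_low < p_high <= 100 or p_low == p_high):
        raise ParameterError(
            f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})"
        )
    arr = np.asarray(channel, dtype=float)
    if arr.size == 0:
        return arr.copy()
    lo, hi = np.percentile(arr, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(arr)
    out = (np.clip(arr, lo, hi) - lo) / (hi - lo)
    if floor > 0:
        out[out < floor] = 0.0
    return out
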