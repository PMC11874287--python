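"""Compartment assignment, areas, densities, frequencies and the CD8 ratio.

Each cell is mapped into the microanatomical compartment (tumour parenchyma,
intratumoural stroma, or the interface compartments) whose mask pixel
contains its centroid. Densities divide cell counts by the ROI area or the
compartment area in mm² (one mask pixel = pixel_size² µm²); when a patient
contributed several ROIs, per-patient values are unweighted means over the
patient's ROIs. The intratumoural CD8 distribution is summarised as the
ratio of parenchymal to stromal CD8 T-cell density.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import UNASSIGNED, CellTable, RegionMask
from .params import ParameterError

__all__ = [
    "assign_compartments",
    "compartment_areas",
    "cell_density",
    "patient_mean",
    "parenchyma_stroma_ratio",
    "flag_low_compartment_rois",
]

logger = logging.getLogger(__name__)

#: Density columns of the records returned by :func:`cell_density`.
DENSITY_COLUMNS = [
    "roi_id", "patient_id", "selector", "compartment",
    "count", "area_mm2", "density",
]


def assign_compartments(
    table: CellTable, masks: Mapping[str, RegionMask]
) -> CellTable:
    """Assign every cell the compartment of the mask pixel under its centroid.

    Cells on background pixels stay ``unassigned``. Centroids outside the
    raster bounds are flagged in a boolean ``out_of_bounds`` column, left
    ``unassigned``, and summarised in the log — never dropped silently.
    """
    missing = set(table.cells["roi_id"]) - set(masks)
    if missing:
        raise KeyError(f"no mask for ROI(s): {sorted(missing)}")
    cells = table.cells.copy()
    compartment = np.full(len(cells), UNASSIGNED, dtype=object)
    out_of_bounds = np.zeros(len(cells), dtype=bool)
    for roi_id, sub in cells.groupby("roi_id", sort=False):
        mask = masks[roi_id]
        idx = sub.index.to_numpy()
        h, w = mask.labels.shape
        px = mask.pixel_size_um
        x = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        j = np.floor(x / px).astype(int)
        i = np.floor(y / px).astype(int)
        # centroid exactly on the right/bottom raster edge -> last pixel
        j[x == w * px] = w - 1
        i[y == h * px] = h - 1
        inside = (i >= 0) & (i < h) & (j >= 0) & (j < w)
        out_of_bounds[idx[~inside]] = True
        labels = mask.labels[i[inside], j[inside]]
        lut = np.full(int(mask.labels.max()) + 1, UNASSIGNED, dtype=object)
        for value, name in mask.semantics.items():
            if int(value) < lut.size:
                lut[int(value)] = name
        compartment[idx[inside]] = lut[labels]
    cells["compartment"] = compartment
    cells["out_of_bounds"] = out_of_bounds
    n_oob = int(out_of_bounds.sum())
    if n_oob:
        logger.warning(
            "%d cell centroid(s) outside mask bounds left unassigned", n_oob
        )
    return table.with_cells(cells)


def compartment_areas(mask: RegionMask) -> dict:
    """Compartment areas in mm² by pixel counting.

    Background (label 0) is excluded from compartment totals and reported
    under the ``"background"`` key.
    """
    px_mm2 = mask.pixel_size_um**2 / 1e6
    values, counts = np.unique(mask.labels, return_counts=True)
    areas: dict = {}
    for value, count in zip(values, counts):
        name = "background" if value == 0 else mask.semantics[int(value)]
        areas[name] = areas.get(name, 0.0) + float(count) * px_mm2
    return areas


def _selector_mask(
    cells: pd.DataFrame, selector
) -> tuple[np.ndarray, str]:
    """Boolean row mask for a selector.

    A selector is a cell-type name, a sequence of type names, a
    ``(column, value)`` pair over a subset-flag column, or a callable
    ``DataFrame -> boolean array``.
    """
    if callable(selector):
        return np.asarray(selector(cells), dtype=bool), getattr(
            selector, "__name__", "custom"
        )
    if isinstance(selector, tuple) and len(selector) == 2:
        column, value = selector
        if column not in cells.columns:
            raise KeyError(f"subset column {column!r} not in cell table")
        return (cells[column] == value).to_numpy(), f"{column}={value}"
    if isinstance(selector, str):
        return (cells["cell_type"] == selector).to_numpy(), selector
    names = list(selector)
    return cells["cell_type"].isin(names).to_numpy(), "|".join(map(str, names))


def cell_density(
    table: CellTable,
    selector,
    compartment: str = "all",
    areas: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-ROI density of the selected cells, cells/mm².

    ``compartment="all"`` divides by the full ROI area from ``roi_meta``;
    a named compartment requires ``areas`` (per-ROI output of
    :func:`compartment_areas`) and counts only cells assigned to it.
    A zero count gives density 0; a zero area with a nonzero count is an
    inconsistency error; zero count over zero area is returned as NaN with
    the ``degenerate`` flag set.
    """
    records = []
    for roi_id in table.roi_ids:
        sub = table.roi(roi_id)
        sel, sel_name = _selector_mask(sub, selector)
        if compartment == "all":
            count = int(sel.sum())
            area = table.roi_area_mm2(roi_id)
        else:
            if areas is None:
                raise ParameterError(
                    "compartment densities need per-ROI compartment areas"
                )
            count = int((sel & (sub["compartment"] == compartment).to_numpy()).sum())
            area = float(areas[roi_id].get(compartment, 0.0))
        degenerate = False
        if area <= 0:
            if count > 0:
                raise ParameterError(
                    f"ROI {roi_id}: {count} cells in compartment "
                    f"{compartment!r} of zero area"
                )
            density, degenerate = math.nan, True
        else:
            density = count / area
        records.append(
            {
                "roi_id": roi_id,
                "patient_id": table.roi_meta.loc[roi_id, "patient_id"],
                "selector": sel_name,
                "compartment": compartment,
                "count": count,
                "area_mm2": area,
                "density": density,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(records, columns=DENSITY_COLUMNS + ["degenerate"])


def patient_mean(records: pd.DataFrame, value: str = "density") -> pd.Series:
    """Unweighted mean of a per-ROI value over each patient's ROIs."""
    return records.groupby("patient_id")[value].mean()


def parenchyma_stroma_ratio(dp: float, ds: float) -> float:
    """Parenchymal:stromal density ratio ``dp / ds``.

    ``ds == 0`` with ``dp > 0`` is +inf (all infiltrate in the parenchyma);
    both zero is undefined and returned as NaN.
    """
    if dp < 0 or ds < 0:
        raise ParameterError("densities must be nonnegative")
    if ds == 0:
        return math.inf if dp > 0 else math.nan
    return dp / ds


def flag_low_compartment_rois(
    areas: Mapping[str, Mapping[str, float]],
    min_fraction: float = 0.05,
    compartments: Sequence[str] = ("parenchyma", "stroma"),
) -> pd.DataFrame:
    """Flag ROIs whose parenchyma or stroma covers less than ``min_fraction``.

    Sensitivity-analysis helper: flags, never drops.
    """
    rows = []
    for roi_id, comp_areas in areas.items():
        total = sum(v for k, v in comp_areas.items() if k != "background")
        fractions = {c: comp_areas.get(c, 0.0) / total if total else 0.0
                     for c in compartments}
        rows.append(
            {
                "roi_id": roi_id,
                **{f"{c}_fraction": fractions[c] for c in compartments},
                "flagged": any(fractions[c] < min_fraction for c in compartments),
            }
        )
    return pd.DataFrame(rows)
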