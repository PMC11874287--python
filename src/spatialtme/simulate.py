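"""Synthetic tumour-microenvironment cohorts.

Everything the pipeline consumes can be simulated: compartment masks
(smooth-noise parenchyma/stroma rasters at 1 µm²/pixel), cell maps
(compartment-wise homogeneous Poisson point patterns over a ~23-type
vocabulary, with optional Thomas-type parent–offspring co-clustering to
plant cell-cell interactions) and per-patient survival tables (exponential
progression-free survival with scenario-specific medians, independent
censoring). The three built-in scenarios realise the immunotype archetypes
— depleted, compartmentalised, enriched — with CD8 densities placed far
from the classifier cutoffs so end-to-end recovery tests measure pipeline
correctness rather than boundary luck; a ``boundary`` scenario sits near
the cutoffs to exercise the conventions deliberately.

All generation is deterministic per seed, and a generated cohort round-trips
losslessly through the package's readers and writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CellTable, RegionMask, read_cell_table, read_region_mask, write_cell_table, write_region_mask
from .params import ParameterError

__all__ = [
    "DEFAULT_VOCABULARY",
    "DEFAULT_IMMUNE_TYPES",
    "Scenario",
    "CohortBundle",
    "default_scenarios",
    "generate_mask",
    "generate_cells",
    "generate_survival_times",
    "generate_cohort",
    "generate_planted_architecture",
    "write_cohort",
    "read_cohort",
]

#: Default 23-type cell vocabulary of an HCC tumour microenvironment.
DEFAULT_VOCABULARY = [
    "Tumour cell", "Hepatocyte", "Cholangiocyte", "Endothelial cell",
    "Fibroblast", "Smooth muscle cell",
    "CD8 T-cell", "CD4 T-cell", "Treg", "Tfh", "MAIT", "NK cell", "NKT cell",
    "B cell", "Plasma cell", "Macrophage", "CD204 macrophage", "Kupffer cell",
    "Monocyte", "Dendritic cell", "Neutrophil", "Mast cell", "pDC",
]

DEFAULT_IMMUNE_TYPES = DEFAULT_VOCABULARY[6:]

#: Background (non-CD8) intensities in cells/mm² shared by all scenarios:
#: structural cells dominate their home compartment, immune background is
#: sparse and uniform.
_BASE_INTENSITIES = {
    ("Tumour cell", "parenchyma"): 600.0,
    ("Cholangiocyte", "parenchyma"): 20.0,
    ("Endothelial cell", "parenchyma"): 60.0,
    ("Endothelial cell", "stroma"): 120.0,
    ("Fibroblast", "stroma"): 400.0,
    ("Smooth muscle cell", "stroma"): 60.0,
    **{
        (t, comp): 15.0
        for t in DEFAULT_IMMUNE_TYPES
        if t != "CD8 T-cell"
        for comp in ("parenchyma", "stroma")
    },
}


@dataclass
class Scenario:
    """One generating condition for an ROI / patient.

    ``intensities`` maps (cell type, compartment) to cells/mm²;
    ``co_cluster`` lists (type A, type B, cluster radius µm, mean offspring
    per parent) tuples — each A cell seeds a Poisson number of extra B cells
    Gaussian-displaced around it, planting A–B proximity. ``pfs_median`` is
    the median progression-free survival in months; ``censor_rate`` the
    probability a patient is censored before the event.
    """

    name: str
    stroma_fraction: float
    intensities: Mapping[tuple, float]
    co_cluster: Sequence[tuple] = ()
    pfs_median: float = 6.0
    censor_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.stroma_fraction <= 1.0:
            raise ParameterError("stroma_fraction must lie in [0, 1]")
        if any(v < 0 for v in self.intensities.values()):
            raise ParameterError("intensities must be nonnegative")
        if not self.pfs_median > 0:
            raise ParameterError("pfs_median must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ParameterError("censor_rate must lie in [0, 1)")


def default_scenarios() -> dict:
    """The three immunotype archetypes plus a near-cutoff boundary scenario.

    CD8 densities (parenchyma/stroma, cells/mm²): depleted 50/50 (overall
    well below the 200 cutoff), compartmentalised 80/600 (ratio 0.13, well
    below both ratio cutoffs), enriched 500/500 (ratio 1). Median PFS
    follows the ordering enriched 8.3 > compartmentalised 6.6 > depleted 4.1
    months.
    """

    def scenario(name, cd8_par, cd8_str, stroma_fraction, pfs_median):
        intensities = dict(_BASE_INTENSITIES)
        intensities[("CD8 T-cell", "parenchyma")] = cd8_par
        intensities[("CD8 T-cell", "stroma")] = cd8_str
        return Scenario(
            name=name,
            stroma_fraction=stroma_fraction,
            intensities=intensities,
            pfs_median=pfs_median,
        )

    return {
        "depleted": scenario("depleted", 50.0, 50.0, 0.35, 4.1),
        "compartmentalised": scenario("compartmentalised", 80.0, 600.0, 0.40, 6.6),
        "enriched": scenario("enriched", 500.0, 500.0, 0.35, 8.3),
        "boundary": scenario("boundary", 110.0, 200.0, 0.40, 6.0),
    }


# ---------------------------------------------------------------------------
# Masks


def generate_mask(
    width: float = 1000.0,
    height: float = 1000.0,
    stroma_fraction: float = 0.35,
    blob_scale: float = 120.0,
    seed: int = 0,
    roi_id: str = "roi",
) -> RegionMask:
    """Smooth-noise parenchyma/stroma mask at 1 µm²/pixel.

    White noise is Gaussian-smoothed at ``blob_scale`` µm and thresholded at
    the quantile that makes the stroma pixel fraction match the target
    (within ±0.02 by construction — the quantile cut is exact up to ties).
    Fractions of exactly 0 or 1 yield uniform masks. Label semantics:
    1 = parenchyma, 2 = stroma.
    """
    if width < 100 or height < 100:
        raise ParameterError("mask dimensions must be >= 100 µm")
    if not blob_scale > 0:
        raise ParameterError("blob_scale must be positive")
    h, w = int(round(height)), int(round(width))
    semantics = {1: "parenchyma", 2: "stroma"}
    if stroma_fraction <= 0.0:
        labels = np.ones((h, w), dtype=np.uint16)
    elif stroma_fraction >= 1.0:
        labels = np.full((h, w), 2, dtype=np.uint16)
    else:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((h, w))
        smooth = ndimage.gaussian_filter(noise, sigma=blob_scale / 4.0)
        threshold = np.quantile(smooth, 1.0 - stroma_fraction)
        labels = np.where(smooth >= threshold, 2, 1).astype(np.uint16)
    return RegionMask(labels=labels, semantics=semantics, roi_id=roi_id)


# ---------------------------------------------------------------------------
# Cells


def _sample_in_compartment(
    mask: RegionMask, label_value: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside the pixels carrying ``label_value`` (µm)."""
    ii, jj = np.nonzero(mask.labels == label_value)
    if len(ii) == 0:
        if n > 0:
            raise ParameterError(
                f"compartment label {label_value} absent from mask {mask.roi_id}"
            )
        return np.empty((0, 2))
    pick = rng.integers(0, len(ii), size=n)
    px = mask.pixel_size_um
    x = (jj[pick] + rng.random(n)) * px
    y = (ii[pick] + rng.random(n)) * px
    return np.column_stack([x, y])


def generate_cells(
    mask: RegionMask,
    scenario: Scenario,
    seed: int = 0,
    roi_id: str | None = None,
    patient_id: str = "P0",
    max_cells: int = 500_000,
    vocabulary: Sequence[str] | None = None,
    immune_types: Sequence[str] | None = None,
) -> CellTable:
    """Realise one ROI's cell map from a scenario.

    Each (type, compartment) intensity drives an independent homogeneous
    Poisson process over that compartment's pixels, so realised compartment
    densities are unbiased estimates of the intensities. Co-cluster entries
    then add offspring B cells around every A parent (Gaussian displacement,
    points falling outside the raster are redrawn a few times then clipped).
    """
    rng = np.random.default_rng(seed)
    roi = roi_id or mask.roi_id
    vocabulary = list(vocabulary or DEFAULT_VOCABULARY)
    immune_types = list(immune_types or DEFAULT_IMMUNE_TYPES)
    label_of = {name: value for value, name in mask.semantics.items()}
    px_mm2 = mask.pixel_size_um**2 / 1e6
    comp_area = {
        name: float(np.sum(mask.labels == value)) * px_mm2
        for value, name in mask.semantics.items()
    }
    expected_total = sum(
        rate * comp_area.get(comp, 0.0)
        for (_, comp), rate in scenario.intensities.items()
    )
    if expected_total > max_cells:
        raise ParameterError(
            f"expected cell count {expected_total:.0f} exceeds cap {max_cells}"
        )
    xs, ys, types = [], [], []
    for (cell_type, comp), rate in sorted(scenario.intensities.items()):
        if cell_type not in vocabulary:
            raise ParameterError(f"scenario type {cell_type!r} not in vocabulary")
        area = comp_area.get(comp, 0.0)
        if rate <= 0 or area <= 0:
            continue
        n = int(rng.poisson(rate * area))
        pts = _sample_in_compartment(mask, label_of[comp], n, rng)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        types.extend([cell_type] * n)
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    types = np.asarray(types, dtype=object)

    # planted co-clustering: offspring B cells around each A parent
    h, w = mask.labels.shape
    px = mask.pixel_size_um
    for type_a, type_b, radius, offspring in scenario.co_cluster:
        parents = np.flatnonzero(types == type_a)
        if len(parents) == 0:
            continue
        counts = rng.poisson(offspring, size=len(parents))
        total = int(counts.sum())
        if total == 0:
            continue
        centres = np.column_stack([x[parents], y[parents]])
        centres = np.repeat(centres, counts, axis=0)
        pts = centres + rng.normal(scale=radius, size=(total, 2))
        for _ in range(5):  # redraw points that left the raster
            outside = (
                (pts[:, 0] < 0) | (pts[:, 0] >= w * px)
                | (pts[:, 1] < 0) | (pts[:, 1] >= h * px)
            )
            if not outside.any():
                break
            pts[outside] = centres[outside] + rng.normal(
                scale=radius, size=(int(outside.sum()), 2)
            )
        pts[:, 0] = np.clip(pts[:, 0], 0.0, np.nextafter(w * px, 0.0))
        pts[:, 1] = np.clip(pts[:, 1], 0.0, np.nextafter(h * px, 0.0))
        x = np.concatenate([x, pts[:, 0]])
        y = np.concatenate([y, pts[:, 1]])
        types = np.concatenate([types, np.full(total, type_b, dtype=object)])

    order = np.lexsort((x, y))
    n_cells = len(order)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{roi}_c{i:06d}" for i in range(n_cells)],
            "roi_id": roi,
            "patient_id": patient_id,
            "x": x[order],
            "y": y[order],
            "cell_type": types[order],
        }
    )
    roi_meta = pd.DataFrame(
        [
            {
                "roi_id": roi,
                "patient_id": patient_id,
                "roi_kind": "tumour",
                "roi_area_um2": float(h * w) * px**2,
                "pixel_size_um": px,
            }
        ]
    )
    return CellTable(
        cells=cells,
        roi_meta=roi_meta,
        type_vocabulary=vocabulary,
        immune_types=immune_types,
    )


# ---------------------------------------------------------------------------
# Survival and cohorts


def generate_survival_times(
    n: int, median: float, censor_rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential event times (hazard ln 2 / median) with random censoring.

    With probability ``censor_rate`` a patient is censored at a uniformly
    earlier time instead of observed.
    """
    scale = median / math.log(2.0)
    times = rng.exponential(scale=scale, size=n)
    censored = rng.random(n) < censor_rate
    times = np.where(censored, times * rng.random(n), times)
    times = np.maximum(times, 1e-6)
    return pd.DataFrame({"time": times, "event": ~censored})


@dataclass
class CohortBundle:
    """A complete synthetic cohort: cells, masks, clinical table and truth."""

    table: CellTable
    masks: dict
    survival: pd.DataFrame  # patient_id, time, event, group (truth scenario)
    truth: pd.DataFrame  # roi_id, patient_id, scenario, patient_scenario, heterogeneous


def generate_cohort(
    scenario_counts: Mapping[str, int],
    rois_per_patient: int = 2,
    heterogeneity_rate: float = 0.0,
    seed: int = 0,
    roi_size_um: float = 1000.0,
    scenarios: Mapping[str, Scenario] | None = None,
) -> CohortBundle:
    """Generate a patient cohort of scenario-driven ROIs plus survival.

    ``scenario_counts`` gives patients per scenario name. Each patient
    contributes ``rois_per_patient`` ROIs from their scenario; with
    probability ``heterogeneity_rate`` (patients with >= 2 ROIs) one ROI is
    drawn from a different scenario instead, mimicking intratumour
    immunotype heterogeneity. Ground-truth labels are retained per ROI and
    patient for recovery testing.
    """
    scenarios = dict(scenarios or default_scenarios())
    unknown = set(scenario_counts) - set(scenarios)
    if unknown:
        raise ParameterError(f"unknown scenario name(s): {sorted(unknown)}")
    if rois_per_patient < 1:
        raise ParameterError("rois_per_patient must be >= 1")
    rng = np.random.default_rng(seed)
    tables, masks, truth_rows, surv_rows = [], {}, [], []
    patient_idx = 0
    for scen_name in sorted(scenario_counts):
        base = scenarios[scen_name]
        for _ in range(int(scenario_counts[scen_name])):
            patient_id = f"P{patient_idx:03d}"
            patient_idx += 1
            roi_scenarios = [scen_name] * rois_per_patient
            heterogeneous = False
            if rois_per_patient >= 2 and rng.random() < heterogeneity_rate:
                others = [s for s in sorted(scenarios) if s != scen_name]
                swap = int(rng.integers(rois_per_patient))
                roi_scenarios[swap] = others[int(rng.integers(len(others)))]
                heterogeneous = True
            for r, roi_scen in enumerate(roi_scenarios):
                roi_id = f"{patient_id}_R{r}"
                scen = scenarios[roi_scen]
                mask_seed = int(rng.integers(2**31))
                cell_seed = int(rng.integers(2**31))
                mask = generate_mask(
                    roi_size_um, roi_size_um, scen.stroma_fraction,
                    seed=mask_seed, roi_id=roi_id,
                )
                masks[roi_id] = mask
                tables.append(
                    generate_cells(
                        mask, scen, seed=cell_seed,
                        roi_id=roi_id, patient_id=patient_id,
                    )
                )
                truth_rows.append(
                    {
                        "roi_id": roi_id,
                        "patient_id": patient_id,
                        "scenario": roi_scen,
                        "patient_scenario": scen_name,
                        "heterogeneous": heterogeneous,
                    }
                )
            surv = generate_survival_times(1, base.pfs_median, base.censor_rate, rng)
            surv_rows.append(
                {
                    "patient_id": patient_id,
                    "time": float(surv["time"].iloc[0]),
                    "event": bool(surv["event"].iloc[0]),
                    "group": scen_name,
                }
            )
    first = tables[0]
    table = CellTable(
        cells=pd.concat([t.cells for t in tables], ignore_index=True),
        roi_meta=pd.concat(
            [t.roi_meta.reset_index(drop=True) for t in tables], ignore_index=True
        ),
        type_vocabulary=first.type_vocabulary,
        immune_types=first.immune_types,
    )
    return CohortBundle(
        table=table,
        masks=masks,
        survival=pd.DataFrame(surv_rows),
        truth=pd.DataFrame(truth_rows),
    )


def generate_planted_architecture(
    seed: int = 0,
    band_width_um: float = 400.0,
    n_bands: int = 3,
    immune_density: float = 1500.0,
    dominance: float = 0.75,
    roi_id: str = "planted",
) -> tuple[CellTable, pd.Series]:
    """ROI with three planted immune architectures in spatial bands.

    Vertical bands (each ``band_width_um`` wide and twice as tall) are
    dominated by, in order, a CD8/plasma mix, a myeloid mix and a B/CD4 mix
    (``dominance`` fraction of dominant types, the rest uniform immune
    background), at the cell density of an immune aggregate, so
    neighbourhood detection should recover the band identity of most cells.
    Returns the table and the per-cell ground-truth band label (indexed by
    cell_id; structural cells excluded).
    """
    rng = np.random.default_rng(seed)
    mixes = [
        ("CD8-hub", ["CD8 T-cell", "Plasma cell"]),
        ("myeloid-hub", ["Macrophage", "CD204 macrophage", "Dendritic cell"]),
        ("B/CD4-hub", ["B cell", "CD4 T-cell"]),
    ]
    width = band_width_um * n_bands
    xs, ys, types, truth = [], [], [], []
    height = 2 * band_width_um
    for b in range(n_bands):
        label, dominant = mixes[b % len(mixes)]
        n = rng.poisson(immune_density * band_width_um * height / 1e6)
        x = rng.uniform(b * band_width_um, (b + 1) * band_width_um, size=n)
        y = rng.uniform(0, height, size=n)
        background = [t for t in DEFAULT_IMMUNE_TYPES if t not in dominant]
        choice = np.where(
            rng.random(n) < dominance,
            rng.choice(dominant, size=n),
            rng.choice(background, size=n),
        )
        xs.append(x)
        ys.append(y)
        types.extend(choice.tolist())
        truth.extend([label] * n)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n_cells = len(x)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{roi_id}_c{i:05d}" for i in range(n_cells)],
            "roi_id": roi_id,
            "patient_id": "P0",
            "x": x,
            "y": y,
            "cell_type": types,
        }
    )
    roi_meta = pd.DataFrame(
        [
            {
                "roi_id": roi_id,
                "patient_id": "P0",
                "roi_kind": "tumour",
                "roi_area_um2": width * height,
                "pixel_size_um": 1.0,
            }
        ]
    )
    table = CellTable(
        cells=cells,
        roi_meta=roi_meta,
        type_vocabulary=DEFAULT_VOCABULARY,
        immune_types=DEFAULT_IMMUNE_TYPES,
    )
    truth_series = pd.Series(truth, index=cells["cell_id"], name="truth")
    return table, truth_series


# ---------------------------------------------------------------------------
# Disk round-trip


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write a cohort as plain files: cells.csv, roi_meta.csv, masks/*.tiff,
    clinical.csv, truth.csv, vocabulary.csv."""
    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    write_cell_table(bundle.table, outdir / "cells.csv")
    bundle.table.roi_meta.reset_index(drop=True).to_csv(
        outdir / "roi_meta.csv", index=False
    )
    pd.DataFrame(
        {
            "cell_type": bundle.table.type_vocabulary,
            "immune": [
                t in bundle.table.immune_types for t in bundle.table.type_vocabulary
            ],
        }
    ).to_csv(outdir / "vocabulary.csv", index=False)
    for roi_id, mask in bundle.masks.items():
        write_region_mask(mask, outdir / "masks" / f"{roi_id}.tiff")
    bundle.survival.to_csv(outdir / "clinical.csv", index=False)
    bundle.truth.to_csv(outdir / "truth.csv", index=False)


def read_cohort(indir: str | Path) -> CohortBundle:
    indir = Path(indir)
    vocab = pd.read_csv(indir / "vocabulary.csv")
    roi_meta = pd.read_csv(indir / "roi_meta.csv")
    table = read_cell_table(
        indir / "cells.csv",
        roi_meta=roi_meta,
        type_vocabulary=vocab["cell_type"].tolist(),
        immune_types=vocab.loc[vocab["immune"], "cell_type"].tolist(),
    )
    semantics = {1: "parenchyma", 2: "stroma"}
    masks = {}
    for path in sorted((indir / "masks").glob("*.tiff")):
        masks[path.stem] = read_region_mask(path, semantics, roi_id=path.stem)
    survival = pd.read_csv(indir / "clinical.csv")
    truth = pd.read_csv(indir / "truth.csv")
    return CohortBundle(table=table, masks=masks, survival=survival, truth=truth)
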