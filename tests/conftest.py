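"""Shared fixtures: tiny hand-checkable tables and generated ROIs."""

import numpy as np
import pandas as pd
import pytest

from spatialtme import CellTable, RegionMask


def make_cells(points, roi_id="r1", patient_id="P1", **extra):
    """Cell DataFrame from (x, y, cell_type) triples."""
    rows = [
        {
            "cell_id": f"c{i:03d}",
            "roi_id": roi_id,
            "patient_id": patient_id,
            "x": float(x),
            "y": float(y),
            "cell_type": t,
        }
        for i, (x, y, t) in enumerate(points)
    ]
    columns = ["cell_id", "roi_id", "patient_id", "x", "y", "cell_type"]
    df = pd.DataFrame(rows, columns=columns)
    for k, v in extra.items():
        df[k] = v
    return df


def make_table(points, roi_area_um2=1e6, immune_types=None, **extra):
    df = make_cells(points, **{k: v for k, v in extra.items() if k in ("roi_id", "patient_id")})
    roi_id = df["roi_id"].iloc[0] if len(df) else "r1"
    patient_id = df["patient_id"].iloc[0] if len(df) else "P1"
    meta = pd.DataFrame(
        [
            {
                "roi_id": roi_id,
                "patient_id": patient_id,
                "roi_kind": "tumour",
                "roi_area_um2": roi_area_um2,
                "pixel_size_um": 1.0,
            }
        ]
    )
    return CellTable(
        cells=df,
        roi_meta=meta,
        immune_types=list(immune_types or []),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def half_mask():
    """100x100 µm mask: left half parenchyma (1), right half stroma (2)."""
    labels = np.ones((100, 100), dtype=np.uint16)
    labels[:, 50:] = 2
    return RegionMask(
        labels=labels, semantics={1: "parenchyma", 2: "stroma"}, roi_id="r1"
    )
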