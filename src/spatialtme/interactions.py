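"""Permutation interaction / avoidance testing between cell subsets.

For an ordered pair of subsets (A, B) on the expansion-contact graph of one
ROI, the directional interaction score counts B neighbours of A cells:

* ``histocat`` method — total number of B neighbours over all A cells,
  divided by the number of A cells that have at least one B neighbour;
* ``classic`` method — the same total divided by the number of A cells.

The observed score is ranked against a null distribution obtained by
permuting subset labels over the fixed cell positions (equivalent to
randomising cell localisations on the image, at a fraction of the cost,
because the graph depends only on positions). A score in the upper
``tail_fraction`` of the null is a significant interaction, in the lower
tail a significant avoidance. Calls are made per ROI; downstream group
comparisons, not the per-ROI calls, are where multiplicity correction
belongs.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .graphs import SpatialGraph
from .io import CellTable, SchemaError
from .params import ParameterError

__all__ = [
    "interaction_score",
    "permutation_interaction_test",
    "summarise_interactions",
]

RECORD_COLUMNS = [
    "roi_id", "from_subset", "to_subset", "observed",
    "null_percentile", "call", "n_permutations",
]


def _labels_for(graph: SpatialGraph, cells, column: str) -> np.ndarray:
    df = cells.cells if isinstance(cells, CellTable) else cells
    if column not in df.columns:
        raise SchemaError(f"subset column {column!r} not in cell table")
    if not np.array_equal(df["cell_id"].to_numpy(), graph.cell_ids):
        raise ValueError("graph and cell table rows do not match")
    return df[column].to_numpy()


def _score_from_counts(n_b_neigh: np.ndarray, is_a: np.ndarray, method: str) -> float:
    """Score from per-cell B-neighbour counts; NaN when undefined."""
    counts = n_b_neigh[is_a]
    if method == "histocat":
        denom = int((counts > 0).sum())
    elif method == "classic":
        denom = int(is_a.sum())
    else:
        raise ParameterError(f"unknown interaction method {method!r}")
    if denom == 0:
        return math.nan
    return float(counts.sum()) / denom


def _b_neighbour_counts(graph: SpatialGraph, is_b: np.ndarray) -> np.ndarray:
    counts = np.zeros(graph.n_cells, dtype=np.int64)
    if graph.n_edges:
        src = graph.edges[:, 0]
        dst = graph.edges[:, 1]
        np.add.at(counts, src[is_b[dst]], 1)
    return counts


def interaction_score(
    graph: SpatialGraph,
    cells,
    a,
    b,
    method: str = "histocat",
    label_column: str = "cell_type",
) -> float:
    """Directional interaction score of subset ``a`` towards subset ``b``.

    Self-pairs (a == b) count neighbours of the same subset; a cell is never
    its own neighbour. Returns NaN when the method's denominator is zero
    (histocat: no A cell touches a B cell; classic: no A cells).
    """
    labels = _labels_for(graph, cells, label_column)
    is_a = labels == a
    is_b = labels == b
    return _score_from_counts(_b_neighbour_counts(graph, is_b), is_a, method)


def permutation_interaction_test(
    graph: SpatialGraph,
    cells,
    pairs: Sequence[tuple],
    n_perm: int = 1000,
    tail_fraction: float = 0.05,
    seed: int = 0,
    method: str = "histocat",
    label_column: str = "cell_type",
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Permutation test of interaction/avoidance for each (A, B) pair.

    One label permutation per iteration is shared by every pair, exactly as
    if the cells had been relocated. The observed score's percentile in the
    null uses mid-ranking of ties,
    ``(#null < obs + 0.5 #null == obs + 0.5) / (n_defined + 1)``,
    which avoids degenerate 0/1 percentiles and keeps upper and lower calls
    symmetric. Permutations whose score is undefined are excluded from the
    null count. ``stratify_by`` optionally shuffles labels only within a
    grouping column (e.g. compartment).

    Returns one record per pair with columns ``roi_id, from_subset,
    to_subset, observed, null_percentile, call, n_permutations``;
    ``call`` is ``interaction`` (percentile >= 1 - tail), ``avoidance``
    (percentile <= tail), ``ns`` otherwise, or ``undefined`` when the
    observed score has a zero denominator.
    """
    if not 0 < tail_fraction < 0.5:
        raise ParameterError(f"tail_fraction must be in (0, 0.5), got {tail_fraction}")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    labels = _labels_for(graph, cells, label_column)
    rng = np.random.default_rng(seed)
    n = graph.n_cells

    strata: list[np.ndarray]
    if stratify_by is not None:
        df = cells.cells if isinstance(cells, CellTable) else cells
        groups = df[stratify_by].to_numpy()
        strata = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    else:
        strata = [np.arange(n)]

    pair_list = [(a, b) for a, b in pairs]
    subset_values = sorted({v for ab in pair_list for v in ab})
    observed = {}
    for a, b in pair_list:
        is_a = labels == a
        is_b = labels == b
        observed[(a, b)] = _score_from_counts(
            _b_neighbour_counts(graph, is_b), is_a, method
        )

    null_lt = {ab: 0 for ab in pair_list}
    null_eq = {ab: 0 for ab in pair_list}
    null_n = {ab: 0 for ab in pair_list}
    perm = labels.copy()
    for _ in range(n_perm):
        for idx in strata:
            perm[idx] = perm[idx[rng.permutation(len(idx))]]
        masks = {v: perm == v for v in subset_values}
        b_counts = {
            b: _b_neighbour_counts(graph, masks[b])
            for b in {b for _, b in pair_list}
        }
        for a, b in pair_list:
            obs = observed[(a, b)]
            if math.isnan(obs):
                continue
            score = _score_from_counts(b_counts[b], masks[a], method)
            if math.isnan(score):
                continue
            null_n[(a, b)] += 1
            if score < obs:
                null_lt[(a, b)] += 1
            elif score == obs:
                null_eq[(a, b)] += 1

    records = []
    for a, b in pair_list:
        obs = observed[(a, b)]
        if math.isnan(obs):
            percentile, call = math.nan, "undefined"
        else:
            m = null_n[(a, b)]
            percentile = (null_lt[(a, b)] + 0.5 * null_eq[(a, b)] + 0.5) / (m + 1)
            if percentile >= 1.0 - tail_fraction:
                call = "interaction"
            elif percentile <= tail_fraction:
                call = "avoidance"
            else:
                call = "ns"
        records.append(
            {
                "roi_id": graph.roi_id,
                "from_subset": a,
                "to_subset": b,
                "observed": obs,
                "null_percentile": percentile,
                "call": call,
                "n_permutations": n_perm,
            }
        )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def summarise_interactions(
    records: pd.DataFrame, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Cohort summary: per (group, A, B), ROI counts and call fractions.

    ``grouping`` maps roi_id to a group label (e.g. the patient's spatial
    immunotype, or an IN when testing within neighbourhoods); without it all
    ROIs form one group.
    """
    df = records.copy()
    if grouping is not None:
        df["group"] = df["roi_id"].map(grouping)
    else:
        df["group"] = "all"
    rows = []
    for (group, a, b), sub in df.groupby(
        ["group", "from_subset", "to_subset"], sort=True
    ):
        n_roi = sub["roi_id"].nunique()
        n_int = int((sub["call"] == "interaction").sum())
        n_avoid = int((sub["call"] == "avoidance").sum())
        rows.append(
            {
                "group": group,
                "from_subset": a,
                "to_subset": b,
                "n_roi": n_roi,
                "n_interaction": n_int,
                "n_avoidance": n_avoid,
                "frac_interaction": n_int / n_roi if n_roi else math.nan,
                "frac_avoidance": n_avoid / n_roi if n_roi else math.nan,
            }
        )
    columns = [
        "group", "from_subset", "to_subset", "n_roi",
        "n_interaction", "n_avoidance", "frac_interaction", "frac_avoidance",
    ]
    return pd.DataFrame(rows, columns=columns)
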