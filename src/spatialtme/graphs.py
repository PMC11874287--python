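"""Spatial neighbour graphs over the cells of one ROI.

Two neighbour relations drive the analysis:

* the **kNN graph** — each cell's k closest neighbours (Euclidean centroid
  distance) within a maximum radius; directed, used to build the local
  composition profiles that feed immune-neighbourhood detection;
* the **expansion-contact graph** — cells modelled as discs, linked when
  their boundaries come within twice the expansion distance of each other;
  symmetric, used for close-interaction permutation testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import CellTable, SchemaError
from .params import ParameterError

__all__ = ["SpatialGraph", "build_knn_graph", "build_expansion_graph", "neighbour_profile"]


@dataclass
class SpatialGraph:
    """Neighbour relation over the cells of one ROI.

    Edges are stored positionally over ``cell_ids`` (row order of the input
    cells): ``edges[:, 0] -> edges[:, 1]``. The kNN variant is directed
    (source to its neighbours); the expansion variant stores both directions
    of every symmetric link. Both are irreflexive.
    """

    roi_id: str
    variant: str  # "knn" | "expansion"
    cell_ids: np.ndarray
    edges: np.ndarray  # (n_edges, 2) int positions
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbours(self, position: int) -> np.ndarray:
        """Positions of the out-neighbours of the cell at ``position``."""
        return self.edges[self.edges[:, 0] == position, 1]

    def edge_id_pairs(self) -> pd.DataFrame:
        """Edge list as cell-id pairs (source, target)."""
        if self.n_edges == 0:
            return pd.DataFrame(columns=["source", "target"])
        return pd.DataFrame(
            {
                "source": self.cell_ids[self.edges[:, 0]],
                "target": self.cell_ids[self.edges[:, 1]],
            }
        )


def _roi_frame(cells) -> pd.DataFrame:
    if isinstance(cells, CellTable):
        if cells.cells["roi_id"].nunique() > 1:
            raise ValueError("graphs are built per ROI; pass one ROI's cells")
        return cells.cells
    return cells


def build_knn_graph(
    cells, k: int = 40, max_dist: float = 75.0, roi_id: str | None = None
) -> SpatialGraph:
    """Directed k-nearest-neighbour graph within a maximum radius.

    Each cell points to its ``<= k`` nearest other cells no farther than
    ``max_dist`` µm. Distance ties at the k-th neighbour are broken by the
    smaller ``cell_id`` so the edge set is identical across platforms.
    Duplicate coordinates are legal; distance-0 neighbours rank first.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if not max_dist > 0:
        raise ParameterError(f"max_dist must be positive, got {max_dist}")
    df = _roi_frame(cells)
    roi = roi_id if roi_id is not None else (df["roi_id"].iloc[0] if len(df) else "")
    ids = df["cell_id"].to_numpy()
    xy = df[["x", "y"]].to_numpy(float)
    n = len(xy)
    params = {"variant": "knn", "k": k, "max_dist": max_dist}
    if n <= 1:
        return SpatialGraph(roi, "knn", ids, np.empty((0, 2), int), params)
    tree = cKDTree(xy)
    neighbour_lists = tree.query_ball_point(xy, r=max_dist)
    # order candidates by (distance, cell_id) and keep the first k
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    src, dst = [], []
    for i, cand in enumerate(neighbour_lists):
        cand = np.asarray([c for c in cand if c != i], dtype=int)
        if cand.size == 0:
            continue
        d = np.linalg.norm(xy[cand] - xy[i], axis=1)
        order = np.lexsort((id_rank[cand], d))
        keep = cand[order[:k]]
        src.extend([i] * len(keep))
        dst.extend(keep.tolist())
    edges = (
        np.column_stack([src, dst]) if src else np.empty((0, 2), int)
    )
    return SpatialGraph(roi, "knn", ids, edges, params)


def build_expansion_graph(
    cells,
    expansion: float = 15.0,
    radii=5.0,
    mode: str = "disc",
    roi_id: str | None = None,
) -> SpatialGraph:
    """Symmetric contact graph after dilating every cell.

    In ``disc`` mode cells are discs of the given radii (scalar default, or a
    per-cell vector, e.g. ``sqrt(area / pi)`` from segment areas); dilating
    both discs by ``expansion`` makes i and j neighbours when the boundary
    gap satisfies ``dist(i, j) - r_i - r_j <= 2 * expansion``. ``centroid``
    mode instead links cells whose centroid distance is at most
    ``expansion``, for compatibility with tools that define expansion as a
    centroid threshold.
    """
    if not expansion > 0:
        raise ParameterError(f"expansion must be positive, got {expansion}")
    if mode not in ("disc", "centroid"):
        raise ParameterError(f"unknown expansion mode {mode!r}")
    df = _roi_frame(cells)
    roi = roi_id if roi_id is not None else (df["roi_id"].iloc[0] if len(df) else "")
    ids = df["cell_id"].to_numpy()
    xy = df[["x", "y"]].to_numpy(float)
    n = len(xy)
    r = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    if (r < 0).any():
        raise ParameterError("cell radii must be nonnegative")
    params = {"variant": "expansion", "expansion": expansion, "mode": mode}
    if n <= 1:
        return SpatialGraph(roi, "expansion", ids, np.empty((0, 2), int), params)
    tree = cKDTree(xy)
    if mode == "centroid":
        pairs = np.asarray(sorted(tree.query_pairs(r=expansion)), dtype=int)
    else:
        reach = 2.0 * expansion + 2.0 * float(r.max())
        cand = np.asarray(sorted(tree.query_pairs(r=reach)), dtype=int)
        if cand.size:
            d = np.linalg.norm(xy[cand[:, 0]] - xy[cand[:, 1]], axis=1)
            gap = d - r[cand[:, 0]] - r[cand[:, 1]]
            pairs = cand[gap <= 2.0 * expansion]
        else:
            pairs = cand
    if pairs.size == 0:
        edges = np.empty((0, 2), int)
    else:
        pairs = pairs.reshape(-1, 2)
        edges = np.vstack([pairs, pairs[:, ::-1]])
    return SpatialGraph(roi, "expansion", ids, edges, params)


def neighbour_profile(
    graph: SpatialGraph,
    cells,
    immune_types,
    mode: str = "fraction",
) -> pd.DataFrame:
    """Local immune composition of every immune cell's kNN neighbourhood.

    For each immune cell, the fraction (or count) of each immune type among
    its out-neighbours that are themselves immune; the index cell's own type
    is not part of its profile. Isolated immune cells get a zero vector;
    fraction vectors otherwise sum to 1. Returns a DataFrame indexed by
    ``cell_id`` with one column per immune type, in vocabulary order.
    """
    if mode not in ("fraction", "count"):
        raise ParameterError(f"unknown profile mode {mode!r}")
    df = _roi_frame(cells)
    immune_types = list(immune_types)
    if isinstance(cells, CellTable):
        unknown = set(immune_types) - set(cells.type_vocabulary)
        if unknown:
            raise SchemaError(f"immune types outside vocabulary: {sorted(unknown)}")
    if not np.array_equal(df["cell_id"].to_numpy(), graph.cell_ids):
        raise ValueError("graph and cell table rows do not match")
    types = df["cell_type"].to_numpy()
    type_index = {t: i for i, t in enumerate(immune_types)}
    is_immune = np.isin(types, immune_types)
    n = len(df)
    counts = np.zeros((n, len(immune_types)), dtype=float)
    if graph.n_edges:
        src = graph.edges[:, 0]
        dst = graph.edges[:, 1]
        keep = is_immune[src] & is_immune[dst]
        src, dst = src[keep], dst[keep]
        cols = np.array([type_index[t] for t in types[dst]], dtype=int) if len(dst) else np.empty(0, int)
        np.add.at(counts, (src, cols), 1.0)
    counts = counts[is_immune]
    if mode == "fraction":
        totals = counts.sum(axis=1, keepdims=True)
        nonzero = totals[:, 0] > 0
        counts[nonzero] = counts[nonzero] / totals[nonzero]
    return pd.DataFrame(
        counts, index=pd.Index(df["cell_id"].to_numpy()[is_immune], name="cell_id"),
        columns=immune_types,
    )
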