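"""Immune-neighbourhood (IN) detection.

Immune cells are clustered by k-means on their local spatial composition
profiles (fractions of immune types among kNN neighbours), pooled across all
ROIs of a cohort so the IN vocabulary is shared between patients. With the
default three centres the clusters are given stable semantic names by
marker-set enrichment: a CD8/plasma-cell hub, a myeloid hub and a B/CD4 hub
— the three immune architectures that recur across tumours. Naming, not the
arbitrary k-means cluster index, is what identifies an IN across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import CellTable
from .params import ParameterError

__all__ = [
    "NeighbourhoodAssignment",
    "DEFAULT_ARCHITECTURES",
    "detect_neighbourhoods",
    "label_neighbourhood_semantics",
    "in_density",
]

#: Marker type-sets defining the three recurrent immune architectures.
DEFAULT_ARCHITECTURES = {
    "CD8-hub": ("CD8 T-cell", "Plasma cell"),
    "myeloid-hub": ("Macrophage", "CD204 macrophage", "Monocyte",
                    "Dendritic cell", "Kupffer cell", "Neutrophil"),
    "B/CD4-hub": ("B cell", "CD4 T-cell", "Tfh"),
}


@dataclass
class NeighbourhoodAssignment:
    """Result of immune-neighbourhood detection.

    ``labels`` maps each immune cell (index: cell_id) to ``IN1..INk``;
    ``centroids`` holds the k composition centroids; ``semantic_names``
    (filled by :func:`label_neighbourhood_semantics` when k = 3) maps IN
    labels to architecture names.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    inertia: float
    params: dict = field(default_factory=dict)
    semantic_names: dict = field(default_factory=dict)

    @property
    def n_centres(self) -> int:
        return len(self.centroids)

    def named_labels(self) -> pd.Series:
        """Per-cell architecture names if semantics are set, else raw labels."""
        if not self.semantic_names:
            return self.labels
        return self.labels.map(self.semantic_names)


def detect_neighbourhoods(
    profiles: pd.DataFrame,
    n_centres: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> NeighbourhoodAssignment:
    """k-means over pooled neighbour-composition profiles.

    Deterministic given ``seed``; the best of ``n_init`` k-means++ restarts
    by within-cluster sum of squares is kept. Raises if the profiles contain
    fewer distinct vectors than centres.
    """
    if n_centres < 1:
        raise ParameterError(f"n_centres must be >= 1, got {n_centres}")
    X = profiles.to_numpy(float)
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < n_centres:
        raise ParameterError(
            f"only {n_distinct} distinct profiles for {n_centres} centres"
        )
    km = KMeans(
        n_clusters=n_centres,
        n_init=n_init,
        random_state=seed,
        tol=1e-6,
        max_iter=300,
    ).fit(X)
    labels = pd.Series(
        [f"IN{i + 1}" for i in km.labels_], index=profiles.index, name="in_label"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_,
        index=[f"IN{i + 1}" for i in range(n_centres)],
        columns=profiles.columns,
    )
    return NeighbourhoodAssignment(
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        params={"n_centres": n_centres, "seed": seed, "n_init": n_init,
                "tol": 1e-6, "max_iter": 300},
    )


def label_neighbourhood_semantics(
    assignment: NeighbourhoodAssignment,
    table: CellTable,
    architectures: dict | None = None,
) -> dict:
    """Name each IN by its most enriched architecture marker set.

    Enrichment of architecture A in cluster c is the fraction of c's member
    cells whose type lies in A's marker set, divided by that fraction over
    all clustered immune cells. Names are assigned greedily on descending
    enrichment, enforcing a bijection between the three INs and the three
    architecture names. Skipped (empty mapping) when k != 3.
    """
    if assignment.n_centres != 3:
        return {}
    architectures = architectures or DEFAULT_ARCHITECTURES
    if len(architectures) != 3:
        raise ParameterError("semantic naming needs exactly three architectures")
    cells = table.cells.set_index("cell_id")
    member_types = cells.loc[assignment.labels.index, "cell_type"]
    overall = {
        name: max(float(member_types.isin(types).mean()), 1e-12)
        for name, types in architectures.items()
    }
    enrichment = []
    for in_label in assignment.centroids.index:
        in_types = member_types[assignment.labels == in_label]
        for name, types in architectures.items():
            frac = float(in_types.isin(types).mean()) if len(in_types) else 0.0
            enrichment.append((frac / overall[name], in_label, name))
    if len({e for e, _, _ in enrichment}) == 1:
        raise ParameterError(
            f"architecture enrichments all tied; cannot name INs: {enrichment}"
        )
    mapping: dict = {}
    used: set = set()
    for score, in_label, name in sorted(
        enrichment, key=lambda t: (-t[0], t[1], t[2])
    ):
        if in_label in mapping or name in used:
            continue
        mapping[in_label] = name
        used.add(name)
    assignment.semantic_names = mapping
    return mapping


def in_density(
    assignment: NeighbourhoodAssignment,
    table: CellTable,
    use_semantic_names: bool = False,
) -> pd.DataFrame:
    """Per-ROI density of each IN's cells over the full ROI area, cells/mm².

    IN densities per ROI sum exactly to that ROI's clustered-immune-cell
    density.
    """
    labels = assignment.named_labels() if use_semantic_names else assignment.labels
    groups = (
        assignment.centroids.index.map(assignment.semantic_names)
        if use_semantic_names
        else assignment.centroids.index
    )
    cells = table.cells.set_index("cell_id")
    roi_of = cells.loc[labels.index, "roi_id"]
    rows = []
    for roi_id in table.roi_ids:
        area = table.roi_area_mm2(roi_id)
        in_roi = labels[roi_of == roi_id]
        for group in groups:
            count = int((in_roi == group).sum())
            rows.append(
                {
                    "roi_id": roi_id,
                    "patient_id": table.roi_meta.loc[roi_id, "patient_id"],
                    "in_label": group,
                    "count": count,
                    "area_mm2": area,
                    "density": count / area,
                }
            )
    return pd.DataFrame(rows)
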