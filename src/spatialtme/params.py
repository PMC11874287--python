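"""Single home for every numeric analysis parameter.

All downstream stages read their constants from :class:`AnalysisParams` so a
run is fully described by one record: the neighbour-graph settings (40
nearest neighbours within 75 µm), the expansion-contact distance (15 µm per
cell), the number of immune-neighbourhood centres (3), the immunotype
cutoffs (200 cells/mm² CD8 density; parenchymal:stromal ratio 0.5 primary /
0.6 revised), the permutation-test tails (5% each) and the arcsinh cofactor
(0.5).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisParams", "ParameterError"]


class ParameterError(ValueError):
    """Raised when an analysis parameter is out of its valid range."""


@dataclass
class AnalysisParams:
    """Every numeric constant of the analysis, with the published defaults.

    Attributes
    ----------
    knn_k : int
        Neighbour cap of the kNN spatial graph (closest neighbours per cell).
    knn_max_dist : float
        Maximum neighbour radius of the kNN graph, µm.
    expansion_dist : float
        Per-cell dilation of the expansion-contact graph, µm. Two cells are
        contact neighbours when their boundaries come within twice this
        distance of each other.
    n_centres : int
        Number of k-means centres for immune-neighbourhood detection.
    density_cutoff : float
        CD8 T-cell density below which an ROI is immune-depleted, cells/mm².
    ratio_cutoff_primary, ratio_cutoff_revised : float
        Parenchymal:stromal CD8 density ratio separating compartmentalised
        from enriched, for the primary and revised classifier versions.
    tail_fraction : float
        Per-tail significance fraction of the permutation interaction test.
    n_permutations : int
        Default number of label permutations per ROI.
    arcsinh_cofactor : float
        Cofactor of the arcsinh channel transform.
    default_cell_radius : float
        Disc radius assumed for cells without a segmented area, µm.
    rng_seed : int
        Seed fanned out to every stochastic stage.
    """

    knn_k: int = 40
    knn_max_dist: float = 75.0
    expansion_dist: float = 15.0
    n_centres: int = 3
    density_cutoff: float = 200.0
    ratio_cutoff_primary: float = 0.5
    ratio_cutoff_revised: float = 0.6
    tail_fraction: float = 0.05
    n_permutations: int = 1000
    arcsinh_cofactor: float = 0.5
    default_cell_radius: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positives = [
            "knn_k", "knn_max_dist", "expansion_dist", "n_centres",
            "density_cutoff", "ratio_cutoff_primary", "ratio_cutoff_revised",
            "n_permutations", "arcsinh_cofactor", "default_cell_radius",
        ]
        for name in positives:
            value = getattr(self, name)
            if not value > 0:
                raise ParameterError(f"{name} must be positive, got {value!r}")
        if not 0.0 < self.tail_fraction < 0.5:
            raise ParameterError(
                f"tail_fraction must lie in (0, 0.5), got {self.tail_fraction!r}"
            )

    def ratio_cutoff(self, version: str) -> float:
        """Ratio cutoff for a classifier ``version`` ('primary' or 'revised')."""
        if version == "primary":
            return self.ratio_cutoff_primary
        if version == "revised":
            return self.ratio_cutoff_revised
        raise ParameterError(f"unknown classifier version {version!r}")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
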