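"""The three-class spatial immunotype classifier.

An ROI is classified from its CD8 T-cell densities: overall density below
the cutoff (200 cells/mm²) is **depleted**; otherwise the parenchymal to
stromal density ratio decides between **compartmentalised** (ratio below the
cutoff — CD8 cells retained in the intratumoural stroma) and **enriched**
(ratio at or above it — CD8 cells infiltrating the tumour parenchyma). The
primary classifier uses a ratio cutoff of 0.5; the revised version, 0.6.

Patients with several ROIs are aggregated either by **consensus** (modal ROI
label; ties re-classified from the mean densities of the tied ROIs) or by
the **highest** immunotype present in any ROI under the hierarchy
enriched > compartmentalised > depleted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compartments import parenchyma_stroma_ratio
from .params import AnalysisParams, ParameterError

__all__ = [
    "LABELS",
    "LABEL_RANK",
    "ImmunotypeCall",
    "classify_roi",
    "classify_patient",
    "heterogeneity_flag",
]

LABELS = ("depleted", "compartmentalised", "enriched")
#: Hierarchy used by the "highest" patient aggregation.
LABEL_RANK = {"depleted": 0, "compartmentalised": 1, "enriched": 2}


@dataclass
class ImmunotypeCall:
    """One immunotype call with its full density provenance."""

    level: str  # "roi" | "patient"
    id: str
    overall_cd8: float
    parenchymal_cd8: float
    stromal_cd8: float
    ratio: float
    label: str
    classifier_version: str
    aggregation: str = "none"
    warnings: list = field(default_factory=list)

    def as_record(self) -> dict:
        return {
            "level": self.level,
            "id": self.id,
            "overall_cd8": self.overall_cd8,
            "parenchymal_cd8": self.parenchymal_cd8,
            "stromal_cd8": self.stromal_cd8,
            "ratio": self.ratio,
            "label": self.label,
            "classifier_version": self.classifier_version,
            "aggregation": self.aggregation,
            "warnings": ";".join(self.warnings),
        }


def classify_roi(
    overall: float,
    dp: float,
    ds: float,
    version: str = "primary",
    params: AnalysisParams | None = None,
    roi_id: str = "",
) -> ImmunotypeCall:
    """Classify one ROI from overall, parenchymal and stromal CD8 densities.

    Total on nonnegative inputs: overall strictly below the density cutoff
    is depleted regardless of the ratio; at or above it, ratio < cutoff is
    compartmentalised and ratio >= cutoff (including +inf when the stroma is
    empty) is enriched. A ratio exactly at the cutoff therefore counts as
    enriched — the half-open convention used throughout. Both compartment
    densities zero while the overall density sits at or above the cutoff is
    geometrically impossible for a real ROI; the call is still total
    (labelled enriched) but carries an inconsistency warning.
    """
    params = params or AnalysisParams()
    if min(overall, dp, ds) < 0:
        raise ParameterError("densities must be nonnegative")
    cutoff = params.ratio_cutoff(version)
    warnings: list = []
    ratio = parenchyma_stroma_ratio(dp, ds)
    if overall < params.density_cutoff:
        label = "depleted"
    else:
        if math.isnan(ratio):
            warnings.append(
                "overall density above cutoff but both compartment densities zero"
            )
            label = "enriched"
        elif ratio < cutoff:
            label = "compartmentalised"
        else:
            label = "enriched"
    return ImmunotypeCall(
        level="roi",
        id=roi_id,
        overall_cd8=overall,
        parenchymal_cd8=dp,
        stromal_cd8=ds,
        ratio=ratio,
        label=label,
        classifier_version=version,
        warnings=warnings,
    )


def classify_patient(
    calls: Sequence[ImmunotypeCall],
    mode: str = "consensus",
    params: AnalysisParams | None = None,
    patient_id: str = "",
) -> ImmunotypeCall:
    """Aggregate a patient's ROI calls.

    ``consensus``: the most frequent ROI label; when distinct labels tie for
    the top count (including a three-way 1-1-1 tie), the tied ROIs' mean
    densities are re-classified and that label is assigned. ``highest``: the
    maximal label present in any ROI under
    enriched > compartmentalised > depleted.
    """
    if not calls:
        raise ParameterError("need at least one ROI call")
    versions = {c.classifier_version for c in calls}
    if len(versions) > 1:
        raise ParameterError(f"mixed classifier versions: {sorted(versions)}")
    version = calls[0].classifier_version
    params = params or AnalysisParams()

    mean_overall = float(np.mean([c.overall_cd8 for c in calls]))
    mean_dp = float(np.mean([c.parenchymal_cd8 for c in calls]))
    mean_ds = float(np.mean([c.stromal_cd8 for c in calls]))

    if mode == "highest":
        label = max((c.label for c in calls), key=LABEL_RANK.__getitem__)
    elif mode == "consensus":
        counts = Counter(c.label for c in calls)
        top = max(counts.values())
        tied = [lab for lab, n in counts.items() if n == top]
        if len(tied) == 1:
            label = tied[0]
        else:
            tied_calls = [c for c in calls if c.label in tied]
            tie_break = classify_roi(
                float(np.mean([c.overall_cd8 for c in tied_calls])),
                float(np.mean([c.parenchymal_cd8 for c in tied_calls])),
                float(np.mean([c.stromal_cd8 for c in tied_calls])),
                version=version,
                params=params,
            )
            label = tie_break.label
    else:
        raise ParameterError(f"unknown aggregation mode {mode!r}")

    return ImmunotypeCall(
        level="patient",
        id=patient_id,
        overall_cd8=mean_overall,
        parenchymal_cd8=mean_dp,
        stromal_cd8=mean_ds,
        ratio=parenchyma_stroma_ratio(mean_dp, mean_ds),
        label=label,
        classifier_version=version,
        aggregation=mode,
    )


def heterogeneity_flag(calls: Sequence[ImmunotypeCall]) -> dict:
    """Intratumour immunotype heterogeneity: >= 2 distinct ROI labels.

    A single-ROI patient cannot be assessed and is returned with
    ``assessable=False`` and ``heterogeneous=False``.
    """
    labels = [c.label for c in calls]
    if len(labels) < 2:
        return {
            "heterogeneous": False,
            "assessable": False,
            "labels": Counter(labels),
        }
    return {
        "heterogeneous": len(set(labels)) >= 2,
        "assessable": True,
        "labels": Counter(labels),
    }
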