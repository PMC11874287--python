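# spatialtme

Spatial single-cell immune-architecture analysis of tumour
microenvironments, built for highly multiplexed tissue imaging (imaging
mass cytometry and comparable platforms) of hepatocellular carcinoma and
similar solid tumours.

Given phenotyped, segmented single-cell tables (one row per cell with µm
centroid coordinates), compartment label masks at 1 µm²/pixel and
per-patient survival data, the package answers the questions a spatial
immuno-oncology analysis asks:

* **Where is each cell?** Centroid lookup against parenchyma/stroma (or
  tumour/capsule/adjacent-liver) masks, compartment areas by pixel
  counting, and compartment-resolved densities in cells/mm².
* **Who is next to whom?** Two neighbour graphs — each cell's k = 40
  nearest neighbours within 75 µm, and an expansion-contact graph linking
  cells whose boundaries come within 2 × 15 µm after dilation.
* **What immune structures recur?** k-means over each immune cell's local
  neighbour composition finds the three immune neighbourhoods (INs) that
  recur across tumours: a CD8/plasma-cell hub, a myeloid hub and a B/CD4
  hub.
* **Which cell subsets interact or avoid each other?** A per-ROI
  permutation test on the contact graph: the directional "histocat" score
  (B-neighbour count over A cells ÷ number of A cells with ≥ 1 B
  neighbour) against a label-permutation null, with 5% significance tails.
* **What is the tumour's spatial immunotype?** The three-class classifier:
  overall CD8 T-cell density < 200 cells/mm² → *depleted*; otherwise the
  parenchymal:stromal CD8 density ratio < 0.5 (primary version; 0.6
  revised) → *compartmentalised*, else *enriched*. Patients with several
  ROIs aggregate by consensus (modal label, density-mean tie-break) or by
  the highest immunotype present (enriched > compartmentalised > depleted).
* **Does it matter for outcome?** Kaplan-Meier curves and medians,
  log-rank and log-rank-for-trend tests, marker dichotomisation and
  fixed-horizon ROC analysis of progression-free survival.

A synthetic-tissue simulator (compartment masks from smoothed noise,
compartment-wise Poisson cell placement over a 23-type vocabulary,
Thomas-type co-clustering to plant interactions, exponential survival)
generates complete cohorts with ground truth, so the entire pipeline is
testable without patient data.

## Worked example

Simulate a 12-patient cohort (four patients per immunotype archetype, two
1 mm² ROIs each), classify every patient and test the survival trend:

```python
import pandas as pd
from spatialtme import (generate_cohort, assign_compartments, compartment_areas,
                        cell_density, classify_roi, classify_patient,
                        km_curve, logrank_trend)

bundle = generate_cohort(
    {"depleted": 4, "compartmentalised": 4, "enriched": 4},
    rois_per_patient=2, seed=42,
)
table = assign_compartments(bundle.table, bundle.masks)
areas = {r: compartment_areas(bundle.masks[r]) for r in table.roi_ids}
d_all = cell_density(table, "CD8 T-cell", "all").set_index("roi_id")
d_par = cell_density(table, "CD8 T-cell", "parenchyma", areas=areas).set_index("roi_id")
d_str = cell_density(table, "CD8 T-cell", "stroma", areas=areas).set_index("roi_id")

rows = []
for pid, meta in table.roi_meta.groupby("patient_id"):
    calls = [classify_roi(d_all.loc[r, "density"], d_par.loc[r, "density"],
                          d_str.loc[r, "density"], version="primary", roi_id=r)
             for r in meta["roi_id"]]
    patient = classify_patient(calls, mode="consensus", patient_id=pid)
    rows.append({"patient": pid, "overall": round(patient.overall_cd8, 1),
                 "ratio": round(patient.ratio, 2), "immunotype": patient.label})
print(pd.DataFrame(rows).head(6).to_string(index=False))

surv = bundle.survival.rename(columns={"group": "immunotype"})
surv["group"] = surv["immunotype"]
for label, sub in surv.groupby("group"):
    print(label, "median PFS", round(km_curve(sub).median, 1), "months")
stat, p = logrank_trend(surv, ["depleted", "compartmentalised", "enriched"])
print(f"log-rank trend chi2 = {stat:.2f}, p = {p:.3f}")
```

prints

```
patient  overall  ratio        immunotype
   P000    283.0   0.12 compartmentalised
   P001    296.5   0.13 compartmentalised
   P002    271.0   0.11 compartmentalised
   P003    278.0   0.17 compartmentalised
   P004     47.5   1.17          depleted
   P005     45.5   0.72          depleted
compartmentalised median PFS 2.1 months
depleted median PFS 1.8 months
enriched median PFS 11.5 months
log-rank trend chi2 = 2.41, p = 0.120
```

The compartmentalised patients sit above the 200 cells/mm² density cutoff
but keep their CD8 T-cells in the stroma (ratio ≈ 0.1), the depleted
patients fall below the cutoff regardless of ratio, and every patient
recovers the immunotype their tissue was generated from. At 12 patients
the survival trend points the right way but is not significant — the
generating median-PFS ordering (4.1 / 6.6 / 8.3 months) needs a larger
cohort to reach significance.

The same stages are available from the shell:

```sh
spatialtme simulate --n-patients 12 --seed 42 --out cohort/
spatialtme classify --cohort cohort/ --version primary --out calls.csv
spatialtme run --config config.yaml     # full pipeline with a run report
```

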