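# Methods

This note records the models, conventions and numerical choices behind
`spatialtme`, in the order the pipeline runs them.

## Data model and coordinate conventions

Cells are points (segmentation centroids) in µm with a categorical type
from a declared vocabulary; masks are integer label rasters at
1 µm²/pixel (the native resolution of imaging mass cytometry). The origin
is the raster top-left, x runs along columns, y down rows; pixel (i, j)
covers the half-open square [j, j+1) × [i, i+1) µm, so centroid→pixel
lookup is a floor, total and deterministic. A centroid exactly on the
right or bottom raster edge belongs to the last pixel. Cells whose
centroid lies on a background pixel stay `unassigned`; centroids outside
the raster are flagged, never dropped. A cell straddling a compartment
boundary is resolved purely by its centroid — segment shapes are not
carried through the table.

Cell tables are delimited text with a declared column mapping rather than
a binary container, so fixtures are diffable and round-trips are
bit-exact; masks are single-channel 16-bit TIFF.

## Channel transforms

Raw channel intensities are arcsinh-transformed with cofactor 0.5
(`asinh(v / 0.5)`), the standard variance-stabilising transform for mass
cytometry. Percentile normalisation clips a channel to a percentile
window, rescales affinely to [0, 1] and zeroes rescaled values below a
noise floor. Optimal percentiles and floors are channel-specific and
chosen by inspection in practice, so they are per-channel configuration
with permissive defaults (p_low = 0, p_high = 99, floor = 0); a
degenerate percentile window returns all zeros rather than raising.

## Densities and the CD8 distribution ratio

Compartment areas are pixel counts × pixel area (mm²); densities are
count ÷ area. Density records keep count and area so the ratio
`density == count / area_mm2` is exact and recheckable. Per-patient
values are unweighted means over the patient's ROIs. The intratumoural
CD8 distribution is the ratio of parenchymal to stromal CD8 density; an
empty stroma with parenchymal infiltrate gives +inf (treated as maximal
infiltration), both compartments empty gives NaN. ROIs with under 5%
stroma or parenchyma can be flagged for sensitivity analyses; flagging
never removes data.

## Spatial graphs

*kNN graph* (neighbourhood detection): each cell points to its ≤ 40
nearest other cells within 75 µm (Euclidean centroid distance). Distance
ties at the k-th neighbour are broken by the smaller cell id so the edge
set is platform-independent. *Expansion-contact graph* (interaction
testing): cells are modelled as discs — radius √(area/π) when segment
areas exist, otherwise a 5 µm default, a typical lymphocyte radius — and
both discs are dilated by 15 µm; cells touch when the boundary gap is at
most 2 × 15 µm. A `centroid` mode (centroid distance ≤ expansion) is
provided for compatibility with tools that define expansion that way;
disc mode is the default because "touching after expansion" is a
statement about boundaries.

## Immune neighbourhoods

Each immune cell's feature vector is the fraction of each immune type
among its kNN out-neighbours, restricted to immune cells; the index
cell's own type is excluded, and fractions (not counts) keep sparse and
dense regions comparable (a counts mode exists). Profiles are pooled
across all ROIs of a cohort so the IN vocabulary is shared between
patients, and clustered by k-means with three centres (k-means++
seeding, 10 restarts, tolerance 1e-6, 300 iterations max; none of these
are scientifically load-bearing and all are recorded in the output
metadata). Because k-means indices are arbitrary, IN identity across
reruns comes from semantic naming: each cluster is named for the
architecture (CD8/plasma hub, myeloid hub, B/CD4 hub) whose marker
type-set is most enriched among its member cells (cluster fraction ÷
pooled fraction), assigned greedily on descending enrichment with a
bijection enforced. IN densities use the full ROI area, so densities over
the three INs sum exactly to the clustered-immune-cell density.

## Interaction testing

The directional score of subset A towards subset B on the contact graph
is, per ROI: total number of B neighbours over all A cells ÷ number of A
cells with at least one B neighbour ("histocat" method; the "classic"
variant divides by all A cells). The null hypothesis — cell positions
carry no information about subset labels — is realised by permuting the
label vector over the fixed graph, which has the same null distribution
as re-randomising cell positions but reuses the geometry. One permutation
per iteration is shared across all tested pairs, exactly as a relocation
would be. The observed score's percentile uses mid-ranking of ties,
(#null < obs + 0.5 · #null = obs + 0.5) / (n + 1), which avoids
degenerate 0/1 percentiles and keeps the two tails symmetric;
permutations with an undefined score (zero denominator) are excluded from
the null count. Calls: percentile ≥ 0.95 → interaction, ≤ 0.05 →
avoidance (5% per tail), undefined observed score → undefined. Calls are
per ROI, with 1000 permutations by default; no multiplicity correction is
applied to calls — correction belongs to downstream group comparisons,
for which a Bonferroni helper is provided but never auto-applied.
Label shuffles are unconstrained by default; a compartment-stratified
shuffle is available when the null should respect compartment
composition. Within-IN interaction analyses subset the cells to one IN
and rerun the same machinery.

## The spatial immunotype classifier

Overall CD8 density below 200 cells/mm² → *depleted*, regardless of
distribution. At or above it, the parenchymal:stromal ratio decides:
below the cutoff → *compartmentalised*, at or above it → *enriched*. The
ratio cutoff is 0.5 (primary version) or 0.6 (revised). Boundary
conventions are half-open throughout — "below 200" means strictly less,
and a ratio exactly at the cutoff is enriched — and are recorded in the
call records. Overall density is computed over the whole ROI area, not
as a mean of compartment densities. The geometrically impossible corner
(overall above the cutoff but both compartment densities zero) stays
total: it is labelled enriched and flagged with an inconsistency warning.

Patient aggregation: *consensus* takes the modal ROI label; tied labels
(including a three-way 1-1-1 tie, an extension of the published two-way
rule) are resolved by re-classifying the mean densities of the tied
ROIs. *highest* takes the maximal label present in any ROI under
enriched > compartmentalised > depleted. Note the consensus tie-break
classifies mean densities, which can produce a label absent from the
tied ROIs — so "highest ≥ consensus" holds whenever the mode is unique
but not universally. Heterogeneity is ≥ 2 distinct ROI labels;
single-ROI patients are reported as not assessable.

## Outcome association

Kaplan-Meier estimation and the plain log-rank test are delegated to
lifelines; the median is the earliest time the survival curve reaches
0.5 or below (undefined if never). The log-rank test for trend across
ordered groups is computed from the pooled risk table: with scores s
(default 1, 2, 3), statistic = (Σ s_g (O_g − E_g))² / (s' V s) with V the
hypergeometric covariance of O − E, referred to χ²(1). Simulation checks
show nominal calibration (5.5% rejections at the 5% level under equal
hazards) and that with ordered exponential hazards it is more significant
than the omnibus test in roughly 72% of replicates.

Fixed-horizon ROC analysis defines the outcome as progression-free
survival ≥ the horizon (8 months by default); patients censored before
the horizon carry no outcome information and are excluded, with their
number reported — imputation was deliberately avoided. AUC is the
tie-corrected rank-sum probability. Marker dichotomisation: median rule
puts values strictly above the median in "high"; the fixed-threshold
rule puts values strictly above in "high" and flags values exactly at
the threshold (assigned low).

## Synthetic tissue

The simulator generates the statistical structure the analysis assumes,
not images. Masks: seeded white noise smoothed with a Gaussian kernel
(blob scale 120 µm by default, the scale of stromal septa) and
thresholded at the quantile matching the target stroma fraction — the
fraction is exact up to ties. Cells: each (type, compartment) intensity
drives an independent homogeneous Poisson process over that compartment's
pixels, so realised densities are unbiased estimates of the intensities;
23 default cell types mirror an HCC microenvironment vocabulary, with
structural cells dominating their home compartment and a sparse uniform
immune background. Planted interactions are Thomas-type parent–offspring
processes: each parent cell of type A seeds a Poisson number of type-B
offspring displaced by an isotropic Gaussian.

The three scenario archetypes fix CD8 intensities far from the
classifier cutoffs so recovery tests measure pipeline correctness rather
than boundary luck: depleted 50/50 (parenchyma/stroma, cells/mm²),
compartmentalised 80/600, enriched 500/500; a `boundary` scenario
(110/200) deliberately exercises the cutoff conventions. Survival is
exponential (hazard ln 2 / median) with medians 4.1, 6.6 and 8.3 months
for depleted, compartmentalised and enriched — the simplest model that
realises the intended ordering — and independent censoring (20% by
default) at a uniformly earlier time. Cohorts draw a configurable number
of ROIs per patient, optionally swapping one ROI to a different scenario
with a set probability to mimic intratumour immunotype heterogeneity;
ground truth is retained for recovery tests. The planted-architecture
fixture places three immune mixes in 400 µm spatial bands at aggregate
density (1500 immune cells/mm², 75% dominant types), the geometry and
density of a well-formed immune hub.

What the simulator does *not* emulate: marker intensity distributions and
spillover, segmentation errors, cell-shape variation (cells are points /
equivalent discs), anisotropic tissue gradients, and correlations between
immune architecture and stroma morphology. Passing recovery tests
therefore demonstrates that the pipeline's computations are correct under
the assumed point-process model, not that the biology of real tissue is
captured.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed; the pipeline fans one
global seed into per-stage child seeds via `SeedSequence`, and reruns
with identical config and seed are byte-identical (checksummed in the
run report). The test suite uses cohorts of up to 60 patients × 2 ROIs of
1 mm² (~140k cells) for end-to-end recovery, 50 random instances for the
kNN-versus-brute-force oracle, exhaustive label enumeration for the
permutation-test oracle on small ROIs, and 400 CSR ROIs × 500
permutations for the interaction test's false-positive rate; these sizes
give every stochastic check a comfortably powered envelope while keeping
the whole suite around a minute on one CPU.

## Known limitations

* The consensus tie-break can label a patient with an immunotype absent
  from their ROIs (see above); this follows the published rule rather
  than papering over it.
* Strict three-way recovery of the generating median-PFS ordering by KM
  medians is noise-limited at small cohorts: with medians 4.1/6.6/8.3
  months the 1.7-month compartmentalised/enriched gap is comparable to
  the sampling error of a median at 40 patients/group, so ordering
  recovery plateaus near 65% there and ~86% at 100/group.
* The permutation null conditions on the observed geometry (fixed
  graph); it does not model uncertainty in segmentation or phenotyping.
* No Cox regression, competing risks or covariate adjustment — the
  outcome stage mirrors the univariate survival comparisons of the
  analysis it implements.
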