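# Methods

`spatialtme` reimplements, as a tested pipeline, a spatial single-cell
analysis of multiplexed (imaging-mass-cytometry-style) tumor tissue from a
two-arm mouse experiment: non-treated tumors (**NT**) versus locally
irradiated tumors (**IT**). Because no public per-cell data accompany this
kind of study, the package ships a synthetic cohort generator that plants
the effects the analysis is meant to detect; every stage can therefore be
validated against known ground truth. This note records the models, the
defaults and their rationale, the numerical conventions, and what passing
tests do and do not establish.

## Synthetic cohort generator

### Spatial model

Each sample is a rectangular region of interest (ROI) in µm with cells as
points carrying a stored area. Defaults: 600 × 600 µm, chosen as a
desk-scale ROI that yields ≈ 1 000–1 200 cells per sample — enough for
stable neighborhood statistics while keeping a six-sample cohort fast to
analyze.

* Tumor, non-neutrophil myeloid cells and CD4/CD8 T cells follow
  independent homogeneous Poisson point processes with intensities
  (cells/µm²): tumor 2·10⁻³, myeloid 4·10⁻⁴, CD4 T and CD8 T 1.2·10⁻⁴
  each. These give the tumor-dominated composition with a minority immune
  infiltrate typical of syngeneic breast-tumor sections.
* Neutrophils follow a Thomas-type cluster process on top of a sparse
  uniform background (5·10⁻⁵/µm²): a **fixed** number of parent centers is
  placed uniformly in the ROI and each receives a Poisson number of
  offspring displaced by an isotropic Gaussian (sd = cluster radius,
  default 20 µm, offspring clipped to the ROI). The parent count is fixed —
  rather than Poisson as in the classical Thomas process — because it is
  the treatment dose being planted: NT samples get 5 clusters of ≈ 40
  cells, IT samples 1. A Poisson parent count would add between-sample
  variance that is not part of the planted contrast.
* Cell areas are lognormal (median 65 µm², log-sd 0.25, clipped to
  [10, 300] µm²), matching typical segmented-cell footprints at 1 µm/px.

### Marker model

Intensities follow a per-type × per-marker lognormal: log-intensity
~ N(µ, σ) with σ = 0.4 throughout. The panel is a 19-antigen list typical
of mouse tumor immunophenotyping. Only the lineage markers (CD11b, Ly6G,
CD3, CD4, CD8a), E-Cadherin, the DNA channel and the EMT-associated
markers (TGFb1, SMAD4, Slug) carry structure; positive populations sit at
µ = log 20, negative at µ = 0, the noise floor at µ = log 1.6. The 7.5-σ
separation between positive and negative populations makes gating nearly
error-free by construction; see "What the synthetic data do not emulate".

Treatment effects are multiplicative intensity shifts per group. NT
defaults: E-Cadherin × 0.5 (loss of intercellular cohesion in untreated,
neutrophil-rich tumors), DNA × 1.3 (extracellular DNA from NET release),
SMAD4 and Slug × 1.25, TGFb1 × 1.0 (no shift). IT is the reference.

### Outcomes

Survival is exponential with group hazards 1/21 d⁻¹ (NT) and 1/45 d⁻¹
(IT). Serum NE-DNA (ELISA absorbance units) is a group mean (NT 1.2,
IT 0.5) plus a linear term in the centered survival time plus N(0, 0.1)
noise. The correlation's sign is configurable and defaults to **positive**
(higher NE-DNA with longer survival); the source literature is ambiguous
on the direction, and the default follows its most literal reading. Flip
`SurvivalModel.correlation_sign` for the opposite reading.

### Rendering

Cells are rendered to images only on request: each cell becomes the
`round(area)` pixels nearest its centroid (1 px = 1 µm²), labeled with its
cell id; contested pixels go to the lower id. Channel images are constant
fills of the cell's recorded intensity, so per-cell mean signal intensity
recovers the generating table exactly for unclipped, non-overlapping
cells — a deliberate property used as an oracle. Label-0 (intercellular)
pixels carry a background level per marker, modeled as 30 % of the
sample's mean cellular intensity: membrane-proximal signal bleeding
outside the masks, which lets group-level marker shifts show up in the
"cell 0" region too.

### What the synthetic data do not emulate

No segmentation errors, spillover, spatial intensity gradients, cell-shape
variation, or overlap between marker populations. In particular the
near-perfect label recovery (≈ 100 %) reflects the planted 7.5-σ marker
separation, not expected performance on real tissue, where gates overlap
and the classifier's probability threshold does real work. Passing tests
demonstrate correctness of the computations and recoverability of planted
effects at the stated effect sizes — not robustness to real-data noise.

## Cell typing

1. **Gating.** Ordered threshold rules assign confident labels:
   neutrophil (CD11b⁺ Ly6G⁺) before myeloid (CD11b⁺ Ly6G⁻) so
   double-positives are not claimed by the myeloid gate; CD8 T
   (CD3⁺ CD8a⁺) before CD4 T (CD3⁺ CD4⁺). Default thresholds are the
   geometric midpoints between positive and negative log-means of the
   default marker model; with real data they are config-supplied.
2. **Classification.** A regularized multinomial logistic model (C = 1,
   L-BFGS) on log1p intensities standardized by training-set statistics
   assigns each ungated cell the class of highest probability — unless
   that probability falls below `probability_threshold` (default 0.5, the
   majority rule), in which case the cell is labeled **tumor**.
3. **Tumor-candidate seeding.** A purely discriminative classifier trained
   only on the four immune classes cannot flag out-of-distribution cells:
   far from every class, its softmax still commits confidently to one of
   them (measured: > 90 % of tumor cells received max probability > 0.9 at
   any regularization strength). The training set is therefore seeded with
   high-confidence epithelial candidates — ungated cells whose E-Cadherin
   exceeds the positive/negative midpoint — labeled tumor. The probability
   fallback remains as the safety net for genuinely ambiguous cells.
   Disable with `tumor_seed_marker=None` to recover the pure
   four-class-plus-fallback behaviour.

Gated labels are never overwritten. Ties in the argmax are broken by the
fixed alphabetical class order.

## Spatial graphs

Two constructions over cell centroids (coordinates in µm, 1 px = 1 µm):

* **Expansion graph** (default for neighborhoods): undirected edge
  whenever centroid distance ≤ 15 µm. The boundary is inclusive, matching
  common expansion-graph semantics. Built with a k-d tree; unit tests pin
  exact equivalence to the O(n²) pairwise construction.
* **k-nearest-neighbor graph** (k = 10): each cell selects its k nearest
  others (k clipped to n−1), exact distance ties broken toward the lower
  cell id (nodes are processed in id order with a stable sort, making the
  tie-break reproducible), and selections symmetrized by union so that
  interaction counting is well defined on an undirected graph.

Both radius-15 expansion and 10-NN graphs are standard in this field; the
pipeline exposes the choice as a config switch and defaults to
expansion/15 for neighborhood construction.

## Cellular neighborhoods

Each cell's neighborhood profile is the fraction of the five final types
among its graph neighbors (self excluded); isolated cells keep an all-zero
profile flagged with neighbor count 0 and participate in clustering, where
they join a low-composition cluster. Profiles are pooled across all
samples of the cohort — clustering once keeps CN labels comparable between
groups — after canonical ordering by (sample id, cell id), which makes the
result invariant to input row order. Pooled profiles are clustered with
k-means (k = 8 by default; k-means++ initialization, 10 restarts, best
inertia kept, tolerance 1e-6, max 300 iterations, fixed seed).

CN indices are arbitrary k-means artifacts. All reports therefore attach
the CN-by-type composition matrix z-scored **per type across CNs** (a type
uniform across CNs gets z = 0 by convention; sample sd, ddof = 1), so
"the neutrophil-rich CN" is identified by composition, not index. Per-
sample CN frequencies are counts divided by the sample's total cell count.

## Interactions

Every undirected edge contributes one count to exactly one unordered
type pair, so pair counts sum to the edge count — an identity asserted in
tests. Because the field lacks a single normalization convention, tables
carry both the raw count and count divided by the number of cells of the
pair's alphabetically first type. Group comparisons use the unpaired
t-test on per-sample counts; permutation-null enrichment testing is
deliberately out of scope.

## Mean signal intensity

MSI(label) is the mean channel value over the pixels of one mask label,
with label 0 — the intercellular space outside all cell masks — treated as
one pseudo-cell so membrane-proximal signal missed by segmentation can be
quantified (this region conflates membrane and true background; callers
should read it as such). For group tests, a sample's cell-region value is
the **unweighted mean over its per-cell MSIs** (each cell counts equally,
large cells are not up-weighted) and its intercellular value is the
label-0 MSI; the t-test then runs on per-sample values (n = samples, not
cells), the defensible unit when samples are the independent replicates.

## Statistics

All statistics are computed from their closed-form definitions
(scipy.stats supplies only distribution tail probabilities); the suite
cross-checks them against scipy, statsmodels and lifelines and verifies
type-I error within [0.03, 0.07] at α = 0.05 over 2 000 null replicates
per test.

* Unpaired t-test: Welch by default (the safer choice under unequal
  variances; Student's pooled form available for exact parity with
  common GraphPad usage). Zero variance in both groups is flagged
  degenerate rather than returning NaN.
* Two-way ANOVA: fixed effects, Type II sums of squares (each main effect
  adjusted for the other; coincides with the classical decomposition on
  balanced layouts, which unit tests assert). The interaction drops out
  automatically without replication.
* Pearson correlation: product-moment r, p from t = r√((n−2)/(1−r²)).
* Kaplan–Meier: product-limit estimator, events before censorings at tied
  times; two-group log-rank with the hypergeometric variance.
* Tissue NLR: neutrophils / (CD4 T + CD8 T), computed in exact rational
  arithmetic; zero lymphocytes yields NaN with a warning, never a silent
  infinity.
* No multiple-testing correction by default, matching per-panel star
  reporting conventions; apply one downstream if needed.

## Pipeline and reproducibility

A single seed fans out into per-stage seeds (`SeedSequence([seed,
crc32(stage)])`), so any stage can be re-run standalone with the same
randomness. CSVs are the interchange format between stages; floats are
written at full precision and re-read with round-trip parsing, making
file-mode runs bit-identical to in-memory runs. A manifest records the
config hash, seeds and package version. Identical config + seed reproduce
all CSV outputs bit-exactly — asserted end to end in the test suite.

## Problem sizes

Defaults used by the test suite and the acceptance script: 600 × 600 µm
ROIs (≈ 1 000–1 200 cells/sample), cohorts of 3 NT + 3 IT samples,
planted-effect recovery over 100 replicate cohorts, statistical
calibration over 2 000 null replicates per test, and a 15 + 15 sample
cohort for survival statistics. These sizes give stable Monte-Carlo
estimates at desk scale.

## Known limitations

* The generator's marker separation makes cell typing nearly perfect;
  recovery rates are upper bounds, not real-data expectations.
* The intercellular background model (constant fraction of mean cellular
  intensity) is the simplest mechanism that propagates group shifts to
  the cell-0 region; real membrane signal is spatially structured.
* k-NN graphs tie-break by cell id; on pixel-quantized real coordinates,
  exact ties are possible and the result, while deterministic, depends on
  id assignment.
* No Cox regression, mixed models, permutation interaction nulls, or
  alternative CN methods (graph communities, spatial LDA).
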