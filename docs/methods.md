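# Methods

## Input model

The pipeline starts from a segmented per-cell table — one row per cell with a
core label, centroid (0-based pixel centers, y down, 0.293 µm/px by default),
morphology (perimeter, cell area, nuclear area in pixels), a QC flag set
upstream, and compartment-resolved raw signal per marker (ER/PR/Ki67/P53/P21/
P16 nuclear, HER2/PCK membranous, P53 also cytosolic; the compartment
extraction happens upstream and is out of scope). Column headers are bound to
this vocabulary by a config-driven schema map, so deposited tables with
arbitrary headers can be ingested unchanged. Per-core IHC scores (ER/PR
percent + intensity, HER2 0/1+/2+/3+ with FISH resolution of 2+, Ki67 percent,
P53 normal/null/OE, P16 normal/OE) and optional GeoJSON polygon annotations
(`exclude_benign`, `include_tumor`, in pixel coordinates) complete the inputs.

## Normalization

Each marker is min-max rescaled to 0–15 independently. The fit population is
every QC-passing segmented cell of the dataset, not just the cancer
population, because the CD8/CD20 cut-points apply to all cells; the fitted
per-marker min/max is recorded in a JSON sidecar so the exact transform is
reproducible and re-normalization is refused outright (guard in the API). A
marker whose observed max equals its min carries no information; its
normalized values are set to 0 with a warning. No percentile clipping is
applied by default — the transform is the plain min-max, and order
preservation is property-tested.

## Gating

Gate order is QC → size → region/PCK, and each rejected cell records the
first rule it failed. Size gates are strict inequalities (perimeter > 90 px,
cell area > 400 px, nuclear area > 10 px); the PCK cancer gate is inclusive
(raw ≥ 1500) — the comparators follow the conventions of the quantification
they calibrate against. Luminal and HER2+ cores select cancer cells by PCK
and drop cells inside benign-duct polygons; TNBC cores (PCK too weak to
threshold) select cells inside manually annotated tumor polygons, and a TNBC
core with no such polygon is a configuration error, not an empty result.
Cells are assigned to regions by centroid only; boundary points count as
inside (deterministic, and conservative for inclusion regions).

## Positivity, EPH classes, subtypes

A cell is positive when its normalized signal is strictly greater than the
marker's cut-point (ER 0.4 separating weak/negative from moderate/strong, PR
1.6, HER2 5.0, Ki67 0.2, P53 0, P16 2, P21 1, CD8/CD20 0.2). Strict
comparison generalizes the one explicitly defined comparator (P53 "> 0") to
all markers; whether a cell exactly at a cut-point is positive is otherwise
unobservable at data scale. The EPH group is the fixed bijection
1 + 4·[ERm/s] + 2·[PR+] + [HER2+], and the 16-class index is group-major,
Ki67-minor: class = 2·(group−1) + 1 + [Ki67+]. This ordering is load-bearing
— the paired-core test consumes the class indices — and is therefore frozen
and tested as a bijection.

Surrogate subtypes are derived from the IHC scores: HER2-positive iff IHC 3+
or FISH-amplified (2+ must be FISH-resolved; unresolved 2+ raises); ER/PR
positive at ≥ 1% (clinical convention); LumA = ER+, HER2−, Ki67 < 20%,
PR ≥ 20%; LumB = remaining ER+ HER2−; LumB_HER2pos = ER+ HER2+; HER2 = ER−
PR− HER2+; TNBC = triple-negative. The Ki67 and PR cuts are configurable
because the consensus classification leaves them to the laboratory; changing
them relabels cores, so they are surfaced prominently in `SubtypeRules`.

## Spatial analysis

Neighborhoods are Euclidean discs (inclusive radius, central cell excluded)
computed per core with a KD-tree; an O(n²) brute-force twin exists solely as
a test oracle and the two are asserted equal on randomized instances. The
default radii are 30 µm and 100 µm, mapped to the conventional 100 and 341 px
at the native pixel size (the exact quotients, 102.4 and 341.3, are rounded
to those printed equivalences; other pixel sizes round arithmetically).

Shannon equitability E_H = H/ln S uses, by default, S = number of classes
present in the core, making E_H comparable across central classes within a
core; "present in neighborhood" and fixed-panel scopes are selectable.
E_H := 0 when S = 1 (a lone species is maximally homogeneous), and a cell
with no neighbors has undefined (NaN) E_H and is excluded from per-class
means. No edge correction is applied at core boundaries. Cumulative
co-occurrence matrices pool neighbor counts per central class across cores
before row-normalizing. Immune neighborhoods label every QC-passing cell as
cancer / CD8 / CD20 / other (immune identity wins over the cancer gate; a
double-positive cell goes to the stronger normalized signal) and report, for
each central lymphocyte at 100 µm, neighbor fractions over the three named
populations.

## Paired-core statistics

The 16-class labels of each core's cancer cells form a numeric vector and two
cores of one specimen are compared with (a) a two-sample Wilcoxon rank-sum
test — exact only for tie-free combined n < 50, otherwise the normal
approximation with tie correction, since class vectors are heavily tied — and
(b) a label-permutation test of T = |mean(a) − mean(b)| with the add-one
estimator p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm), n_perm = 10,000 by
default. Treating nominal classes as ordinal scores is a deliberate,
documented simplification (the class ordering is fixed); a chi-squared
contingency test is provided as a sensitivity alternative but is not the
decision rule. Permutations are implemented by resampling per-class counts
from a multivariate hypergeometric distribution — exactly the label-shuffle
distribution at O(classes) per permutation — and are verified in tests
against literal shuffles and against exhaustive enumeration at tiny n. A pair
is significant only when both p-values are below α = 0.01; the conjunction is
conservative, and no multiple-testing correction is applied across cases. All
permutation p-values are bit-reproducible given (seed, n_perm). Subtype-level
comparisons (class fractions across subtypes, E_H across central classes) use
one-way ANOVA with Tukey HSD.

## Synthetic data

The generator emulates what the analysis consumes: 1.1 mm discs of segmented
cells at the default pixel size, cancer-class labels multinomial from
specified 16-class fractions, lymphocytes (scattered or aggregated), stromal
"other" cells, and optionally benign-duct epithelium with an exclusion
polygon; TNBC cores emit a tumor-inclusion polygon. Default cell count per
core is 1200 (desk-scale; real cores carry roughly twice that, which affects
absolute neighborhood sizes but none of the tested contrasts). Spatial models
are uniform-on-disc or a Thomas process (Poisson parents, Gaussian offspring,
offspring mean 60, cluster SD 80 px), with optionally class-pure clusters.
Non-cancer cells are drawn below the size gate — lymphocytes and fibroblasts
genuinely are smaller than carcinoma cells — which keeps the generator's
ground truth exact through both the PCK and the annotation gating paths.

Intensities are drawn on a latent 0–15 scale per marker: negatives as a
scaled Beta(1.5, 3) below the cut-point with a 5% guard band, positives as
cut-point + Gamma(2, ·) truncated at 15 (a "hot" variant with a heavier tail
models the high-P53 TNBC stratum), then mapped to raw counts by a per-marker
affine scale. Because the pipeline's normalization is dataset-global, the
generator pins two anchors per marker — the lowest-signal negative cell to
the detector floor (0) and the highest-signal positive cell to saturation
(15) — making min-max normalization the identity on the latent scale, so the
printed cut-points recover the intended positivity with zero leakage (a
nonzero leak rate is configurable). A marker with no positive cell in a
dataset is emitted as uniform background, since global rescaling would
otherwise manufacture positives out of noise; a marker with positives but no
negatives cannot survive fitted min-max normalization and raises. Ground
truth (population, class, gate flags, intended positivity) travels in a
separate JSON manifest, never in the cell table, so tests cannot leak labels
through the pipeline.

What the generator does **not** model: staining-round bleaching artifacts,
segmentation errors, spatially correlated intensity gradients, marker-marker
intensity correlations beyond class structure, or cell-shape anisotropy.
Passing tests therefore certify the pipeline's arithmetic, gating logic,
calibration and spatial statistics on data whose class structure is known
exactly — not robustness to optical artifacts in real images.

## Numerical and design choices

- Degenerate inputs: empty cores are flagged `empty` with NaN (undefined)
  fractions, never 0; all-zero neighborhood counts are undefined; a constant
  pooled class vector gives p = 1 in both paired tests.
- Permutation ties: T_perm ≥ T_obs is compared with a 1e-12 slack to keep the
  count exact under floating-point equality.
- Sample SDs use ddof = 1; per-class E_H aggregation reports n alongside
  mean/SD.
- The default scenario (5 subtypes, 11 paired cases, 22 cores × 1200 cells,
  one planted 30%-mass-shift pair, one benign-duct core, immune-rich HER2+
  cores, one high-P53 TNBC case) is the package's standing integration
  fixture; calibration simulations (1000 null pairs at 500 cells/core,
  n_perm = 2000) run at the sizes the test suite declares.
- Stage order and artifact immutability: each pipeline stage writes its
  outputs once; re-running a config reproduces byte-identical artifacts.

## Known limitations

- The Wilcoxon/permutation pair test inherits the ordinal-score caveat above:
  compositional differences that leave the mean class index unchanged are
  detectable only through the rank test's distributional sensitivity.
- Global min-max normalization is sensitive to single extreme cells in real
  data; optional percentile clipping exists but is off by default to keep the
  transform faithful to its definition.
- E_H at 30 µm on sparse cores rests on small neighbor counts and is noisy;
  per-class means should be read together with the reported n.
- No survival or outcome modelling, no batch correction across staining
  rounds, no pixel-level image processing.
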