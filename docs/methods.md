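# Methods

This note documents the models, conventions and numerical choices behind
`foltme`, in the order the pipeline runs, and states what the synthetic
generators do and do not emulate.

## Optical density and stain deconvolution (`stains`)

Bright-field chromogens obey Beer–Lambert absorption, so staining is
linear in optical density, `OD_c = −log10((I_c + ε)/I₀)` per RGB channel
`c`, with white level `I₀ = 255` and `ε = 1` grey level to keep black
pixels finite. A `StainMatrix` holds three unit row vectors in OD-RGB
space; the defaults are the published Ruifrok–Johnston hematoxylin and
DAB vectors and the AEC vector used for sequential-IHC red chromogen
(identical to scikit-image's `rgb_from_hdx`/`rgb_from_hax` up to row
normalization), with the residual row the normalized cross product of the
other two. Unmixing solves the 3×3 system `OD = C·M` per pixel; negative
concentrations are physically impossible and are clipped to zero with the
clipped fraction recorded (the residual channel routinely absorbs camera
noise, so some clipping is normal). `compose` is the exact inverse
(`I = I₀·10^(−C·M) − ε`, quantized), so compose → deconvolve round-trips
to within 8-bit quantization.

Quantization bounds the achievable round-trip accuracy: the per-channel
OD error of a one-half grey-level rounding is `0.5·log10(e)/(I+ε)`, which
grows as pixels darken. In the renderer's physical regime — counterstain
up to 0.8 OD, chromogen up to 1.0 OD — the worst-case per-pixel
concentration error stays below 0.02 OD; if both stains were pushed to
1.0 simultaneously (darker than any realistically counterstained slide)
it would reach ≈ 0.024. Validation random fields therefore sample
hematoxylin in [0, 0.8] and chromogen in [0, 1.0].

## Synthetic slides (`slidesim`)

A high-power field (HPF) is modeled as a square of 0.0625 mm²
(250 µm × 250 µm, the conventional 40× field); all densities are
cells/HPF regardless of rendered pixel size. Per ROI the generator:

- places random ellipses (semi-axes 40–90 µm) greedily until the union
  covers the target IF fraction (default 0.5 ± 0.05), mirroring the
  roughly half-follicular composition of the tissue;
- draws each marker's cell count per compartment as
  Poisson(density × compartment area / HPF area) and scatters centers
  uniformly in the compartment; cells are Gaussian-profile disks
  (radius 3.5 µm, peak 0.9 OD) in concentration space — adequate for
  count/ratio validation, not for morphology;
- renders CD21 not as discrete cells but as a ridge-like meshwork
  texture strictly inside follicles (it marks the follicular-dendritic
  network), which is what the segmentation stage thresholds;
- uses one shared hematoxylin texture across rounds (same tissue,
  re-counterstained), the modality registration aligns on;
- simulates double-positive populations (e.g. CD68/CD163) by re-using a
  configured fraction of the partner marker's centers;
- composes channels through the stain matrix of the round's chromogen
  plus Gaussian OD noise (default sd 0.015), and can distort each round
  by a stored rigid + smooth elastic sampling map (elastic magnitude
  bounded at 15 px).

Default densities (CD68 40/60, CD163 2/45, CD8 2/30 cells/HPF for IF/EF)
reflect the observed compartment asymmetry: macrophage and T-cell
markers are predominantly extrafollicular, with the per-patient CD68
generator ranges 12–67.5 (IF) and 22–103.5 (EF) available in
`cohortsim`. Not emulated: nuclear texture, tissue folds, defocus,
whole-slide canvases, staining batch effects — so passing tests certify
the computational pipeline, not robustness to those artifacts.

## Registration (`registration`)

A `Transform` is the sampling map `V(x) = A·[x + d(x), 1]` used to pull
the moving image onto the fixed grid (displacement field first, then
affine). Ground truth for a synthetic distortion is the numerical
inverse of the distorting map (fixed-point iteration, which converges for
the smooth bounded fields used here).

Global alignment: phase cross-correlation with 20× subpixel refinement
seeds a Powell search over rigid (angle + shift) or affine (6 d.o.f.)
parameters, minimizing intensity MSE over a 3-level Gaussian pyramid
(relative tolerances 1e-4/1e-6). Elastic refinement: iterative
Lucas–Kanade optical flow between the fixed image and the prior-warped
moving image, Gaussian-smoothed (σ = 4 px) as an explicit smoothness
penalty, composed with the prior; if refinement fails to reduce MSE the
prior is returned unchanged, making the chain monotone by construction.
Registration always runs on the hematoxylin concentration channel — the
only modality shared across rounds — with round 1 (the CD21 round) as
reference, since compartment masks derive from it. On synthetic
distortions within the design envelope (≤ 10 px shift, ≤ 2° rotation,
≤ 10 px elastic) the chain recovers landmarks to ≈ 0.1–0.2 px mean error.

## Compartment segmentation (`compartments`)

Otsu threshold on the CD21 concentration channel → morphological closing
(default radius 15 px at 0.25 µm/px; scale with pixel size) → hole fill →
removal of components below `min_area` (default 2000 px², a small
follicle at 0.25 µm/px). Both parameters are config-exposed; validation
at 1 µm/px uses radius 6 and 300 px². An effectively constant channel
yields an empty mask plus a warning rather than an error, so batch runs
survive follicle-free ROIs. The EF mask is the exact complement — every
ROI pixel belongs to exactly one compartment, with no gap class; a
pathologist-drawn PNG mask (0 = EF, 255 = IF) can be supplied and takes
precedence over automatic segmentation.

## Quantification (`quantify`)

Detection is multi-scale Laplacian-of-Gaussian blob detection (radii
converted to σ = r/√2, 8 scale steps, >50 % overlap suppression) — a
deliberate, dependency-light re-implementation of interactive
cell-segmentation tooling, sufficient for count-level accuracy (F1 > 0.92
on default synthetic slides). A cell's compartment is decided by its
center pixel (boundary cells are not split). Double positives across
co-registered rounds are mutual nearest neighbors within a match radius,
each detection joining at most one pair. Image-cytometry tables merge
all detections into cell objects by greedy union over mutual-NN pairs;
per-cell intensity is the maximum concentration within the match radius
of the object center, robust to the 1–2 px residual elastic registration
leaves. Gating is a strict `intensity > threshold` percentage.

## Scoring and survival (`scoring_survival`)

- Patient score = median over the (default 10) per-ROI counts; even
  counts give midpoint medians, hence half-integer scores and
  half-integer data-driven thresholds (32.5, 39.75, 16.25, 53.75).
- Ratio = median over ROIs of `100 × num/den`, the less abundant marker
  as numerator by convention; ROIs with zero denominator are excluded
  and flagged, a patient with no usable ROI is an error. Thresholds on
  ratios are kept as dimensionless values.
- "High" means score ≥ threshold, matching the stratification convention
  of the source figures.
- Cutpoints: exhaustive scan of midpoints between consecutive sorted
  unique scores, maximizing the two-group log-rank statistic subject to
  both groups holding ≥ `min_group_frac` (default 0.15) of the cohort —
  the single-split reading of recursive partitioning. Ties break toward
  the lowest threshold; the reported p is the naive log-rank p at the
  selected split (selection-adjusted inference is out of scope).
- Kaplan–Meier is implemented directly (product-limit, Greenwood
  variance, CI on the log(−log S) scale truncated to [0, 1]) and
  cross-checked against lifelines in the tests; the log-rank statistic
  is the vectorized O−E / hypergeometric-variance form, needed anyway
  for the cutpoint scan and the 1000-replicate calibration loops, and is
  also validated against lifelines. Cox fits go through statsmodels
  `PHReg` (Efron ties default, Breslow available); monotone likelihood
  is flagged (`converged=False`) rather than raised.
- Group tests: Mann–Whitney U (scipy exact where feasible) for two
  groups; Kruskal–Wallis plus Dunn's pairwise rank z-tests
  (tie-corrected pooled variance, Bonferroni adjustment) for three or
  more. Dunn's test is implemented in-package because no maintained
  implementation is available in the dependency set; its two-group z²
  reproduces the Kruskal–Wallis statistic exactly.
- No multiplicity adjustment is applied across markers; two-sided
  α = 0.05 throughout.

## Cohort simulation (`cohortsim`)

Categorical marginals default to the 49-patient composition (stage
10/11/9/19, grade 24/25, FLIPI 6/22/21, BCL2 13/36, sex 26/23); variables
are sampled independently unless coupling is configured explicitly. Ages
are a truncated normal (mean 58, sd 12, clipped to 34–87) rounded to
years. Event times are exponential proportional hazards — any PH law
would do; the exponential gives closed forms for testing (median ln2/λ,
S(t) = e^(−λt)) — with baseline hazard 0.008/month, independent
exponential censoring (0.004/month) truncated at a 120-month
administrative horizon. `log_hazard_coefs` keys covariate columns (or
`"variable:level"` indicators) to log hazard ratios; the reference
effect size for recovery experiments is HR 0.23 for the low-risk group.
POD24 = 1 iff an event occurred within 24 months; patients censored
before 24 months count as POD24 = 0, and deaths without progression are
treated as censored (the EFS definition leaves both unstated; these are
the package's choices). Marker profiles are uniform within configured
per-marker/compartment ranges, with an optional signed BCL2-negative
density shift (clipped back into range) to emulate the observed
BCL2–CD68 association.

## Epimutation scan (`epimutation`)

SEM definition: beta outside `[Q1 − 3·IQR, Q3 + 3·IQR]` of the
full-cohort per-CpG distribution (the established SEM convention);
quantiles use linear interpolation, and zero-IQR CpGs are never callable
and are flagged. Burden: Poisson GLM of per-sample SEM count on a group
indicator, unadjusted, Wald p (the single-covariate MLE rate ratio is
the group mean ratio, asserted in tests). Window scan: windows of
`window_size` consecutive CpGs (default 10) per chromosome in position
order, step 1; `k` counts window CpGs that are SEM in ≥ 1 sample of the
group (calls pooled within group), and p is the exact upper-tail
hypergeometric probability against the genome-wide totals. Overlapping
windows with p ≤ α (default 0.05) merge into regions annotated to genes.
Window size, step and α have no reference values, so published gene
counts cannot serve as reproduction targets; the scan is validated by
exact combinatorial equality and brute-force window enumeration instead.
The synthetic methylome is bimodal (CpG means near 0.15/0.85), Beta-
distributed with precision 150 (tight array-like cohort IQRs), with SEMs
injected as reflections to the opposite methylation extreme; at the
3×IQR fence this yields ≥ 0.9 sensitivity and ≥ 0.99 specificity. FFPE
noise, probe filtering and normalization are out of scope.

## Validation problem sizes (`validation`, `scripts/acceptance.py`)

Benchmarks run at sizes chosen to exercise every stage in a few minutes
on one CPU: 256² random fields for the unmixing round trip; 20 distorted
320² slides for registration; 10 250² ROIs for segmentation; 300-patient
cohorts × 100 replicates for cutpoint recovery (patient scores are
medians of 10 Poisson HPF counts, so the score grid is half-integer);
1000 null replicates for each type-I calibration; 200 replicates at
n = 500 for Cox CI coverage of HR 0.23. All randomness derives from a
single seed.

## Known limitations

- Blob detection has no notion of touching/overlapping nuclei; at very
  high densities counts bias low.
- The renderer's noise model is additive Gaussian in OD; real slides
  have structured chromatic noise, so stain-vector misspecification is
  untested.
- The cutpoint p-value is not adjusted for threshold selection.
- Categorical cohort variables are independent by default; real
  clinical covariates correlate.
- The elastic registration assumes deformations within ~10 px and
  shared counterstain texture; it has no feature-matching fallback for
  larger motions.
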