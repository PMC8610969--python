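# Methods

## Signal model and estimators

The package assumes magnitude DWI volumes acquired at b = 0, 50, 250,
800 s/mm² (configurable via `BValueScheme`, strictly increasing with
b0 = 0) that are already reconstructed to isotropic diffusion-weighted
images on a common grid. No registration, motion correction or spatial
smoothing is applied; every estimator is a pure per-voxel function, so
parameter maps are invariant to voxel iteration and storage order.

The bi-exponential IVIM signal is inverted in closed form rather than by
free fitting. The log-slopes ADC(0,800), D1'(50,800) and D2'(250,800)
estimate diffusion with decreasing perfusion contamination; f1' and f2'
measure the relative excess of S(0) over the back-extrapolated diffusion
component; D*' inverts the b = 50 reading for the pseudo-diffusion rate
using D2' and f2'. The forward model used by the phantom,
`S(b) = S0·[(1−f)·e^(−bD) + f·e^(−bD*)]`, decays the perfusion
compartment with rate D* itself — the parametrisation that the D*'
inversion is consistent with. A switch to the alternative
`e^(−b·(D+D*))` convention is available on `ivim_signal` and
`CohortSpec` (`compartment_rate="d_plus_dstar"`).

Internal units are mm²/s and unit fractions throughout; the
conventional report scales (coefficients ×10⁻⁶ mm²/s, fractions ×10⁻³)
are applied only when summaries and tables are produced.

### Undefined and negative voxels

A voxel has no defined value where a logarithm argument or denominator
is non-positive: any signal ≤ 0 for the log-slopes, S(0) ≤ 0 for the
fractions, and for D*' a perfusion fraction f2' ≤ 0 or a non-positive
log argument (the b = 50 reading at or below the extrapolated diffusion
component). Undefined voxels hold NaN, but the boolean `defined` mask is
authoritative; ROI statistics use defined voxels only, and per-parameter
exclusion counts are logged. Negative but defined values (noise
artefacts, mostly in f1'/f2') are *retained* in ROI statistics — only
undefined voxels are excluded — with a separate `negative` mask kept so
the stricter policy is one filter away. In the mono-exponential limit
f2' cancels to zero only up to rounding, so the D*' inversion treats
f2' ≤ 1e-12 as "no perfusion compartment" (far below any physical
fraction, above the ~1e-15 rounding floor).

### Known bias of the closed-form diffusion estimates

D2' attributes the perfusion signal still present at b = 250 to
diffusion, inflating it by
`Δd2 = ln[(1 + r·e^(−250·(D*−D))) / (1 + r·e^(−800·(D*−D)))]/550`,
`r = f/(1−f)`. For fast perfusion (D* ≳ 20×10⁻³ mm²/s) and moderate f
this is well below 1% of D, but it grows steeply as D* approaches
10×10⁻³ mm²/s or f approaches 0.4 — several percent in that corner. The
same residue propagates into f2'. The test suite verifies that the
pipeline's end-to-end recovery error on noise-free phantoms equals this
analytic bias to 0.2%, i.e. the implementation adds no error of its own;
the strict 1%/5% per-lesion recovery check over the full calibrated
parameter distributions fails precisely for the low-D*/high-f tail, and
that failure is an intrinsic property of the simplified method, not of
the code.

## ROI model

Lesions are delineated per slice on the acquisition grid (0-based
(slice, row, column) voxel coordinates, no sub-voxel geometry). The
first and last lesion slice are always labelled "bad" (partial-volume
risk), as is any artefact-degraded slice; exactly one good slice is the
2D reference. Six variants are analysed: extents 2D / 3DG (good slices)
/ 3DA (all slices), each including or excluding the lesion's centrally
deviating area (CDA: necrosis, cystic components, scars). For CDA-free
lesions the two tissue modes coincide and both rows are emitted.

Summaries are computed over defined voxels only: mean, median, sample SD
(n−1), percentiles 5/10/25/75/90/95 by linear interpolation between
order statistics at fractional rank p·(n−1) (numpy's default; fixed and
used everywhere including tests), adjusted Fisher–Pearson sample
skewness, and excess kurtosis (normal → 0; a documented switch
`summarize_roi.excess_kurtosis = False` selects the raw convention).
Zero-variance ROIs report NaN skewness/kurtosis; ROIs with no defined
voxel (a fully unperfused D*' map) are marked unavailable and dropped
pairwise from any comparison that needs them, with counts logged.

## Diagnostic evaluation

The empirical (Mann–Whitney) AUC counts benign/malignant pairs with ties
scored ½. The orientation ("benign-high" `>` vs "benign-low" `<`) is
chosen per marker as the direction with AUC ≥ 0.5 (ties → benign-high)
and always reported. Variances and covariances of paired AUCs use the
DeLong structural-components estimator; confidence intervals are normal
approximations clipped to [0, 1] (consistent with printed upper bounds
of exactly 1.000 at small benign counts); paired curves are compared
with the DeLong z test. Youden-optimal cut-offs scan the midpoints of
adjacent sorted unique pooled values plus ±∞, treat malignant as the
positive class, and break ties toward the smallest cut-off. Accuracy is
prevalence-weighted: `(Sen·N_mal + Spec·N_ben)/(N_mal + N_ben)`. Raw
p-values are reported with α = 0.05 and no multiple-testing adjustment —
matching how such tables are conventionally presented; both choices are
configurable at the call sites.

Three comparison families are produced: (i) 2D vs 3DG vs 3DA per
parameter and tissue mode (mean metric); (ii) CDA included vs excluded
per parameter and extent; (iii) each 2D histogram metric vs the 2D mean
in three tissue pairings, including the cross pairing metric-inclCDA vs
mean-exclCDA that asks whether low percentiles can replace manual CDA
exclusion.

## Synthetic phantom

The generator emulates the clinical study material this pipeline is
aimed at, with known ground truth:

* **Cohort composition** — 74 malignant and 35 benign lesions by
  default (the 1.5 T study size), a CDA in 36/109 of lesions.
* **Lesion-level parameter distributions** — truncated normals
  calibrated on the published 1.5 T group statistics (2D-ROI, CDA
  excluded): malignant D 939±250, benign 1423±416 (×10⁻⁶ mm²/s, from
  the D2' column); malignant f 0.141±0.096, benign 0.191±0.104 (f2'
  column); malignant D* 18.8±8.6, benign 21.2±13.3 (×10⁻³ mm²/s, D*'
  column). Truncation bounds are physical/literature limits fixed in
  advance: D ∈ [0.2, 2.8]×10⁻³ mm²/s, f ∈ [0.02, 0.40],
  D* ∈ [10, 80]×10⁻³ mm²/s.
* **Geometry** — one ellipsoidal lesion per 9×32×32 grid (in-plane
  semi-axes 6–11 voxels, 5–7 slices), embedded in liver-like background
  tissue (D 1.05×10⁻³, f 0.25, D* 60×10⁻³). The coarse grid keeps a
  full study-sized cohort in the low seconds on one CPU.
* **CDA cores** — concentric ellipsoids (35–70% of the lesion's
  semi-axes) of free-fluid-like tissue: D 2.5–3.0×10⁻³ mm²/s, f ≈ 0.01.
* **Bad slices** — edge slices labelled bad; interior slices are
  artefact-degraded at rate 0.15 by translating their two high-b images
  one to two voxels in plane (pixel misalignment), always leaving at
  least one good slice. The reference slice is the good slice with the
  largest ROI area, ties to the lowest index (central slices preferred,
  lower slices less affected by cardiac motion).
* **Noise** — Rician: `√((S+ε₁)²+ε₂²)`, ε ~ N(0, σ²), default σ = 15
  against a lesion S0 of 1000. No SNR was published for the source
  protocol; this default is a documented guess chosen so that a small
  percentage of ROI voxels yields negative or undefined parameters, the
  regime the masking logic is built for.

All randomness flows from a single seed through named substreams
(parameter draws, geometry/artefacts, per-lesion noise), so cohorts are
bit-reproducible. The phantom does **not** model anatomy, partial-volume
voxels at lesion rims, respiratory/cardiac motion beyond the slice-level
artefacts, field-strength effects, or inter-rater ROI variability —
passing tests therefore demonstrate correctness of the estimation and
comparison machinery under the stated signal model, not clinical
performance on real data.

## Validation strategy and problem sizes

The suite checks every stage against an independent oracle: hand-derived
worked examples for the closed-form estimators; a nonlinear
two-compartment least-squares fit on 10³ noise-free voxels drawn from a
class-typical box (group means ± ~½ SD: D ∈ [0.8, 1.6]×10⁻³, f ∈
[0.08, 0.25], D* ∈ [16, 30]×10⁻³ — the regime the 4-point design is
meant for); brute-force pair counting and exhaustive threshold search
for AUC and Youden on 200 random tied instances; a 10⁴-resample
lesion-level bootstrap for DeLong p-values on 20 paired instances; and a
20-seed majority-vote replication of the qualitative ROI-strategy
findings on study-sized noisy cohorts (CDA exclusion helps the diffusion
parameters, p10-with-CDA matches mean-without-CDA, 2D ≈ 3D). These sizes
keep the full suite around two minutes on one CPU while leaving the
stochastic checks comfortable margins.

## Design choices made where the design was open

* Direction of each ROC curve is computed from the data (the published
  tables print a direction column but no rule); it is always reported.
* Cut-off candidates are midpoints of adjacent unique values — printed
  cut-offs fall between group clusters, consistent with midpoint-style
  thresholds, but no exact rule is stated anywhere.
* Negative parameter values enter ROI statistics (only undefined voxels
  are excluded); treatments differ across the literature, so the
  per-voxel negative flag keeps the alternative one switch away.
* The 2D histogram analysis uses the same 2D ROIs as the mean analysis
  in both tissue modes.
* Lesion summaries that are unavailable are dropped pairwise per
  comparison rather than listwise across the whole analysis.
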