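# Methods

`thyropet` re-implements, as a tested pipeline over synthetic data, the
quantitative analysis of [18F]FDG-PET/CT in cytologically indeterminate
(Bethesda III/IV) thyroid nodules: SUV-based rule-out threshold analysis with
separate non-Hürthle and Hürthle cut-offs, and a factor-based radiomic
classifier. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data can and cannot show.

## Synthetic cohort and phantoms

No per-patient dataset is public; the generator emulates the published
cohort structure: n = 123, cytology 45/32/24% (AUS/FLUS, FN/SFN, HCN/SHCN),
27% malignant/borderline outcome, and group-wise SUV distributions matching
the published median/IQR summaries per stratum and outcome.

**SUV distribution family.** SUVs are positive and right-skewed and the
summaries are median/IQR, so each (cytology group, outcome) stratum draws
SUVmax from a log-normal. The fit is the closed-form quartile fit
`mu = (ln q1 + ln q3)/2`, `sigma = ln(q3/q1) / (2 z_0.75)`, which reproduces
both quartiles exactly. A two-parameter log-normal cannot also match an
arbitrary median; the implied median is the geometric mean `sqrt(q1 q3)`,
which for the published summaries sits within 10% of the printed medians —
inside the generator's Monte-Carlo calibration tolerance, which is what the
calibration tests assert. SUVpeak is drawn from its own calibrated log-normal
coupled to SUVmax through a shared Gaussian factor (rho = 0.9) and capped at
SUVmax; the contralateral background SUVmax is independent.

**Visual positivity** is modelled as a contrast rule, not a reader:
positive iff SUVmax / background > 1 + eps with eps = 0.1 (configurable).
The published visual reads are a judgement call this rule only approximates;
with the calibrated distributions it yields ~75–80% positive versus the
published 68%, which is acceptable for its role (selecting the radiomic
subset and the visual rows of the accuracy tables).

**Allocation** of subgroup and outcome counts is deterministic
largest-remainder by default (a multinomial option exists), so n = 123 at
27% prevalence gives exactly 33 malignant/borderline cases.

**Phantom rendering** (imaging mode): the PET nodule is an ellipsoid of
peak uptake over a flat thyroid background, multiplied inside the support by
`1 + a*t(x)` where `t` is a band-limited Gaussian random field (correlation
length 6 mm, normalised to unit maximum amplitude) and `a` the texture
amplitude; the volume is convolved with an isotropic Gaussian PSF
(default FWHM 7 mm, a typical reconstructed PET resolution) and Gaussian
noise is added (sd = 5% of background — simple, sufficient for exercising
the texture pipeline; Poisson-like noise is out of scope). The tabulated
SUVmax is used as the *pre-blur* peak, so measured SUVs fall below tabulated
values for small nodules — the partial-volume effect is deliberate.
Default grids: PET 3.18 mm isotropic; the ldCT is rendered at 1.59 mm
isotropic in cohort mode (half the PET spacing keeps the 2 mm interpolation
target non-trivial while an 84-case cohort stays tractable; standalone
phantoms accept any CT spacing, e.g. 1 mm). The nodule sits off-centre in
one "lobe" so a box mirrored through the grid centre samples the
contralateral background.

What the phantoms do **not** emulate: scanner/reconstruction physics
(sinograms, EARL harmonisation), respiratory motion, multi-nodule glands,
incidentalomas, correlated PET/CT texture, and any real association between
image texture and malignancy. Passing tests therefore demonstrate
correctness of the computational pipeline and calibration of its statistics,
not clinical performance on patients.

## SUV quantification

SUVmax is the maximum voxel value in the region; the background SUVmax is
the maximum in the contralateral region (mirrored box in phantom mode, input
column in tabular mode); the ratios divide nodule SUVmax/SUVpeak by that
background. Input volumes are assumed already body-weight-normalised (g/mL).

SUVpeak is the maximum mean over a 1 cm³ sphere (radius 6.204 mm). Sphere
membership is by voxel-centre inclusion and candidate centres are voxel
centres whose sphere intersects the region — no sub-voxel placement and no
partial-volume weighting, the standard deterministic construction, and the
brute-force oracle in the tests implements exactly the same contract.
Spheres may extend beyond the nodule (consistent with the cited SUVpeak
definition); near the volume edge the mean is over the in-volume part.

## Segmentation

The VOI is the set of in-box voxels at or above a background-corrected
50%-of-SUVpeak threshold, reduced to the single 26-connected component
containing the in-box SUVmax voxel. The source method's exact formula is not
printed in the study; both standard readings are implemented:

* `relative` (default): `T = bg + 0.5 (SUVpeak − bg)`
* `additive`: `T = 0.5 SUVpeak + bg`

The choice is recorded in the mask provenance; no claim is made about which
produced the study's masks. Ties at the threshold are included (`>=`).
Boxing crops an axis-aligned region around the locator (default margin 1.5×
the stated size) to exclude neighbouring avid tissue. The ldCT VOI is
derived by nearest-neighbour resampling in world coordinates. The study's
visual mask-mismatch check is replaced by automated Dice/volume assertions
in the test suite.

## Radiomic features

PET is trilinearly interpolated to 4 mm isotropic, ldCT to 2 mm; masks are
nearest-neighbour resampled alongside, and extraction never mixes grids.
Intensities are discretised at fixed bin widths (0.5 g/mL PET, 25 HU CT)
with bin edges anchored at the in-mask minimum (the common fixed-bin-width
convention; IBSI permits other anchors, so the anchor is stated here).

107 features per modality, frozen in a golden manifest:
14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM;
PET additionally carries TLG = SUVmean × MTV. Texture conventions: GLCM and
GLRLM use distance 1 over the 13 unique 3-D directions, symmetric matrices,
features averaged over directions; GLSZM/GLDM use 26-connectivity; GLDM
dependence tolerance alpha = 0 with the dependence size counting the centre
voxel; NGTDM uses the 26-neighbourhood. Degenerate inputs take documented
convention values (single grey level: GLCM correlation 1, NGTDM coarseness
10^6; single-voxel masks: texture features NaN, never silently zero).

Shape features are mesh-based: marching cubes on the binary mask after a
light Gaussian smoothing (sigma = 1 voxel) of the indicator field. The
smoothing removes the staircase bias of binary marching cubes — on a
digitised sphere it brings sphericity within ~0.5% of 1 versus ~9% error on
the raw mesh; masks too small to survive smoothing fall back to the binary
mesh. Principal-axis lengths use the physical-coordinate covariance of voxel
centres (4·sqrt(eigenvalue)).

The reference extraction tool is not installable in this environment, so
cross-checking is against independent oracles instead: exhaustive pair/run/
zone enumeration on small grids, analytic phantoms, and algebraic
identities. The feature names follow that tool's default catalogue, which
the family counts pin down.

## Dimensionality reduction

Per training split: z-standardise on training statistics; greedily drop
features until no retained pair has |Pearson r| > 0.9 (threshold unprinted
in the source workflow; 0.9 is the package default and a logged config
item), removing first the feature with the most super-threshold partners,
ties broken by name; fit a maximum-likelihood factor model on the training
correlation matrix with `floor(n_train/10)` factors (minimum 1); varimax
rotation (own Kaiser implementation, communalities preserved to 1e-8);
factors ordered by explained variance with deterministic sign convention;
Thomson regression score weights `W = (ΛΛ' + Ψ)^{-1} Λ` (Bartlett scores are
a documented alternative, not implemented). Test cases are projected with
training means/sds and weights only — deleting test cases cannot change the
fit, and the tests assert this.

KMO is `Σr² / (Σr² + Σpartial²)` over off-diagonal entries, with partial
correlations from the inverse correlation matrix; a singular matrix gets the
smallest ridge from {1e-6, 1e-5, ...} that restores positive definiteness
(logged via warning). Note a genuine small-sample effect: when the retained
feature count approaches the training-set size the barely-regularised
inverse makes partial correlations saturate and KMO collapses toward 0 —
the published per-fold KMO (≥ 0.927) came from a more strongly shrunken
correlation estimate on real, heavily inter-correlated radiomics, and is not
a desk-scale reproducible quantity.

Factors are reported by their top-loading features; no semantic naming is
attempted (that was a qualitative interpretation step).

## Classifier and evaluation

Elastic-net logistic regression on the factor scores, minimising mean
negative log-likelihood plus `strength·[l1·||β||₁ + (1−l1)/2·||β||₂²]`,
intercept unpenalised, predictors standardised internally. Defaults:
l1_ratio 0.5; penalty strength either fixed or selected by stratified
5-fold CV on the training split (both unprinted in the source; both logged).
The intercept is profiled to its exact optimum after the solver finishes, so
the infinite-penalty limit lands on the class log-odds.

Evaluation: 20 stratified 80/20 random splits (stratification is this
package's choice — with 27% prevalence and test sets of ~17 an unstratified
split frequently lacks positives; it is logged and switchable). The entire
reduction (standardisation, filtering, factor model, penalty selection) is
refit per split on the training cases only. Test AUC is the rank (Mann–
Whitney) AUC with ties at one half. The 95% CI is the corrected resampled
t-test: `mean ± t_{k−1,0.975} sqrt(s²(1/k + n_test/n_train))` with realised
split sizes, clipped to [0, 1]; zero variance degenerates to the mean. The
null-calibration test (200 label-permuted cohorts of n = 84, 20 splits
each) checks that this CI covers 0.5 at the nominal rate.

The published real-data AUCs (0.445 / 0.519 / 0.694) depend on the patient
images and are deliberately not value-targets; the classifier arm is
property-tested (oracle predictor, null calibration, leakage checks,
planted-factor recovery) instead.

## Threshold analysis

Positivity is `value >= cut-off` (higher uptake is more suspicious).
Candidate cut-offs are the observed values (selection on exact values by
default; a one-decimal rounded mode mirrors published presentation); the
selected cut-off is the largest with sensitivity ≥ 95%, which among equally
sensitive candidates maximises specificity. If none qualifies, the minimum
value is returned with a warning. Sensitivity, specificity, NPV, PPV and
the benign call rate `(tn+fn)/n` carry exact Clopper–Pearson intervals from
beta quantiles (lower bound exactly 0 at 0 successes, upper exactly 100% at
n); zero-denominator proportions are reported as not applicable, never 0/0.
ROC AUC is trapezoidal over the empirical curve (identical to the rank AUC;
asserted to 1e-12) with a DeLong interval — the AUC CI method is unprinted
in the source, DeLong is the standard nonparametric choice and is
bootstrap-cross-checked in the tests.

## Problem sizes and determinism

Defaults are chosen so the full pipeline is interactive on one CPU: tabular
cohorts of 123; imaging demonstrations on 24–84 cases at 48³–64³ PET grids;
the null-calibration simulation uses 200 repetitions of 20 splits on
10-feature cohorts. Every stochastic stage takes a seed derived from the
single run seed; identical seeds give bit-identical volumes, cohorts and
evaluation JSON (asserted in tests).

## Known limitations

* The synthetic feature table used by tabular-mode classifier runs carries a
  planted block-factor structure, not image-derived texture; it exercises
  the reduction/classification machinery only.
* The generator leaves any joint dependence between SUV level and texture
  class unspecified (unconstrained by the published summaries); it is a
  config knob, not an assertion.
* Shape `Maximum2DDiameter{Slice,Column,Row}` are projected in-plane mesh
  diameters with the axis convention documented in the code; other tools
  bind these names to specific anatomical planes.
* Visual positivity as a threshold rule cannot reproduce reader
  idiosyncrasies; visual-row results on synthetic cohorts are illustrative.
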