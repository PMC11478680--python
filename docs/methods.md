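# Methods

## Problem and data model

The package estimates leaf chlorophyll content C (mg per g fresh mass)
from leaf-clip reflectance spectra sampled on a uniform wavelength grid,
by default 350–2500 nm at 1 nm (2151 bands). A `SpectraSet` couples the
n×p reflectance matrix with per-leaf metadata: seedling id, drought
treatment (T1–T4, T1 the most severe), leaf-pair position counted from
the shoot apex (1 = first pair of top leaves; treatment Tk carries
positions 1..k), leaf side within the pair, and the assay chlorophyll
value. Bands are addressed by physical nm label everywhere; averaging of
replicate instrument scans is assumed done upstream, one spectrum per
leaf. Raw reflectance must lie in (0, 1]; transformed sets are
unconstrained. Noisy edge bands are kept by default; `SpectraSet.trim`
exposes optional trimming.

## Assay arithmetic

Chlorophyll a and b in the acetone extract follow
Ca = 12.21·A663 − 2.81·A646 and Cb = 20.13·A646 − 5.03·A663 (mg/L), and
the content is C = V(Ca+Cb)/(1000·M) with V the extraction volume (mL)
and M the fresh mass in grams. The combined form
V(17.32·A646 + 7.18·A663)/(1000·M) is an exact algebraic identity of the
first two equations; the tests assert it to machine precision. M is
taken in grams: a milligram reading would put typical leaf contents three
orders of magnitude too low, so a 0.2 g aliquot enters as M = 0.2. The
calculator takes V and M explicitly so any aliquot convention is
expressible.

## Preprocessing registry

21 transforms: identity R plus 20 compositions of d1 (first derivative),
d2, √, log10, reciprocal, SNV and MSC. Numerical choices:

- Derivatives are central differences on the nm grid with one-sided
  differences at the two endpoint bands — no Savitzky–Golay smoothing,
  which keeps the operator linear and parameter-free.
- Log base is 10 (absorbance convention for log(1/R)). PLS predictions
  are invariant to the base, so this cannot affect model comparison.
- FD-SNV / FD-MSC take the derivative first, then scatter-correct.
- SNV scales each row to mean 0, sd 1 (ddof = 1); a zero-variance row is
  an error, not an imputation.
- MSC regresses each spectrum on a reference by OLS and inverts the
  fitted offset/slope. The reference is the mean of the *training* rows:
  `TransformSpec.fit` captures it and `FittedTransform.apply` corrects
  held-out spectra against it. All other transforms are stateless and
  row-wise.
- Domain violations (log/√/reciprocal of an out-of-domain value) raise an
  error naming the row and wavelength; nothing is imputed.

Because log(1/R) = −logR and log√R = logR/2 exactly, any |r|-based
screening, the selected band sets, and PLS accuracy are identical across
the three log variants — a structural equivalence the acceptance suite
verifies to 1e−8.

## Band selection

- CA: Pearson r of every band against chlorophyll on training rows; keep
  the k = 10 largest |r|, ties broken toward the shorter wavelength
  (deterministic and data-independent).
- CA(W): two rounds — six bands over the whole grid, then the two
  strongest bands inside each water window 1390–1490 and 1870–1970 nm. A
  window band already taken in the main round is not duplicated; the
  next-best window band backfills so the selection is always ten bands,
  four window-tagged.
- PCA: components of the standardized (correlation-scale) band matrix,
  retaining eigenvalues > 1. The Kaiser rule is only meaningful on the
  correlation scale, hence standardization is the default
  (covariance-scale is available). The training mean/scale/rotation are
  stored; held-out spectra are projected, never refit.

## Regression and validation

PLS1 via NIPALS on centered data; coefficients are folded back to the
original scale as B = W(PᵀW)⁻¹q, so predictions through latent scores and
through the linear form agree to machine precision, and PLS1 with as many
components as the design rank reproduces OLS. The latent-variable count
is chosen by inner grouped CV minimizing RMSE, then relaxed to the
smallest count within one standard error of the minimum (parsimony
against over-fitting smooth collinear spectra). Index models use OLS.

Cross-validation is 5-fold and grouped by seedling, shuffled within
treatment strata under a seed; the two leaves of a pair are near
duplicates, so leaf-level folds would leak. R² = 1 − SS_res/SS_tot on the
pooled out-of-fold predictions (not the mean of per-fold R²). All fitted
statistics — MSC reference, screening, PCA rotation, latent count,
coefficients — are re-estimated inside each training fold; a spy-recipe
test audits that no validation row ever reaches a fit.

Hold-out evaluation uses an 80/20 split by seedling, stratified by
treatment so every leaf position reaches the test set. Per-position
metrics are computed on test leaves only; positions with fewer than five
test leaves are flagged low-n rather than dropped.

Model ranking (`select_optimal`) is a bottleneck criterion: strategies
are ordered by hold-out R² on position-1 leaves (quantized at 1e−6),
ties broken by the smallest R² range across positions; the full trace is
emitted so the decision is auditable.

## Synthetic study generator

The measured data behind the original drought experiment are not
deposited, so the generator reproduces the *statistical structure* the
pipeline depends on, not leaf physics:

reflectance(λ) = clip(m·[baseline(λ) + g(C′)·bump₅₅₀(λ)
− d₁·W·trough₁₄₄₀(λ) − d₂·W·trough₁₉₂₀(λ)] + ε(λ), 0.001, 0.999)

- `baseline` is a fixed leaf-like curve: visible floor 0.08, red-edge
  sigmoid at 715 nm to a NIR plateau ≈ 0.45, smooth SWIR decline.
- The green bump (Gaussian, center 550 nm, width 35 nm) has amplitude
  0.25·exp(−C′/12), strictly decreasing in pigment, so more chlorophyll
  lowers the green peak and raises GNDVI.
- Water troughs (Gaussians at 1440/1920 nm) have depth proportional to
  water status W ∈ [0,1], so drier leaves reflect more in the windows.
- m = 1 + N(0, 0.02) is per-leaf multiplicative scatter and ε is additive
  noise (spectrally smooth component, 30 nm correlation length, sd 0.003,
  plus white sd 0.001) — exactly the nuisances SNV/MSC correct, so those
  transforms are non-trivial.
- C and W are drawn from treatment- and position-dependent normals.
  Chlorophyll means fall with drought severity (T1 6 → T4 18 mg/g) and
  with depth below the apex (−1.5 mg/g per pair); water falls likewise
  (treatment base 0.45→0.69, −0.10 per pair). The scale was chosen so
  error magnitudes land where leaf-chlorophyll calibration studies report
  them (RMSE of a few mg/g).
- C′ = C + η is the pigment signal the spectrum actually encodes; the
  link noise η has sd 4.5 mg/g at position 1 versus 0.7–1.2 elsewhere.
  This is the generator's mechanism for the study design's hardest case:
  the first top pair appears in all four treatments (widest range, from
  nearly abscising under T1 to healthy young leaves under T4) and is
  developmentally in flux, so its spectra are the least informative about
  its pigment. Bottom leaves get the widest within-group spread
  (sd 5 mg/g at position 4, senescence scatter).
- Treatment Tk emits pairs 1..k, two leaves each; the lowest pair of
  T2–T4 collapses to a single leaf with probability 0.3, giving ≈478
  leaves for 100 seedlings at the default size.
- True chlorophyll is routed through the assay arithmetic (content →
  absorbances → content), so metadata follows the same computation path
  as a laboratory value.

Calibration targets of the defaults: corr(C, R₅₅₀) ≈ −0.78 on the seeded
study fixture, matching the green-peak correlation magnitudes the
original analysis reports; leaf count within 10% of 478; position 1 worst
for every modeling strategy. The water–treatment coupling is deliberately
moderate (between-treatment spread 0.24 against within-group sd 0.15):
a stronger coupling turns the water bands into a treatment label that
full-spectrum models exploit, which masks the position-1 bottleneck in a
way the original study did not observe. One divergence to note: because
water and chlorophyll share the drought driver here, water-band
correlations with chlorophyll are ~0.3–0.5, larger than the ~0.08 the
original correlation tables show; the pipeline's behavior does not depend
on this magnitude, only on the water windows carrying water information.

What passing tests do **not** show about real data: the generator has no
specular/BRDF effects, no detector-splice artifacts, no wavelength
miscalibration, Gaussian features instead of true pigment/water
absorption line shapes, and additive noise that is stationary across the
grid. Absolute accuracies on real leaves will differ; the structural
claims (log-family equivalence, leakage-free CV, selection structure,
bottleneck ranking logic) are data-independent.

## Fixtures and problem sizes

`make_fixture("tiny")` = 4 seedlings/treatment on a 5 nm grid (76 leaves
× 431 bands), used for fast unit and equivalence tests.
`make_fixture("study")` = 25 seedlings/treatment on the full grid (473
leaves × 2151 bands), used for parameter-recovery and ranking tests. Both
carry fixed internal seeds. Per-position hold-out accuracy at study scale
rests on ~8–40 test leaves per position, so the bottleneck test averages
per-position R²_P over ten repeated hold-out splits (seeds 0–9) — a
repeated-hold-out estimator chosen for precision, with the split seeds
fixed a priori.

## Known limitations

- PLS1 only (single response); no PLS2, kernel or sparse variants.
- The eigenvalue > 1 rule is heuristic; no parallel analysis.
- The published ten-band equation's input convention (raw reflectance vs
  log(1/R)) is ambiguous in its source; both are implemented and neither
  asserted.
- The TVI index's printed formula is ambiguous; the literal
  parenthesization 60(R750−R500) − 100(R670−R500) is the default with the
  canonical 0.5[120(R750−R550) − 200(R670−R550)] switchable.
- The generator's treatment/position chlorophyll moments are plausible
  values chosen to reproduce reported correlation magnitudes, not the
  original study's (unpublished) moments.
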