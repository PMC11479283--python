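# Methods

This note documents the models, conventions and design choices behind
`spectraleaf`: what the synthetic generator simulates and deliberately does
not, and the exact definitions behind every statistic the analysis modules
report.

## The synthetic dataset

The generator emulates a two-species leaf phenotyping study: two
*Tradescantia*-like archetypes — a green-leaf form and an
anthocyanin-rich purple-leaf form — measured with a fluorometer (OJIP
transients) and a full-range spectroradiometer (reflectance and
transmittance, 350–2500 nm), with eight structural/ultrastructural traits
per leaf. Defaults: n = 200 leaves, balanced species, 5 nm wavelength step
(431 channels; 1 nm is available via `wavelength_step`), 70 log-spaced
time points on 10⁻⁵–1 s, fixed seed. The same seed reproduces every output
bit-for-bit.

### Traits

Each independently drawn trait is a truncated normal per species,
parameterized by a pooled mean, pooled CV%, and hard min/max bounds, plus a
signed fractional species shift (`species_effect`). Two deliberate
departures from the naive "draw N(mean, mean·cv/100) and truncate" recipe:

1. **Variance partition.** The pooled CV is split into a between-species
   component (the opposed species shifts) and a within-species SD, so that
   the pooled sample reproduces the configured spread rather than
   inflating it by the species contrast.
2. **Moment matching.** Truncating a normal at asymmetric bounds shifts
   its mean and shrinks its SD. The parent (μ, σ) are therefore solved
   numerically (via `scipy.stats.truncnorm` moments and Brent root
   finding) so the *truncated* mean equals the target exactly, and the
   truncated SD matches the target where the bounds allow. Some configured
   CVs are provably unattainable inside their bounds (a distribution
   confined to [212, 452] cannot have SD 83 μm around mean 372); in that
   case the generator takes the closest attainable SD and logs it. Mean
   matching never degrades.

Total leaf thickness is **never drawn**: it is the exact per-sample sum of
the four layer traits (adaxial epidermis + adaxial hypodermis + parenchyma
+ abaxial hypodermis). The default layer means sum to 849.2 μm, matching
the published pooled total (849.1 μm) to 0.01% — the internal-consistency
fact that justifies the additive design. The species shifts oppose each
other across layers (purple: thicker epidermis and parenchyma; green:
thicker hypodermis layers), so the total's relative spread is far below
that of the major layers, as observed in real data.

Chloroplast count is drawn as a continuous quantity; rounding to integers
would bias the degenerate (CV = 0) case and buys no downstream realism.
"Thylakoid layer–granum" is treated as a generic positive dimensionless
trait; whether it is a layer count or a thickness is immaterial to the
analysis.

### Fluorescence (OJIP)

F(t) = O + Σₖ Aₖ (1 − e^(−t/τₖ)) over the three rise phases with default
characteristic times τ_J = 4·10⁻⁴ s, τ_I = 2·10⁻² s, τ_P = 2·10⁻¹ s. The
green archetype has a slightly higher O level (1.1 vs 1.0) and phase
amplitudes scaled 1.3×, so its mean transient lies above the purple one at
every time point. Phase amplitudes are modulated multiplicatively by
standardized trait values: the adaxial hypodermis acts on the J phase, the
chloroplast count on I, the adaxial epidermis weakly on P, and granum
height carries a deliberately sub-noise J coupling. The transient is
measured from the adaxial surface, so abaxial-side anatomy is given **no**
fluorescence coupling — which reproduces the published pattern in which
fluorescence calibrations succeed for the adaxial hypodermis but fail for
the abaxial one. Noise is multiplicative Gaussian (default SD 1.5%);
amplitudes that would go negative after modulation are clipped at zero
with a logged warning.

### Optics (R, T, A)

A wavelength-dependent absorption budget is assembled from: a small
achromatic floor; chlorophyll-like bands at 430, 490 and 662 nm; an
anthocyanin-like band at 544 nm (strong in the purple archetype — hence
its depressed green-region reflectance); and water bands at 1200, 1450,
1940 and 2400 nm whose depth scales with standardized total leaf thickness
(`water_coupling`, default 0.15 per SD). The remaining light is split into
a reflected and a transmitted share (a gentle linear function of
wavelength), which guarantees R + T < 1 before features are added.
Trait-linked Gaussian features (center, width, amplitude per standardized
trait unit, target mode) are then added: strong features for the
hypodermis layers (red edge 700 nm, green region 544 nm, SWIR flanks near
1441/1607 nm, NIR 1125 nm, 2488 nm), a moderate blue feature for the
epidermis, chlorophyll-band features for chloroplast count, and **nothing**
for parenchyma, granum height and the thylakoid ratio. Additive Gaussian
noise (SD 0.005) is applied per channel; values are clipped to [0, 1] and
rescaled where R + T would exceed 1 (logged). Absorbance is always derived
as A = 1 − (R + T), so the three optical modes satisfy the conservation
identity exactly.

### Coupling jitter

Spectra respond to correlates of anatomy (water content, pigment packing),
not to micrometer measurements themselves. To keep trait predictions from
becoming unrealistically perfect as channels accumulate, the trait value
the optics "see" is the standardized trait plus a per-sample Gaussian
jitter (`signature_jitter_sd`, default 0.35 standardized units). This caps
the attainable prediction R² near 1/(1 + 0.35²) ≈ 0.89 for
strong-signature traits — the regime published calibrations of this kind
occupy — and is the main knob controlling overall task difficulty.

### What the generator does not model

No radiative-transfer realism (no plate/PROSPECT-style model), no
per-detector noise structure or splice artifacts, no within-species
trait–trait correlations beyond the shared species contrast, and no
spatial/imaging effects. Passing tests therefore demonstrate that the
*estimators* recover known structure under realistic noise — not that any
particular biological effect size is correct.

## Analysis conventions

* **SD and CV** use the n − 1 denominator everywhere; CV% = 100·SD/mean.
* **Median** of an even sample is the midpoint of the central order
  statistics.
* **Splits and folds** are stratified by species and fully seeded;
  calibration fraction defaults to 0.75.
* **PCA** centers but does not scale (one convention shared with PLSR);
  it is a deterministic SVD, with each component's sign fixed so its
  largest-magnitude loading element is positive. Explained variance is
  singular value² over total centered sum of squares. "Correlation
  loadings" are per-channel Pearson correlations with the first three
  scores; channels with |r| ≥ 0.70 are flagged influential.
* **Two-band index maps**: undefined cells (diagonal, zero denominators,
  zero index variance, < 3 defined samples) are NaN, never 0. The map's R²
  is the squared Pearson correlation, identical to simple-regression R²
  for one predictor. Ties in the best-pair search resolve to the smaller
  first channel, then the smaller second channel. The operation is
  axis-agnostic and is applied to fluorescence time pairs unchanged.
* **NIPALS-PLSR**: classical single-response algorithm (unit-norm weight
  w ∝ Xᵀy, score t = Xw, loadings p = Xᵀt/tᵀt and q = yᵀt/tᵀt, deflation
  of X and y). Extraction stops early if the y-residual becomes orthogonal
  to X. Factor selection: seeded species-stratified 10-fold
  cross-validation; the chosen count is the smallest whose RMSECV lies
  within 2% of the global minimum, capped at 7.
* **Validation metrics**: bias = mean(predicted − observed); RMSE with the
  n denominator; SEP = bias-corrected residual SD (n − 1); RPD =
  SD(observed)/SEP; slope/offset regress predicted on observed. Under
  these definitions RMSE² = ((n−1)/n)·SEP² + bias² holds exactly — the
  only convention under which published SEP/RMSEP/bias triples of this
  literature are mutually consistent, which is why it is normative here.
  The reported R² is r²; a 1 − SSres/SStot diagnostic (`r2_ss`), which can
  go negative on held-out data, is carried alongside.
* **Discrimination**: per-channel two-group ANOVA F; spectral regions are
  half-open ([350, 700), [700, 1300), [1300, 1800), [1800, 2500]) so each
  boundary wavelength belongs to exactly one region. The classifier behind
  accuracy/κ is a two-class Fisher discriminant on the first three PC
  scores of each training fold (a deliberately simple, deterministic
  choice); the confusion matrix accumulates out-of-fold predictions.
  Cluster heatmaps use Ward linkage on Euclidean distances of Z-scores,
  on both the trait and the sample axis.

## Numerical choices and degenerate inputs

Zero-variance traits raise errors in Z-scoring, index mapping and metrics
(they make the statistics undefined). Channels with zero variance yield
NaN correlation loadings and infinite-F markers rather than silent zeros.
The truncated-normal calibration brackets its root searches adaptively
(the tilted-exponential regime needs the parent mean to scale like
σ²/distance-to-bound) and falls back to the closest attainable SD when
scipy's far-tail moments saturate. CSV output uses ≥ 10 significant
digits, making write→read round trips exact to 10⁻⁹.

## Problem sizes

Default test and acceptance runs use the study conditions directly
(n = 200, 431 channels, 70 time points); the parameter-recovery study
repeats them over five seeds. The full pipeline example uses a coarser
grid purely to keep the demonstration snappy; nothing in the methods
depends on grid resolution beyond the stated step.
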