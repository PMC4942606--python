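# Methods

## Scientific setting

`snomchemo` implements the computational analysis of two complementary
infrared measurements of exfoliated cervical cells:

1. **Near-field transmission images** (SNOM with a tunable IR source).  Each
   cell is scanned at four fixed biomarker wavelengths — lipids 5.71 μm
   (~1750 cm⁻¹), Amide I 6.06 μm (~1650 cm⁻¹), Amide II 6.46 μm
   (~1550 cm⁻¹) and DNA ν_as PO₂⁻ 8.16 μm (~1225 cm⁻¹) — producing one
   150×150 intensity matrix per (cell, wavelength) over a 400 μm scan.
2. **ATR-FTIR absorbance spectra** of bulk cell deposits on a
   900–3100 cm⁻¹ axis at 8 cm⁻¹ spacing, ten spectra per specimen.

Five cytological classes are compared throughout: normal, low-grade
dyskaryosis, high-grade dyskaryosis, a mixed squamous/glandular pre-invasive
lesion (CIN2 + HGCGIN) and adenocarcinoma stage 1B1.

## Image arm

**Reduction.** A transmission matrix X (rows = slow-scan lines) is collapsed
to a spectrum-like signal by the column mean, `s_j = (1/m) Σ_i x_ij`,
yielding one value per fast-scan position.  With a 150×150 matrix both
averaging directions are dimension-compatible; averaging over rows is the
reading consistent with a 1×150 row-vector output, and is what
`image_to_signal` does.

**Normalization.** The signal is mean-centred and then the absolute value is
taken, in that order.  The centred vector has exactly zero mean; the output
is non-negative, so integrated areas are non-negative.  Because the centring
removes any constant offset, the analysis is invariant to the background
transmission level and to the raw polarity of the signal (absorbing cell
darker or brighter than the background) — both are config switches in the
generator whose defaults (zero baseline, absorption-positive) are therefore
innocuous.

**Replicates.** Each (cell, biomarker) is measured in triplicate.  The
default reduction normalizes each replicate and then averages; the opposite
order (average, then normalize) is available via `average_first=True`.  For
noise-free signals the two orders coincide because the operations commute on
signals that share a common shape; on noisy data the default slightly
de-weights single-replicate baseline excursions.

**Areas and ΔA%.** The normalized signal is integrated by the trapezoidal
rule over a spatial interval covering the cell content; endpoints snap to
the pixel grid (snaps are logged).  Intervals can be supplied per class or
derived automatically as the smallest interval containing all points above
50% of the signal maximum, padded by 10% of the axis span.  The per-class
area change is `ΔA% = 100·(A − A_normal)/A_normal`; the normal class is the
reference and carries no ΔA% of its own.

**Per-biomarker PCA.** For each biomarker the five class-averaged normalized
signals form a 5×150 matrix analysed by PCA (2 components by default) with
Hotelling T² and Q-residual diagnostics.  With n = 5 samples the 95% limits
are only indicative; the code computes them but logs a small-sample caveat.

**Image enhancement** (`enhance_image`) reproduces the presentation-side
cleanup — per-row median alignment followed by removal of high radial
spatial frequencies in the 2-D Fourier domain — and marks its output
`presentation_only`.  It is deliberately excluded from the analysis path:
areas and PCA always consume raw data.  Two precise choices: the row-median
step adds back the median of the row medians so the overall level (and any
constant image) is preserved, and the cutoff is expressed as a fraction of
the maximal (corner) radial frequency so that `cutoff_fraction = 1` is
exactly the identity.

## Spectral arm

**Kennard–Stone split.** The classic maximin ordering: start from the two
most distant samples (squared Euclidean metric, raw intensities, no
scaling), then repeatedly add the sample with the largest minimum distance
to the selected set; ties break to the lowest index; duplicate rows only
trigger a logged warning.  The first `round(0.70 n)` samples in KS order
train the models, the next `round(0.15 n)` form the validation set and the
remainder the prediction set (train is rounded first, prediction absorbs the
remainder, so n = 20 splits 14/3/3 and n = 50 splits 35/8/7).  The split is
global, not stratified by class, matching the classic algorithm.

**PCA.** Mean-centred SVD.  Explained variance per component is
`100·σ_a²/Σσ²`.  Sign convention: the largest-magnitude element of each
loading column is made positive, so results are bit-reproducible.  T² for a
sample is `Σ_a t_a²/λ_a` with λ_a the training-score variance (ddof 1); Q is
the squared residual norm off the model plane.  The 95% T² limit is
`A(n−1)/(n−A)·F₀.₉₅(A, n−A)`; the Q limit uses the Jackson–Mudholkar
approximation from the residual eigenvalues (degenerating to ~0 for a
full-rank model, where Q ≡ 0).

**LDA.** Nearest class mean under the pooled within-class Mahalanobis
metric.  The pooled covariance uses divisor n − K; when its smallest
eigenvalue drops below 1e−10·trace/d a ridge of 1e−8·trace/d is added
(logged) — necessary in full-spectrum regimes (n ≈ 50, p ≈ 276) where the
pooled covariance is singular without compression or selection.  Prediction
ties resolve to the lowest class index and are logged.

**G cost.** Model selection on the validation set uses
`G = (1/N_v) Σ_n r²(x_n, m_own) / min_rival r²(x_n, m_rival)`: the mean
ratio of each validation sample's squared Mahalanobis distance to its own
class mean over its distance to the nearest rival mean.  G = 0 when every
validation sample sits at its class mean; a sample on a decision boundary
contributes 1.

**PCA-LDA** fits PCA on the training block for A = 1..max_A, an LDA on the
training scores, and picks the A minimizing validation G (ties → smallest
A; `criterion="accuracy"` implements the alternative of maximizing
validation accuracy).  The choice of criterion is genuinely open in this
design; G is the default because it is continuous in the scores and breaks
ties that 0/1 accuracy cannot.

**SPA-LDA.** From every viable starting variable a successive-projections
chain is grown: the next variable is the one whose (mean-centred) training
column has maximal norm after orthogonal projection onto the complement of
the selected columns — the collinearity-minimizing forward selection.
Every prefix of every chain is scored by validation G; the global minimizer
is selected (ties → fewer variables, then lexicographic).  Chain length is
capped at `min(p, n_train − K − 1)` so the LDA behind the cost stays well
posed.

## Synthetic data generator

The generator supplies ground-truth-known inputs shaped like the study's
measurements; it is the package's test bed, not a physical simulation.

**Images.** A cell is a filled ellipse (default radii 45×55 px centred in a
150×150 frame) with a cosine-tapered edge — a parametric stand-in chosen for
reproducibility; real cells are irregular.  The image is
`baseline + amplitude·effect(class, biomarker)·mask`, plus per-row offsets
(sd 0.005) emulating line noise and i.i.d. pixel noise (sd 0.01, tripled on
the lipid channel to reflect that channel's weaker source).  The effect
table's defaults are `1 + ΔA%/100` with the ΔA% pattern of the five classes
(e.g. amide I suppressed in squamous dyskaryosis, everything elevated in the
pre-invasive mixed lesion, DNA elevated everywhere), so a noise-free run of
the pipeline recovers both the signs and the magnitudes of the encoded
table; this is the round-trip the tests assert.  Not emulated: tip
artifacts, shear-force feedback, topography cross-talk, cell debris — so
passing tests demonstrate correctness of the computation, not robustness to
those instrumental effects.

**Spectra.** Gaussian bands (sd 16 cm⁻¹) at the ten diagnostic wavenumbers
1022, 1157, 1184, 1234, 1331, 1512, 1566, 1662, 2345 and 2939 cm⁻¹ on the
8 cm⁻¹ grid, a flat 0.05 a.u. baseline, and white noise of 0.005 a.u. — a
realistic noise floor for a 32-scan ATR accumulation.  Band shape is a
modelling choice (nothing in the analysis depends on it).  Per-class band
amplitudes are fixed once so that every class pair differs at three or more
bands by well over the noise, giving the strongly separated regime in which
both classifiers reach 100% prediction accuracy; `class_separation` scales
all amplitude differences towards the reference class, providing a
separability dial used by the tests (accuracy is non-decreasing in it).
Ten spectra per class mirror the ten sampling sites per specimen.

## Numerical choices and degenerate inputs

- Trapezoidal quadrature for areas (exact for piecewise-linear signals);
  interval endpoints snapped to the pixel grid, degenerate intervals
  rejected.
- Double normalization is a contract error, not a no-op.
- PCA component counts are validated against the rank bound min(n−1, p).
- All tie-breaks (KS selection, LDA prediction, model-size selection) are
  deterministic and documented above; every data-dependent decision taken at
  run time (interval snapping, ridge activation, ties) is logged at INFO.
- Problem sizes in the tests and the acceptance script are the generator's
  defaults: 60 images (5 classes × 4 biomarkers × 3 replicates), 50 spectra
  × 276 wavenumbers, 10,000 Monte-Carlo draws for the T² limit calibration.

## Known limitations

- The ΔA% magnitudes the pipeline recovers are exactly the encoded effect
  table only in the noise-free setting; with the default noise they
  fluctuate by a few percent.
- Kennard–Stone is unstratified; with very small or very unbalanced classes
  a class can be underrepresented in the training block, in which case LDA
  raises rather than silently degrading.
- The T²/Q limits assume approximately normal scores; the per-biomarker PCA
  on five class means is far below the asymptotic regime and its limits are
  indicative only.
- No spectral pre-processing (derivatives, SNV, baseline correction) is
  applied or provided: the spectral arm analyses raw absorbance by design.
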