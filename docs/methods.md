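# Methods

`aposematrix` implements an end-to-end analysis of warning-signal
diversity as seen by an avian predator: calibrated multispectral images
(or cone-catch tables) are turned into colour attributes, attribute
tables into cross-validated discriminant "uniqueness" scores,
cone-catch contrasts against natural backgrounds into mixed-model
conspicuousness tests, and species-level attributes into
phylogenetic-signal estimates.  Because the photographic data such
studies rest on are rarely deposited, the package ships a first-class
synthetic-data module that generates every input with known ground
truth; all tests and the acceptance script run against those known
truths.

## Visual model

**Cone catches.**  The quantum catch of receptor *i* for a surface with
reflectance R(λ) under illuminant I(λ) is the trapezoidal integral of
R·I·S_i divided by the integral of I·S_i (von Kries normalization), so
a perfect reflector has catch 1 in every channel.  The modelled viewer
is a blue-tit-like tetrachromat: single cones UV, SW, MW, LW plus the
double cone D for achromatic (luminance) vision.  Sensitivities are
unit-area Gaussians with peaks near published blue tit values
(372/449/503/563 nm, double cone 563 nm, broader); the shipped
constants file is a synthetic stand-in, and no result in the test suite
depends on the specific numbers.

**Receptor noise.**  Noise-to-signal ratios follow
ω_i = ν / √(η_i), with relative cone abundances η (0.37 : 0.70 :
0.99 : 1.00 for UV:SW:MW:LW) rescaled so the most abundant class has
η = 1 and therefore ω equal to the Weber fraction ν = 0.05.  The
printed form of this formula is ambiguous about normalization; the
convention used here (Weber fraction anchored to the most abundant
cone) is the dominant one for this model, and the alternative
(unrescaled abundances) is one configuration flag away.

**Discrimination distances.**  Chromatic distance ΔS between stimuli a
and b uses the log form of the receptor-noise-limited model:
Δf_i = ln(q_i^a / q_i^b), and the standard tetrachromatic closed form
whose numerator sums (ω_j ω_k)² (Δf_l − Δf_m)² over channel pairs and
whose denominator sums (ω_j ω_k ω_l)² over channel triples.  This
equals the quadratic form Δfᵀ A Δf with A = W − W𝟙𝟙ᵀW/(𝟙ᵀW𝟙),
W = diag(1/ω²) — inverse-noise weighting with the achromatic direction
projected out — and the test suite keeps that generic quadratic form
as an independent oracle.  Achromatic distance is |ln(a_D/b_D)|/ω_D.
ΔS values of roughly 1–3 JND are treated as indistinguishable; that
band is stored as a reporting constant only.

**Colour attributes.**  Catch proportions (UV, SW, MW, LW) are mapped
to a regular tetrahedron whose achromatic centre (equal proportions)
sits at the origin and whose vertices are at distance 0.75; saturation
is the Euclidean distance to the origin.  The orientation convention
(UV on +Z) is arbitrary and saturation does not depend on it.  Hue is
summarised by the two fixed channel-sum ratios H1 = (LW+MW)/(UV+SW)
and H2 = (UV+LW)/(MW+SW), computed on raw catches (both are invariant
to uniform scaling).  A PCA of standardized channel catches is
available as a diagnostic for the opponent-style structure these
ratios stand in for, but hue values always use the fixed ratios.
Internal pattern contrast is the achromatic JND between spot and
elytra.

## Image calibration

The camera model is a single gamma exponent per image: raw =
linear^(1/γ), inverted exactly by `linearize`.  Reflectance
normalization uses the in-frame grey standards: one standard gives a
per-channel scale, a pair (e.g. 8% and 95%) gives a per-channel affine
map through both points, which also removes additive offsets and is
exact on the standards themselves.  The camera-to-cone-catch mapping
is an ordinary-least-squares polynomial regression (degree 2 with
cross terms by default; degree is a config knob) fitted on a library
of training spectra for which both camera responses and true cone
catches are computed by integration.  Specular (glossy) pixels are
excluded by a luminance-percentile rule: pixels whose double-cone
value exceeds the region's 99th percentile (default) are dropped
before averaging — the goal (measure only non-specular areas) is from
the study design; the percentile operator is this package's choice.
Predicted catches are floored at 1e-6 so the log-form model stays
defined.

## Discriminant uniqueness

Nine attributes per specimen enter the analysis: elytra H1, elytra H2,
elytra saturation, spot luminance (double-cone catch), spot
saturation, spot hue (H1), internal contrast (log-transformed, as a
JND-scaled quantity), spot area as % of elytra, and body length.  The
exact composition of the nine is configurable; this default gives the
elytra two hue columns and the spot one.  Columns are z-scored
(classification is affine-invariant, so this only aids conditioning
and reporting).  Classification is linear discriminant analysis with
pooled within-class covariance and equal priors (each colour form is
an equally interesting class; frequency priors are a flag), evaluated
by leave-one-out cross-validation.  The LOO loop uses exact rank-one
downdates of the held-out class mean and pooled scatter, verified
against a naive refit (scikit-learn) in the tests.  Ties in the
discriminant score break by class-label order.  Per-class uniqueness
is the percentage of its individuals classified correctly.
Per-variable power is the one-way decomposition: η² = SSB/SST,
univariate Wilks' Λ = 1 − η², and F = (η²/(k−1))/((1−η²)/(N−k)).

A note on chance levels: jackknifed LDA at 16 classes × 20 individuals
× 9 features is not exactly at the nominal 1/16 accuracy under
exchangeable labels — it sits a fraction of a percentage point above
it (a finite-sample property of the procedure, reproduced with plain
Gaussian features and with scikit-learn's implementation).  The
calibration test therefore compares the zero-separation population
against the procedure's own permutation chance level rather than the
naive binomial band.

## Background contrast

Each specimen's elytra catch is contrasted against three backgrounds:
the mean catch of its own collection site's samples, the average green
and the average brown background (arithmetic means of the sample cone
catches, as in the study design).  Chromatic JNDs are not computed for
melanic specimens — very dark measurements are noise dominated — but
their achromatic contrasts are kept.  Log (natural) chromatic JND is
the response, floored at 1e-6.

The mixed models are fitted by REML with statsmodels: the species
model has species × background-type fixed effects and a random
intercept per individual; the habitat model has habitat-use ×
background-type fixed effects with random intercepts for species and
for individual nested in species.  Post hoc pairwise background
comparisons are computed as within-individual paired differences with
species-cluster-robust standard errors and t tests on clusters − 1
degrees of freedom, reported raw and Holm-adjusted.  This replaces the
original MCMC-based post hoc with a deterministic test that targets
the same contrasts; it was chosen over Wald contrasts from the
random-intercept fit because the within-individual covariance across
background types is not compound-symmetric (different background
directions project an individual's colour deviation differently), and
the paired cluster-robust test is calibrated under exactly that
structure.  Type-I error of the green-vs-brown contrast is verified to
sit in [0.03, 0.07] at α = 0.05 by simulation.

## Synthetic data

The generators define the study conditions:

* **Spectra** are logistic-transformed Gaussian-process draws
  (squared-exponential kernel, length scale 140 nm) on the 300–700 nm
  grid: smooth, broadband and strictly inside (0, 1) like physical
  reflectances.  They train the polynomial mapping and drive the image
  renderer.
* **Camera**: six unit-area Gaussian channels at 340, 380, 455, 520,
  585 and 650 nm, emulating a UV-converted DSLR photographed through
  UV-pass and UV/IR-block filters.  Six channels spanning 320–690 nm
  carry enough spectral information for the degree-2 mapping to
  predict cone catches to within ~1% on in-distribution spectra.
* **Rendered images** contain an elytra patch with an inset spot, one
  grey patch per standard and a dark backdrop; raw values pass through
  the same gamma model the calibration inverts, and a configurable
  fraction of body pixels (1% at 10× by default) is made specular so
  the exclusion rule is exercised.
* **Uniqueness-arm populations**: per-species attribute means drawn
  with spread `separation` × within-species SD around a common centre,
  individuals multivariate normal around their species mean (log-catch
  SD 0.08, body-length SD 0.06, spot-fraction logit SD 0.25); 16 colour
  forms × 20 individuals by default, 7/16 generalist, 2/16 flagged
  melanic.  With separation 0 all classes are identically distributed.
* **Contrast-arm studies**: species elytra colours are placed in
  log-catch space on the surface equidistant (in the receptor-noise
  metric) from the green and brown templates, at a species-specific
  distance around 25 JND (log-normal spread 0.15), so the
  green-vs-brown contrast is null by construction.  Individual and
  background-sample chromatic jitter is isotropic in the RNL metric
  (2 JND and 0.5 JND SD respectively) — Euclidean log-catch jitter
  would introduce a direction-dependent curvature bias of order 0.01
  log-JND into that null.  Background sample sets are calibrated so
  their arithmetic mean equals the class template exactly: the
  template is defined as the class's population-average catch, which
  is the quantity the analysis averages.  Each species' own-site
  background starts at its habitat template and is moved away from the
  species' elytra colour along the log-catch line joining them by an
  own-contrast factor: 1.0 for generalists (no tuning) and 1.65 for
  specialists, i.e. specialist own-background contrast is raised by
  ln 1.65 ≈ 0.5 natural-log units — a clearly detectable but moderate
  local adaptation.  Melanic species get dark elytra (catches near
  0.03).
* **Trees** are pure-birth (Yule) trees scaled to unit height, with
  terminal edges extended by one waiting time of the n-tip process so
  the covariance matrix is positive definite; traits are multivariate
  normal with covariance σ²C(λ), C(λ) scaling off-diagonal shared
  branch lengths by λ.

What the synthetic data does **not** emulate: real camera noise
models, vignetting and chromatic aberration, the actual arc-lamp
spectrum (a 6500 K Planck curve stands in), pigment-specific
reflectance shapes, non-ultrametric empirical trees, or realistic
between-leaf background variation (background within-class spread is
kept small so class averages are precise).  Passing tests therefore
demonstrate that the machinery is correct and calibrated under known
conditions, not that any particular empirical effect size would be
recovered from real photographs.

## Phylogenetic comparative statistics

Trees are consumed as Newick with branch lengths.  The phylogenetic
covariance C holds shared root-to-tip path lengths.  Pagel's λ scales
the off-diagonals of C; λ is estimated by bounded scalar ML on [0, 1]
(tolerance 1e-6) with μ and σ² profiled analytically through a
Cholesky factorization, and tested by likelihood ratio against λ = 0
(χ², 1 df).  On a star phylogeny C(λ) does not depend on λ and the
result is flagged non-identifiable.  Blomberg's K is the observed
MSE₀/MSE ratio (variance about the phylogenetically weighted mean over
the GLS error variance) divided by its Brownian-motion expectation
(tr C − n/(𝟙ᵀC⁻¹𝟙))/(n−1); its P-value is a one-tailed tip-permutation
test (999 permutations by default, +1 continuity, recorded seed).
Both estimators are cross-checked against R `phytools::phylosig` on a
fixture tree in the test suite.  PGLS is generalized least squares
with residual covariance C (statsmodels GLS), which reduces exactly to
OLS when C is the identity.  When both signal estimators are
nonsignificant for every attribute, the pipeline proceeds without
phylogenetic correction — the workflow branch the signal test exists
to support.

## Numerical choices and problem sizes

Catches are floored at 1e-6 before any logarithm; chromatic JNDs at
1e-6 before log-transforming.  Mixed models retry three optimizers
(L-BFGS, Powell, CG) and accept boundary solutions with near-zero
variance components; a fit is rejected only if estimates or standard
errors are non-finite.  Monte-Carlo checks use the replicate counts
they state (typically 200 replicates of paper-scale data: 16 × 20
specimens, 64-tip trees, 10 background samples per class); these sizes
give the estimator-recovery bands quoted in the tests while keeping a
full run of the suite and the acceptance script to a few minutes.

## Known limitations

* The polynomial mapping's accuracy is premised on test spectra coming
  from the same smooth family as the training library; sharp spectral
  features (interference colours, narrow-band pigments) would degrade
  it.
* The per-individual covariance structure across background types is
  modelled only through the paired post hoc tests; the REML fixed
  -effect table itself still assumes compound symmetry.
* Degrees of freedom for fixed-effect t statistics are large-sample
  (N − p); no Satterthwaite approximation is attempted.
* Blomberg's K permutation P-values are one-tailed against "more
  signal than permuted"; two-tailed alternatives are not offered.
* The habitat analysis treats habitat use as a two-level factor; real
  habitat breadth is continuous.
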