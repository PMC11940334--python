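# Methods

This note documents the models and numerical choices behind `hemigrad`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Pipeline model

**Quality control.** Subjects with mean framewise displacement > 0.35 mm or
any-frame FD > 3 mm are excluded before any computation.  The rule is a
strict inequality, so boundary values are retained.  Region-level exclusion
is deliberately unsupported: the homotopic asymmetry index needs complete
pairs, so QC acts at the subject level only.

**Connectivity.** FC is the Fisher z transform of the Pearson correlation
of regional time series.  The diagonal is set to 0 before any downstream
step (atanh(1) is undefined), and thresholding can never select it.  A
correlation of |r| = 1 off the diagonal is treated as a data error
(duplicated signal), not silently clipped.

**Hemispheric blocks.** With a homotopic parcellation of n regions per
hemisphere, the FC matrix splits into LL, RR (intra-hemispheric) and LR, RL
(inter-hemispheric) n×n blocks.  At construction RL = LRᵀ; they diverge
downstream because gradients are computed over each block's own row
profiles.  The profile of a scored region is its **row** in the block: LR
rows are left regions scored by their connectivity to right targets, RL
rows are right regions.  Each block therefore yields gradients for its
source hemisphere, which is what the pairwise AI requires.  (Whether the
inter-hemispheric affinity should be built over rows or columns is not
derivable from the procedure's usual description; the row convention is a
declared choice.)

**Gradients.** Per block: keep the top ceil(0.10 · n) entries of each
profile by signed value (ties at the cut boundary break toward the smallest
column index, making runs bit-reproducible; an all-equal profile keeps its
first ceil entries and warns); build the normalized-angle affinity
1 − arccos(cosine)/π, clipped to [−1, 1] before arccos; embed by diffusion
maps.  The embedding density-normalizes W with α = 0.5 (W_α = D^−α W D^−α),
forms the Markov operator P, and eigendecomposes the symmetric conjugate of
P with a dense deterministic solver (exact for the n ≤ 2000 regime this
package targets; no randomized methods).  The trivial unit eigenvalue is
discarded; a second unit eigenvalue (disconnected affinity graph) is an
error.  At diffusion time t = 0 component i is scaled by λᵢ/(1−λᵢ), the
convention of the widely used gradient toolboxes; literal λᵢ^t is available
via `diffusion_time > 0`.  Explained variance is reported as
λᵢ/Σλⱼ over the retained non-trivial eigenvalues (a λ²-based variant is
selectable), since no canonical definition exists for diffusion maps.

**Templates and alignment.** The intra template embeds the element-wise
mean of the reference subjects' LL and RR blocks; the inter template the
mean of LR and RL.  By default the reference set is the HC group.  Template
column signs are fixed by positive correlation with a reference vector
(first-half-regions indicator by default; the planted loadings for
synthetic studies) — individual gradients inherit orientation through
alignment, and the orientation cancels in group AI contrasts as long as it
is consistent.  Alignment is orthogonal Procrustes (R = UVᵀ from the SVD of
GᵀT; no centering or scaling), computed per block against the matching
template.

**Asymmetry.** AI is the raw left-minus-right difference of aligned
gradient scores, not a normalized laterality quotient: gradient scores can
be negative, making (L−R)/(L+R) ill-defined.  Only the first 3 gradients
flow into AI (configurable).  Network AI averages each hemisphere's scores
over the network's regions first, then differences — identical to averaging
pair AIs when the parcellation is homotopic, but stated in that order to
match the aggregation its users expect.

**Harmonization.** Parametric empirical-Bayes ComBat (location/scale model
with normal/inverse-gamma priors, method-of-moments hyperpriors, iterative
EB update to 1e−4 relative change, max 200 iterations).  The implementation
was verified against Bioconductor `sva::ComBat` on a fixed fixture
(agreement to ~1e−6, limited by the stopping rule).  Two protocols are
used: *pooled* (fit on the whole cohort with group, age, sex, mean FD in
the design) before group statistics, and *split* (fit separately within
training and test sets, never with group in the design) inside
cross-validated prediction.  For the split protocol the covariate design
defaults to age, sex and mean FD only; whether per-split harmonization
should carry covariates at all is an open choice, so it is configurable.
A single site yields an identity model with a warning; applying a model to
an unseen site is an error rather than a silent pass-through.  Note the EB
shrinkage leaves a residual site gap of order δ²/(n·τ² + δ²); site-removal
checks must be run at sample sizes where that residual is small.

**Group statistics.** Per feature, OLS of AI on {intercept, group (SZ = 1),
age, sex (M = 1), mean FD}; the group coefficient's t is reported with
two-sided p and BH-adjusted q (rejection at q ≤ 0.05).  Positive t means
higher AI in SZ.  FDR families: all 42 network tests (7 networks × 3
gradients × 2 types) form one family; region tests form one family per
(gradient, type).  The family definitions are declared in the outputs and
configurable, since the region-level family span is a genuine ambiguity.
Cohen's d maps are one-sample d = mean/SD within each group with BH across
regions within (gradient, type, group).  Demographic tests: 2×2 sex χ² with
Yates continuity correction (the correction is required to reproduce the
published χ² = 0.25; uncorrected gives 0.36) and pooled-variance Student's
t for age and motion, both also computable from printed summary statistics.

**Prediction.** Feature selection takes the union of significant network
and region AI features from the full-cohort analysis (as the original
procedure describes; this is optimistic, and a strictly nested selection
mode exists behind a flag).  Classification: L2 logistic regression,
C ∈ {10⁻³ … 10³} (7 log-spaced), stratified 4:1 splits, inner stratified
5-fold accuracy-scored grid search.  Regression: ridge,
α ∈ {10⁻² … 10⁴}, plain 4:1 splits, inner 4-fold MSE-scored search,
test-set Pearson r.  100 repeats by default; each repeat's streams derive
from (seed, repeat index).  Constant training features are dropped with a
logged note; class-deficient splits are re-drawn with a note.  Covariates
enter prediction only through harmonization, not as features.

## Synthetic-data generator

The generator produces what the pipeline consumes — parcellated time
series, phenotype and a homotopic parcellation — from an explicit latent
model, so recovery can be scored exactly.

**Latent geometry.** Each region carries a 3-vector of loadings; pairwise
covariance is `base + exp(−‖xᵢ − xⱼ‖²/ℓ²)` with base 0.1, ℓ = 0.8, plus
0.05 jitter on the diagonal (defaults chosen once so the matrix is
comfortably positive definite and embedding recovery is strong across
parcellation sizes).  The three axes are smooth orthogonal functions of
region index (linear, second harmonic, third harmonic) with SDs 1.0 /
0.75 / 0.5: smoothness is what makes the axes recoverable by diffusion
embedding even at 32 regions per hemisphere (template–loading correlations
≈ 0.99/0.99/0.97 there), and makes a network's embedded response to a
planted shift spatially coherent — quasi-random axis layouts were tested
and produce sign-incoherent network responses at small n.  Homotopic
partners share identical loadings, so HC asymmetry is exactly zero in
expectation (the generating law is invariant under hemisphere swap and the
pipeline is equivariant, so the AI distribution is symmetric about 0).

**Planted effects.** An effect (network, gradient, type, magnitude) shifts
the left-hemisphere loadings of the network's regions along the gradient
axis by magnitude × axis SD (positive = leftward).  The full covariance is
the kernel over one consistent latent point set per subject: a block-wise
construction with separate intra/inter point sets is not positive
semi-definite for nonzero shifts, so type-exclusive planting is impossible
under this covariance model.  Consequently a planted shift propagates to
both intra- and inter-hemispheric AI (and, through the nonlinear embedding
and shared Procrustes frame, partially into other networks and gradients);
the `kind` field records which AI family a recovery analysis targets.
Patients get a per-subject effect multiplier ~ N(1, 0.4) truncated at 0.1,
which creates the individual variation that symptom prediction exploits.

**Cohort.** Ages ~ N(36, 11) truncated to [18, 65]; sex ~ Bernoulli(0.33
female); mean FD lognormal around 0.15–0.16 mm (patients slightly higher)
so the 0.35 mm QC threshold excludes a few percent; max FD a random 3–10×
multiple of mean FD.  PANSS-positive is linear in the standardized effect
multiplier with noise set for R² ≈ 0.2 (test-set prediction r lands in the
0.1–0.6 band); PANSS-negative is pure noise and PANSS-general carries a
much weaker link, emulating symptom scales the planted asymmetry does not
drive.  Scores are integers clipped to the instrument's range, present only
for patients.

**Site effects.** On raw time series, site effects are affine (additive
location, multiplicative scale), following the ComBat generative model.
Because Pearson correlation is invariant to per-row affine maps, these
effects — faithfully — do not reach FC or AI; they exercise the I/O and
standardization paths.  The harmonization stage is therefore validated
against `simulate_site_features`, which plants location/scale site effects
and a group effect directly at the feature level under the same model
ComBat assumes, with groups balanced within sites.

**What the generator does not emulate.** Raw BOLD, hemodynamics, scanner
physics, spatial autocorrelation of noise, realistic within-group AI
variance (unknown for real data; planted magnitudes are chosen for
statistical power at n ≈ 100–200 per group, not realism), left-handedness,
or site effects that genuinely distort covariance.  Passing recovery tests
demonstrates the pipeline's correctness and sensitivity under this model,
not effect sizes in real cohorts.

**Determinism.** All randomness flows from one integer seed; per-subject
streams derive from (seed, CRC32(subject id)), so cohorts are reproducible
subject-by-subject and independent of generation order.

## Problem sizes in the test and acceptance suites

The property suites run at deliberately small scales chosen as package
defaults: null-symmetry checks use 200 cohorts of 40 subjects with 16
regions and 200 timepoints; planted-effect recovery uses 50 cohorts of
100 + 100 subjects with 64 regions and 300 timepoints; harmonization checks
use 2 × 80 subjects × 12 features with site-location SD 1.0 (placing the EB
shrinkage residual well under the 5% acceptance bound); prediction sanity
uses 400 subjects × 6 features at 20 repeats.  The acceptance script
mirrors these, with 100 null cohorts and 30 recovery cohorts.

## Known limitations

- Planted asymmetries are not type-exclusive (see above) and leak across
  networks/gradients through the embedding; recovery criteria therefore
  check the targeted features' sign and significance, not specificity.
- Pair-level AI magnitudes are in embedding units, proportional to — but
  not equal to — the planted loading shifts.
- Full-cohort feature selection before cross-validation is optimistic by
  construction; the nested mode is provided but not the default, to match
  the procedure being reimplemented.
- The EB ComBat variant is parametric only; longitudinal and GAM variants
  are out of scope.
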