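# Methods

`popcongruence` implements the analysis chain for population recordings made
while touch is either delivered to a participant (*actual*) or watched being
delivered to another person (*observed*), over a factorial stimulus design.
This note documents the models, the synthetic-data regime the package is
validated on, and the numerical choices made where the procedures were
genuinely open.

## Task structure and data model

Conditions are cells of a factorial design: person ∈ {actual, observed} ×
body part ∈ {cheek, shoulder} × touch type ∈ {pinch, press, rub, tap}. The
basic task (BSMT) uses rubs only (4 conditions, 6 sessions, ~126 units per
session); the multidimensional task (MSMT) crosses all three factors (16
conditions, 8 sessions, ~119 units). Both use 10 trials per condition and 3 s
of stimulation. A *sensory field* (format) is the (person, body part) pair:
Ac, As, Oc, Os.

Spike counts live in a `units × trials × bins` tensor at 10 ms resolution
(half-open bins, stimulus-onset-relative seconds), covering at least
[−1.5, +4.0] s so every published analysis window fits. The canonical
condition order — actual before observed, cheek before shoulder, touch types
alphabetical — fixes all matrix layouts. Sessions are independent tensors:
the array is re-sorted daily, so unit counts differ across days and no unit
identity is assumed across sessions.

Analysis windows: the **response** is the mean rate from 0.5 s after stimulus
onset to 0.5 s after offset ([0.5, 3.5] s for 3 s stimulation); the
**baseline** is the 1 s before onset. Windows are snapped *outward* to bin
edges, deterministically. Units enter analysis only if mean rate > 0.5 Hz and
SNR > 0.5; SNR is waveform-derived upstream and therefore carried as supplied
metadata, never recomputed from binned counts (the synthetic generator emits
it from a configured distribution).

## Per-neuron tuning

Each unit's baseline-subtracted response is regressed on condition
indicators, `FR = Σ_c β_c X_c + β_0` with a zero-intercept reference, so
`β_c` is the modulation from baseline in condition c. Significance is the
two-sided OLS t-test per coefficient with Benjamini–Hochberg FDR at q = 0.05.
Open choices, resolved as follows and exposed as parameters:

* the FDR family is the conditions *within* one unit (the responsive-fraction
  figure is per-condition per-unit); pooling across units is available by
  calling `fdr_correct` on a pooled p-vector;
* two-sided tests — suppression counts as modulation;
* responsive fractions are computed per session; the 95% CI is a seeded
  percentile bootstrap (1,000 resamples) across sessions.

Event-related averages use 750 ms windows stepped at 100 ms with window
starts from −0.5 to +2.5 s (31 starts).

## Population discriminability and similarity

The discriminability index between the stimulation-window population vector A
and the baseline vector B is the standardized difference
`DI = (Ā − B̄) / sqrt((σ_A² + σ_B²)/2)`. This univariate formula is the
default; a leave-one-trial-out, shrinkage-regularized multivariate
Mahalanobis variant (`crossval_mahalanobis_di`) is provided as a flagged
alternative, since figure-level descriptions of such distances are sometimes
multivariate while the printed formula is univariate. Neither is asserted as
"the" original computation; the formula is the only bit-exact specification
available.

Split-half correlation: per resample, each condition's trials are split
50/50 (⌈n/2⌉/⌊n/2⌋ for odd counts, alternating which half is larger),
per-condition population rate vectors are averaged within halves, and half-1
of condition i is Pearson-correlated with half-2 of condition j; 250
resamples by default, matrix symmetrized by averaging the two orientations.
The within-condition diagonal is the reliability ceiling of the similarity
measure. The matched/mismatched body-part comparison is a two-sample t-test
on session-level correlation values.

## Time-resolved decoding

The classifier is Gaussian LDA under two restrictions: one covariance shared
across classes, and a diagonal covariance (independent units). It is fit as
per-class means plus one pooled diagonal variance (MLE pooling), floored at
ε = 1e−6 Hz² so units silent in a window do not produce infinities. Equal
priors (the design is balanced); argmax ties break toward the first class in
sorted order. Accuracy is stratified leave-one-out CV within session, in
sliding 300 ms windows stepped at 10 ms starting 0.5 s before onset; all
units are included (no preselection of modulated units, avoiding peeking).
The end of the sliding range is not pinned down by the source description;
window starts default to −0.5 … +3.0 s (351 windows) and are configurable.

## Congruency models

A congruency model assigns each sensory field to "unresponsive" or to a class
of fields sharing one response profile, canonicalized by numbering classes in
field order Ac, As, Oc, Os. In binary mode (BSMT) all responsive fields share
one 0/1 coefficient: 2⁴ = 16 models *including* the all-unresponsive one. In
SP-sharing mode (MSMT) each class carries its own 4-vector selectivity
pattern over touch types: Σ_{k=1..4} C(4,k)·Bell(k) = 51 models, the
all-unresponsive assignment excluded. The asymmetry (16 includes the empty
model, 51 excludes it) is deliberate — those are the two printed counts.

**Fitting.** Rates are measured per trial over the analysis window and
referenced to the unit's *mean* baseline rate (mean over trials of the 1 s
pre-stimulus rate; per-trial subtraction would double the noise variance).
The design matrix has one indicator column per class (binary) or per
(class × touch type) (SP-sharing) and **no intercept**: after baseline
subtraction a trial in an unresponsive field predicts 0, which is exactly the
"coefficient collapses to a scalar" reading of the linear model. This also
keeps every candidate design full-column-rank on the balanced design — with
an intercept, any model covering all four fields would be rank-deficient
(touch-type indicators sum to the constant column).

**Selection.** `BIC = n·ln(RSS/n) + k·ln(n)` on the OLS residual (Gaussian
likelihood; RSS/n floored at 1e−12 for exact fits), minimized; and cvR² =
1 − SS_res/SS_tot on held-out folds of a seeded, condition-stratified 10-fold
split (SS_tot about the training-fold mean), maximized. The CV protocol is
not specified by the source; this one is recorded in config. Ties within
1e−9 break toward fewer parameters (a noiseless fit is achieved by every
supermodel of the truth; parsimony recovers the canonical representative),
and the event is observable in the per-model score table. BIC-best and
cvR²-best are reported separately and never merged. Zero-variance units are
flagged and assigned the non-responsive baseline category.

**Categories.** Binary models map to the four structural categories:
invariant (all fields one class), body-part specific (classes match within
cheek and within shoulder but not across — the mirror-like pattern), person
specific (match within actual and within observed), idiosyncratic (all other
patterns, including no modulation anywhere). SP-sharing models map to an
8-way structural taxonomy: the four above (with "unresponsive" counting as a
matching assignment), plus single-field, three-fields-one-class, other
two-class patterns, and non-responsive. The 8-way rules are this package's
own taxonomy, chosen to capture the same high-level modes a reader would
group by; they are deterministic and exhaustively tested, but not copied
from any published legend.

## Subspace generalization

Two analyses ask whether the population code is built from building blocks
that transfer across contexts.

**Demixed axes.** Within a training context (one level of a held-out
dimension), condition-mean responses per time window are decomposed exactly
into grand mean + factor-1 marginal + factor-2 marginal + interaction (the
balanced two-way decomposition; components are orthogonal and variance
fractions sum to 1). Per marginalization, an encoder/decoder pair is fit by
ridge-regularized low-rank regression of the marginalized matrix on the full
centered matrix — the standard demixed-PCA objective — with
(levels − 1) components per factor and up to 3 for the interaction
(results are "dPCA-style"; the original's exact hyperparameters are not
public). Generalization is the ratio of cross-validated squared level
separations in latent space, test context over training context. To keep the
ratio unbiased, axes are fit on half the training trials, the training
separation is measured on the other half, and every separation is a
split-half cross-product (two independent half-estimates of the level
difference multiplied), so noise-only separations average to ~0 rather than
inflating. A ratio is reported only when the training separation is reliably
positive (> 2 resampling SEs); otherwise it is undefined — e.g. the
interaction ratio on purely additive data.

**Axis transfer.** For a pair of conditions, a unit-norm discrimination axis
is learned as the difference of condition means whitened by the pooled
diagonal variance (the LDA direction under the diagonal-covariance
assumption; scale-invariant). The normalized generalization index is the
cross-validated squared distance between the *test* pair along the axis over
the same quantity for the *training* pair. Per resample the training trials
are split in thirds — one learns the axis, the other two give independent
mean-difference estimates whose product is an unbiased squared distance —
and the test trials are split in halves the axis never saw. Numerator and
denominator are averaged across 50 resamples before dividing; the 1-D
covariance scaling cancels in the ratio. If the test data literally coincide
with the training data the index is exactly 1. The index is declared
undefined when the training separation is not reliably positive (mean ≤ 0,
< 2 resampling SEs, or below twice the projected-noise floor
`σ̂₁²/n₁ + σ̂₂²/n₂`); undefined pairs are excluded with a log entry. Whether
the original normalization cross-validates both numerator and denominator is
unstated; both are cross-validated here to keep null data near 0.

## Synthetic data

The generator is the package's acceptance surface: it reproduces the two
tasks' trial structure with known per-unit ground truth. It does **not**
emulate correlated noise across units (beyond optional low-rank structure),
non-Poisson count dispersion, slow drift, or within-trial rate dynamics
beyond a step response — so passing tests demonstrate correctness of the
estimators under the stated noise model, not robustness to every property of
real recordings.

* **Congruency-model regime.** Each unit draws a model from a mixture,
  a baseline from U(1, 10) Hz, and per-class selectivity increments from
  U(2, 15) Hz per touch type. These magnitudes are plausibility choices
  (per-condition effect sizes for the real neurons are not published). The
  default mixture puts most mass on idiosyncratic/complex models with a
  minority of body-part-specific (mirror-like) congruent units, echoing the
  reported heterogeneity (12% mirror-like in the basic task, 3% in the
  multidimensional task) without asserting those exact values.
* **Compositional regime.** Mean rates are
  `baseline + g_p·(W_body + W_touch) + κ·W_int[person] + person-gain term`,
  with low-rank, column-centered factor loadings (SD 2 Hz by default) shared
  across persons, and interaction loadings drawn independently per person
  context and double-centered so they are pure interaction. The
  context-specific interaction is what makes "the interaction does not
  generalize" reproducible by construction; `observed_scale = 0` yields a
  person-specific control with no factor signal in the observed context.
* Responses step on at the ~60 ms sensory latency and are sustained through
  0.5 s after offset, so the mean rate over the standard analysis window is
  exactly baseline + increment. Counts are Poisson per 10 ms bin; a
  deterministic cumulative-rounding mode ("none") exists for exact-fit
  fixtures, and a Gaussian-rate-jitter mode for closed-form checks.
* A single seed fixes everything: the population seed fans out to per-session
  generators, and the pipeline seed fans out to per-stage child seeds via
  `SeedSequence([seed, stage_index])`, so reruns are bit-identical.

## Problem sizes used in the shipped checks

The test suite and acceptance checks run at desk scale by choice: recovery
uses one 120-unit session (10 trials/condition, 51-model sweep, vectorized
across units); generalization uses 80-unit, 4-session compositional
populations with 10–20 split resamples; the decoding demo uses a coarser
window step than the 10 ms production default. These sizes keep the full
suite under a minute of simulation while leaving every statistical margin
wide (e.g. BIC recovery ~98% against the 85% bar).

## Known limitations

* The 8-way MSMT category taxonomy is package-defined (see above).
* cvR² model recovery is markedly weaker than BIC at 10 trials/condition
  (ties among supermodels are broken by parsimony, but cvR² is noisy);
  both criteria are always reported side by side.
* `window_rate` snapping means windows not aligned to 10 ms bins are
  enlarged, never shrunk; rates are exact only for aligned windows.
* The univariate DI saturates when single-unit SDs are heterogeneous; the
  multivariate variant is provided but slower and shrinkage-dependent.
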