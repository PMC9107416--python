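# Methods

## The analysis model

The pipeline treats a two-arm pre/post resting-state study as a
group-discrimination problem. The signal of interest is the fractional
amplitude of low-frequency fluctuations: for a series x(t) sampled at
interval dt (default TR = 1.5 s, 320 volumes, first 10 discarded by the
reader as dummy scans), the one-sided amplitude spectrum is the square
root of the power spectrum, normalised so that the summed squared
amplitudes equal the signal energy (Parseval). Then

- ALFF = mean amplitude over the closed band 0.01 ≤ f ≤ 0.08 Hz,
- fALFF = (sum of band amplitudes) / (sum of amplitudes over all
  positive-frequency bins).

Two conventions are deliberate and configurable:

- **Ratio form.** "Band over whole spectrum" is implemented as
  sum-over-sum (the standard definition); a mean-over-mean switch
  (`ratio="mean"`) differs only by the constant bin-count factor
  n_all/n_band and therefore changes no z-scored result.
- **DC handling.** The zero-frequency bin encodes the signal mean, not a
  fluctuation, and is excluded from the denominator.

fALFF is scale-invariant (a ratio), ALFF scales linearly with signal
amplitude; both properties are asserted by tests. Maps are z-scored
within an analysis mask — whole-volume by default, a grey-matter mask
where white-matter contamination of sphere ROIs is a concern — and the
subject-level feature is the voxelwise difference post − pre of the
z-maps, averaged over each ROI.

ROI spheres include a voxel when its centre, mapped through the image
affine, lies within the radius (boundary ties included, Marsbar-like);
label-volume ROIs take voxels equal to the label id. The affine is the
single source of truth for geometry; MNI coordinates are RAS
millimetres.

## Classification and subset search

The classifier is a linear soft-margin SVM (scikit-learn `SVC`,
C = `c_reg`, default 1.0 — the value is not critical and is exposed in
every interface). Accuracy is estimated by leave-one-out
cross-validation; the treatment arm is the positive class for
sensitivity/specificity/DOR bookkeeping, and the diagnostic odds ratio
uses the Haldane 0.5 continuity correction when a confusion cell is
zero.

**Per-fold class weighting.** Every LOOCV training fold is one subject
short in the held-out subject's class. An unweighted C-SVM then tilts
toward the fold's majority class, and because the held-out subject always
belongs to the minority, the null accuracy of a permutation control
settles several points *below* the 50 % chance level (we measured
~45-47 % across feature scales). Per-fold inverse-frequency class
weights (`class_weight="balanced"`) restore the balanced-prior problem
and the null mean to 50 % — the calibration the control is supposed to
have. Because the weights change when a subject is removed, every fold
is refitted from scratch (no support-vector shortcuts).

Subset search is sequential floating forward selection with LOOCV
accuracy as the criterion: forward steps add the candidate with the
highest criterion (ties broken by catalog order); after each addition,
backward removals are accepted while they strictly improve on the best
accuracy previously recorded at the smaller size. The reported best
subset is the smallest subset attaining the highest accuracy. The
criterion is evaluated on the full dataset — *non-nested* by design: the
optimism this induces is exactly what the feature-selection control
measures, and collapsing it (e.g. by nesting) would remove the
phenomenon the pipeline exists to quantify.

## Permutation controls

Both controls relabel by flipping a random floor(n_g/2) members of each
group, which preserves label counts and prevents any permutation from
being a near-mirror of the original labelling (free shuffling is
available as an option). Each permutation draws from its own child
stream of the master seed, so results are independent of execution
order.

- *Traditional*: LOOCV of the fixed experimental subset per
  relabelling; null mean ≈ 50 %.
- *FSC*: the full SFFS + SVM + LOOCV search per relabelling; the best
  CA found enters the null. Its mean exceeds 50 % on pure noise, and
  overfitting is estimated as mean − 50.

P-values use the add-one estimator p = (1 + #{null ≥ exp}) / (n + 1),
ties counting against the experimental value. Effect sizes are
d_z = (experimental CA − null mean) / null SD. The sizing rule
n = ceil(4/W²) gives the permutations needed to resolve a CA difference
W; its domain is taken as 0 < W ≤ 1 so the degenerate W = 1 case is
well-defined (n = 4). Defaults are 10,000 traditional and 500 FSC
permutations; the desk-scale profile used in examples and tests reduces
these (1,000 / 100) while staying above the sizing rule's minimum for
W = 0.2. Summaries report the genuine standard deviation of the null CA
distribution for both controls. With a single permutation the SD is
reported as 0 with a warning.

## Behavioral regression

Rating differences (post − pre, VAS units) are regressed on the
selected ROIs' Δ-zfALFF, the treatment indicator (0 = sham,
1 = treatment) and ROI×treatment interactions, by bidirectional stepwise
OLS minimising AIC (BIC optional). Marginality is enforced — no visited
model contains an interaction without both main effects — but an
interaction may *enter* together with its missing main effects as one
composite move; without this, a data-generating model whose treatment
main effect is zero would make the interaction unreachable (the
treatment term alone never improves the criterion). Ratings are analysed
as raw VAS differences, unstandardised. The hemispheric asymmetry index
is the signed right − left difference (positive = right-dominant); an
absolute-value option exists but the signed form is the default since
the sign carries the interpretation.

## The synthetic cohort generator

Each subject-session-ROI series is a sum of `n_sinusoids` (default 8)
sinusoids with frequencies drawn uniformly in 0.01-0.08 Hz and random
phases, scaled to total band variance (amplitude parameter)², plus white
noise of SD `noise_sd` (default 1). Because fALFF is a spectral ratio,
a multiplicative in-band amplitude change maps monotonically to a fALFF
change, making injected effects analytically interpretable. The
treatment effect multiplies the band amplitude by `effect_size` in the
post session of treatment-arm subjects, only inside `effect_rois`.

Three variance components make the emulation honest rather than
degenerate:

- **Regional heterogeneity** (`roi_amplitude_range`, default 0.6-1.4×):
  per-ROI base amplitudes span a stable profile shared by all subjects.
  Without it, the across-ROI z-scoring denominator would be pure
  sampling noise and z-values would be amplified noise.
- **Between-subject/-session variability** (`subject_sd`, default 0.35,
  log-normal): each subject-session-ROI amplitude carries idiosyncratic
  jitter. In real resting-state cohorts this component dominates group
  effects (subject spread of Δ-zfALFF exceeds group median differences);
  without it a 2× effect saturates classification at 100 %.
- **A background z-scoring bank** (`n_background`, default 30, series
  mode only): voxelwise zfALFF is normalised over a whole-brain mask in
  which analysis ROIs are a negligible fraction. Z-scoring across only
  the analysis ROIs would redistribute an injected contrast into the
  non-effect ROIs (sum-zero coupling); the background bank reproduces
  the externally-anchored normalisation.

Ratings are generated directly on the difference scale,
diff = b₀ + b₁·x + b₂·treated·x + ε with x the subject's realised
Δ-zfALFF in a designated ROI (the analysis only uses differences);
per-session values are reconstructed around a baseline near mid-scale.
Volume mode writes small grids (e.g. 12-20 voxels per axis at 3 mm)
so sphere extraction is exercised at desk scale; the per-ROI series
mode skips the voxel grid for fast statistical testing.

What the generator does *not* model: hemodynamic response shape, head
motion, physiological noise, scanner drift, spatial autocorrelation
beyond ROI-level coherence, or non-Gaussian rating floors/ceilings.
Passing tests therefore demonstrate the statistical machinery —
calibrated nulls, selection optimism, parameter recovery — not
robustness to fMRI artifacts, which upstream preprocessing is assumed
to have handled.

## Problem sizes and numerical choices

Simulation-based tests and the calibration script run at desk scale,
chosen as the smallest sizes at which the tested property is stable:
null calibration uses the study-sized cohort (17/group, 8 ROIs) with
1,000 traditional permutations; the selection-optimism contrast uses 100
FSC permutations over 8 features; oracle-equivalence checks use ≤6
features where exhaustive enumeration is the reference; recovery checks
use 20 seeds. Master seeds spawn child streams (numpy `SeedSequence`)
for every stochastic component, so any run is bit-reproducible and
independent of subject ordering and permutation execution order.
Degenerate inputs fail loudly: empty ROIs name the ROI, NaNs name
subject and ROI, zero-variance masks, single-class folds and
rank-deficient designs raise with context.

## Known limitations

- The paper-style analysis is non-nested by construction; the FSC
  quantifies but does not remove selection optimism. A nested variant is
  intentionally out of scope.
- Sensitivity/specificity bookkeeping assumes the two-group, binary
  design; no multi-class support.
- Label-volume ROIs require user-supplied atlases; the bundled brainstem
  catalog approximates atlas nuclei as spheres and is marked synthetic.
- The FSC at large feature counts (e.g. >100 ROIs × 500 permutations) is
  computationally heavy; `max_subset_size` and reduced `n_perm_fsc`
  (with `required_permutations` as the lower bound) are the intended
  mitigations.
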