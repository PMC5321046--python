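# Methods

This note documents the models, the estimation machinery, the synthetic
cohorts used for validation, and the design choices made where the design
was genuinely open. It states no empirical numbers beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## The regression model

Each voxel's tissue probability (and, in a first stage, each subject's
global tissue volume) is modeled as

y = θ₀ + Σₘ θₘ Bₘ(X) + e,

with basis functions Bₘ that are products of at most two hinge functions
(x − t)₊ or (t − x)₊, and X the 4-column design matrix (age in months; sex,
male = 1; field strength, 3 T = 1; combined quality score in z-units).
Coefficients are estimated by least squares (minimum-norm on rank-deficient
bases). Binary predictors enter as plain linear terms: a hinge on a
two-level variable is affinely equivalent to a linear term, and knot-count
constraints are degenerate there.

### Forward pass

Reflected hinge pairs (and products with existing basis functions) are added
greedily by largest SSE reduction, scored exactly via a rank-2 Schur
complement of the normal equations (with a 1e-10-scaled ridge for numerical
safety; accepted models are always refit exactly). Candidate knots are
observed data values satisfying two subject-count constraints:

- `min_obs_to_edge` (default 10) observations strictly below and strictly
  above the knot;
- `min_obs_between_knots` (default 20) observations strictly between the
  candidate and every knot already placed on the same variable, ties counted
  with multiplicity.

Counting subjects rather than predictor distance keeps fits stable near the
sparse extremes of a cohort's age range. The pass stops at
`max_initial_funcs` (default 40 = 5 x the final cap) or when no admissible
candidate reduces the SSE beyond rounding (relative threshold 1e-9 against
both the response variance and the mean-square response, so constant voxels
yield intercept-only models). Ties break toward the lowest variable index,
then the smallest knot, then the earliest parent term — fits are
deterministic and voxel-order independent.

### Backward pass and GCV

One basis function is deleted at a time — the one whose removal least
increases the SSE, found in closed form from β²ⱼ/(G⁻¹)ⱼⱼ — and the best
model of each size is recorded. The returned model minimizes the
generalized cross-validation score

GCV = (SSE/n) / (1 − C/n)², C = M + 1 + penalty × (number of distinct knots),

subject to M ≤ `max_final_funcs` (default 8). SSEs at rounding level are
floored to 1e-12·Σy² before scoring so that exact fits prefer the smaller
model. The knot penalty is selected by 5-fold cross-validation of the full
fit on the global series over the grid {0, 1, 2, 3, 4, 5} (ties toward the
smallest value; folds are a deterministic permutation from `rng_seed`), and
the selected value is reused for every voxel fit of that class, in all four
options.

### Cubic mode

After pruning, each hinge can be replaced by a C¹ piecewise cubic with side
knots at the midpoints toward the neighbouring knots on the same variable
(or the training extremes); outside the side-knot interval the cubic equals
the linear hinge exactly. Coefficients are refit on the cubic basis. This
preserves smoothly varying age trajectories without changing the knot
structure.

## The four homogeneity options

Voxels within a tissue class are spatially dependent; fitting them
independently ignores that, while forcing one model on all voxels is too
rigid. Four options interpolate between the extremes:

1. **Scaled global pattern.** The pruned global-volume model defines one
   curve ĝ(X); each voxel fits only an intercept and gain, y ≈ a + b·ĝ(X).
   Two parameters per voxel, one shared shape.
2. **Frozen candidate basis.** The *unpruned* forward-pass basis of the
   global fit is frozen; per voxel, coefficients are refit and backward
   pruning is run. The selected subset must fit at least as well as option
   1's scaled-curve fit at that voxel (which remains the fallback), so
   per-voxel explained variance dominates option 1 exactly while pruning is
   otherwise unrestricted.
3. **Inherited constraints.** Free per-voxel forward+backward fits, but
   `max_final_funcs` is set to the pruned global model's basis count and
   `min_obs_between_knots` to the smallest observed inter-knot subject count
   of the global model (falling back to the configured default when the
   global model carries fewer than two knots on every variable).
4. **Independent fits** with the configured defaults.

Options 1–2 share one basis family (the unpruned global basis, with cubic
side knots computed from its full knot inventory); this is what makes the
option-1-vs-2 nesting exact rather than approximate in cubic mode. Voxels
with response variance below 1e-12 get intercept-only models. Only voxels
whose cohort-mean probability strictly exceeds 10% are fitted; out-of-mask
voxels carry the cohort-mean map so assembled priors stay smooth at mask
edges.

The option-1 semantics (scale the global curve rather than refit all its
coefficients per voxel) was a genuinely open design point. We chose the
scaled-curve reading because it is the only one that makes option 1
unambiguously the most conservative: refitting all ~8 global coefficients
freely at every voxel gives option 1 a *higher* per-voxel dimension than
the pruned options 2–4, which inverts the intended
conservative-to-liberal ordering of map homogeneity at realistic sample
sizes.

## Prior generation

A prior request lists demographic rows (age, sex, field strength), each
required to lie within the training range — the spline basis is not safe to
extrapolate. The quality covariate is always set to the best (maximum)
training value, so generated priors reflect the data at its cleanest. One
map per row is predicted and the rows are averaged ("matched pairs").
Assembly then clips to [0, 1], applies a 3×3×3 median filter per class
(replicate-padded; median filtering enforces local homogeneity without the
spatial blurring of a Gaussian), and repairs the probability simplex:
the residual 1 − Σ classes is added to the background class; where that
would drive background negative, background is set to zero and the other
five classes are rescaled proportionally. Filtering happens before the
repair so the repair is the last word on the simplex contract. Voxels where
all classes vanish become pure background (logged).

Covariate-difference overlays subtract priors generated at two settings of
one predictor and zero out differences of at most 5% probability, the
conventional display threshold.

## Quality metrics

- **Affine scaling**: |det| of the 3×3 block of the affine matrix.
- **Nonlinear volume change**: det(I + ∇u) of the displacement field u by
  central differences (one-sided at borders), which algebraically equals
  the total mapping's Jacobian determinant divided by the affine
  determinant — the affine contribution is removed exactly. Sum and mean of
  |det J| over a brain mask; a centered variant (|det J − 1|) is available.
- **Dissimilarity from the mean**: per subject, Σ|image − cohort mean| over
  all voxels (whole-volume sums; an optional mask argument exists).
- **Neighbourhood inhomogeneity**: for voxels above 10% probability, the
  mean absolute difference to their up-to-26 in-volume neighbours, averaged
  over qualifying voxels, in percent. Border neighbourhoods are truncated.
- **Baselines**: a voxelwise polynomial GLM (intercept, age, age², age³,
  sex, field, quality; age standardized before powering) and a centered
  moving-average curve over the n nearest-by-rank subjects.
- **Lilliefors normality**: KS statistic against a normal with estimated
  parameters; critical values from a seeded Monte-Carlo null (default 1000
  replicates) since parameter estimation invalidates the standard KS table.
- **Comparison protocol**: subgroups of 25/50/100 subjects are drawn
  repeatedly; their plain map average and the matched synthetic prior
  (generated from the subgroup's demographics) are each scored by
  sum-of-absolute-differences against the full population mean (the gold
  standard), yielding score distributions per group size. A
  shrinking-population variant removes random subjects in steps of 25 and
  re-scores matched priors of 25 random subjects against each shrinking
  population's mean.

## Phantom cohorts

The generator produces statistical, not anatomical, phantoms: a spherically
layered head (WM core, GM shell, CSF/bone/soft shells, background) with
smoothstep transitions of width 0.2 in normalized radius, emulating
partial-volume blur. Demographics: ages uniform on 13–900 months, sex and
field strength Bernoulli (46% male, 70% 3 T), resolution/CNR/INR drawn to
mimic multi-site heterogeneity; the combined quality score sets per-subject
noise σ = σ₀·exp(−0.15·q).

Age and sex effects move probability mass into GM from all other classes in
proportion to their local share (spatial weight 4·m_GM(1 − m_GM)); the
field-strength effect exchanges GM and WM mass at their interface (weight
4·m_GM·m_WM). Both conserve the per-voxel simplex exactly before noise;
Gaussian noise is then added independently per class and clipped to [0, 1],
leaving the kind of per-voxel inconsistency real segmentations exhibit and
prior assembly must repair. The GM age trajectory is a unit-peak gamma
pulse (a/τ)·e^(1−a/τ) whose peak age τ varies regionally
(τ = 120·(1 + 0.5·sin(2π·1.5·z)) months along one axis), reflecting that
regional maturation does not follow the global curve; defaults put the peak
near 10 years with a slow adult decline.

What the phantoms do *not* emulate: anatomy (no MNI-space structure),
registration error, spatially correlated noise, site batch effects beyond
field strength, or any quality effect on the *mean* signal (quality affects
noise only). Passing tests therefore demonstrate correctness of the
estimation and generation machinery under known ground truth, not
performance on real MRI data.

Deformation phantoms (identity, pure affine scale, sinusoidal displacement)
carry closed-form Jacobian determinants for validating the volume-change
metric.

## Validation scales and known limitations

The test suite runs phantoms of 8³–32³ voxels with 60–500 subjects — large
enough for the constraints (≥ 21 subjects) and for the statistical
properties under test, small enough for a complete run in minutes on one
core. The comparison protocol runs at 32³ with a population of 400 and 20
repeats; the option-ordering experiment uses ten seeded replicates of a
low-noise 8³/300-subject cohort, where estimation noise is small relative
to the structural differences between options.

At these scales the clearly resolvable homogeneity ordering is option 1
versus the rest: the scaled-global-curve option produces visibly more
homogeneous maps, while options 2–4 — all GCV-pruned approximations of the
same smooth truth — differ by less than the seed-to-seed variability of the
experiment. Distinguishing options 2, 3 and 4 by map homogeneity appears to
require cohort and voxel counts orders of magnitude beyond desk scale.
Mean explained variance, by contrast, orders the options cleanly at desk
scale, option 2 dominates option 1 voxel-by-voxel by construction, and the
spline fits explain more variance than the polynomial GLM baseline despite
the GLM's extra age terms.

Other limitations: no spatial regularization beyond the four options
(hierarchical or Markov-field coupling across voxels is out of scope);
priors cannot be generated outside the training range by design; model
containers are JSON (exact float round-trip, bit-reproducible predictions)
rather than a compact binary format, which is the right trade-off at
package scale but would be slow for 10⁶-voxel whole-brain grids.
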