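# Methods

This note documents the statistical procedures `scanmorph` implements,
the conventions chosen where several are defensible, what the synthetic
generator does and does not emulate, and known limitations.

## Superimposition

Configurations of *p* three-dimensional landmarks are superimposed by
generalized Procrustes analysis: each configuration is centered, scaled
to **unit centroid size** (the root of summed squared deviations from the
centroid), and rotated to the current consensus; the consensus is the
coordinate-wise mean, re-scaled to unit size, and the loop repeats until
it moves by less than `tol` (root-sum-square, default 1e-10) or
`max_iter` (default 100) is reached.  Rotations come from the SVD of the
3×3 cross-product matrix with the smallest singular direction
sign-corrected to det = +1; reflections are permitted only where
explicitly requested (the mirrored copies in the symmetry machinery).
The per-iteration objective (summed squared distance of all aligned
configurations to the consensus) is non-increasing, because each
rotation step and each unit-norm consensus update is the constrained
optimum; the implementation records the objective history so tests can
assert this.

After convergence the whole solution is rotated so the consensus lies on
its principal axes with a shape-determined sign convention.  This makes
the fit a pure function of shape: pre-rotating every input configuration
leaves aligned coordinates and tangent coordinates unchanged.

Shape variables are obtained by **orthogonal tangent projection**:
deviations of the flattened aligned configurations from the consensus,
with the component along the unit consensus direction removed.  The
stereographic alternative would differ in the fourth decimal for large
shape variation; orthogonal projection is the common choice and the one
implemented.

Scaling convention: all reported statistics (%Var, R², F, repeatability,
variance ratios, classification) are ratios and do not depend on the
unit-size convention.

## Sliding semilandmarks

Curve semilandmarks carry one degree of freedom, surface patch points
two, fixed landmarks none.  Tangent directions are estimated on the
**current consensus** (per-specimen frames are available behind a flag
but are noisier): a curve point's direction is the unit chord between
its two neighbours; a patch point's plane is spanned by the top-2
principal directions of its neighbour set centered on the point.  A
sliding step moves each sliding point by the projection of
(consensus − point) onto its allowed directions — the Procrustes-distance
criterion, which by construction cannot increase the distance to the
consensus — and alternates with re-superimposition for `n_cycles`
(default 3; convergence is rapid).  Bending-energy sliding is not
implemented.

Because only point data exist once digitization is done, a patch point's
"surface" is approximated by its 6 nearest non-fixed template points.
This is the closest point-set analogue of sliding on a mesh and is the
main approximation users should be aware of when transferring results to
mesh-based workflows.

## Object symmetry

A bilateral map partitions the points into left/right pairs and midline
points.  `mirror_relabel` negates one coordinate axis (default `x`, with
an autodetection option choosing the axis whose mirror image is closest
to the original) and swaps each pair's rows.  `decompose` runs a joint
GPA over the originals and their mirrored-relabeled copies — originals
restricted to proper rotations, mirrored copies allowed reflections —
and splits each specimen into a symmetric component (the mean of its two
aligned copies) and an asymmetric remainder.  The decomposition is exact
by construction (symmetric + asymmetric = aligned original), the mean
asymmetric component is the directional asymmetry, and its individual
variation the fluctuating asymmetry.  Because the canonical orientation
step may permute coordinate axes, the decomposition also reports the
fitted mirror-plane normal rather than assuming it is `x`.

## Procrustes ANOVA

Shape variation summed over all 3*p* tangent coordinates is decomposed
by sequential (Type I) sums of squares over an ordered factor list; each
term's SS is the squared norm of the projection of the data onto the
subspace its dummy columns add to the design.  Degrees of freedom are
the **standard linear-model ranks on specimen counts** (e.g. 18 / 19 /
76 for an individual + individual:device model on 114 observations).
Software that multiplies df by shape dimension exists; since %Var and R²
are df-free ratios, the choice does not affect the variance shares, and
the rank convention is reproducible and documented.  The decomposition
is exact: factor SS plus residual SS equals total SS to 1e-9 relative.

Significance comes from **residual randomization** (999 permutations by
default, seed mandatory): for each term, the reduced model containing
all prior terms is fitted, its residuals are permuted across
observations, and the term's F is recomputed; p = (b+1)/(n_perm+1) with
b the count of permuted F at least as large as the observed one (ties
counted with a 1e-9 relative tolerance so that exact-tie permutations
are not lost to float jitter).  The effect size Z is the standardized
position of log F in the permutation distribution of log F — a
convention, documented as such.  Type-I error of the test is calibrated
in the acceptance suite (200 null simulations × 499 permutations;
rejection rate within the exact binomial band around 0.05).

The object-symmetry ANOVA works on the doubled data (aligned originals
plus mirrored copies) with terms individual, side, individual×side, and
device-within-individual; the residual captures replicate digitization
error.  Per-factor percentages are 100 × SS / ΣSS.

## Error metrics

Repeatability is the intraclass-correlation analogue from one-factor
(individual) Procrustes ANOVA mean squares with *r* replicates per
individual: s²_A = (MS_among − MS_within)/r and R = s²_A/(s²_A +
MS_within).  The formula assumes balance, so unbalanced replicate counts
are rejected rather than silently approximated, and a non-positive
among-group excess yields a negative R that is **reported with a
warning, not clamped** — clamping would hide degenerate designs.  The
`repeatability` pipeline re-runs superimposition (and optionally
symmetric-component extraction) on the requested landmark subset (all /
fixed+curves / fixed only) before fitting the ANOVA.  By default the
plain (non-symmetrized) analysis is used for quantitative work because
the per-coordinate prediction σ²_ind/(σ²_ind + σ²_dig) applies to it
directly; symmetrization halves the effective noise at paired points
(the two mirrored copies average independent errors) and removes the
off-plane noise of midline points entirely, so symmetric-component
repeatability is systematically higher and is offered behind the
`symmetric` flag.

Procrustes variance of a replicate cell is the mean squared deviation
from the cell mean with **denominator n** (the trace of the cell
covariance over the number of observations), matching the definition
used in the morphological-disparity literature; an n−1 option exists and
is off by default.  Device-level values are unweighted means over the
device's individual cells (the design is balanced).  Devices are
compared by permuting device labels within individuals and recomputing
the absolute difference of device means.

## Between-group PCA classification

Between-group PCA takes the principal components of the *g* group mean
shapes with equal group weights, centers on the grand mean of the means,
and projects every specimen, yielding at most g−1 axes.  As a classifier
a specimen is assigned to the group whose mean is nearest in score space
(Euclidean; the score space has at most g−1 dimensions and sample sizes
are tiny, so a Mahalanobis metric would be poorly estimated).  The
leave-one-out loop refits the group means **and the axes** without the
held-out specimen (mean-only refitting is available via `refit_axes=False`;
axis refitting is the default since it is the stricter cross-validation).
Ties go deterministically to the lowest-indexed group with a logged
warning.  For device-wise dimorphism analysis, replicate triads are
averaged per individual and device first (`average_replicates`), while
the accompanying sex + device ANOVA uses all replicates.  Reports carry
the confusion matrix, row percentages, overall accuracy, and Cohen's
κ = (p_o − p_e)/(1 − p_e).

Null behaviour worth knowing: with tiny samples, leave-one-out
nearest-mean classification is slightly *below* the naive chance rate
(excluding the held-out point biases its own group mean away from it);
the acceptance suite checks the implementation against an independent
analytic reduction of this rule rather than against 50%.

## Synthetic data generator

The generator emulates a two-device repeated-digitization study.  The
template is a set of points on the upper half of an ellipsoid
(semi-axes 5 × 10 × 4 length units, so a roughly 20-unit-long
cranium-like surface) with exact mirror pairs about x = 0; midline and
lateral points are organized into ordered chains bracketed by fixed
landmarks, giving every curve semilandmark its slider neighbours, and
patch points are scattered on the surface.  Default counts reproduce the
study design: 19 individuals × 2 devices × 3 replicates = 114
configurations of 289 points (58 fixed / 145 curve / 86 patch).

Shape is built additively from:

| component | default | meaning |
|---|---|---|
| `sigma_individual` | 0.15 | per-coordinate sd of the symmetric individual effect (shared across devices/replicates) |
| `da_magnitude` | 0.08 | RMS of one antisymmetric field shared by all individuals (directional asymmetry) |
| `sigma_fa` | 0.03 | per-coordinate sd of each individual's antisymmetric field (fluctuating asymmetry) |
| `device_offset_scale` | 0.1 | RMS of a smooth symmetric polynomial field added to every device-2 configuration (systematic device error — a coherent shape shift, visible in ordinations, not white noise) |
| `sigma_digitization` | (0.04, 0.02) | per-device replicate noise sd; device 1 is the noisier, lower-resolution analogue |
| `sliding_noise_factor` | 0.6 | noise multiplier at semilandmark/patch points, emulating their (semi-)automated placement relative to manually placed fixed landmarks |
| nuisance | full rotations, translations up to one template diameter, scale in [0.5, 2] | removed by GPA |

All sds are in template length units.  Smooth fields have their
similarity-transform component (translations, infinitesimal rotations,
scaling) projected out before scaling, so their nominal RMS survives
superimposition instead of varying with the random polynomial
coefficients.  A sexed subset of individuals (7:4 female:male out of 11
for the default 19, scaled proportionally otherwise) optionally carries
a small symmetric dimorphism field (`sex_effect_scale`, default 0.02 —
deliberately subtle).

Exact effect draws are recorded in `SyntheticTruth` for
parameter-recovery tests.  `expected_repeatability` predicts the ICC as
σ²_ind/(σ²_ind + σ²_dig); the `midline_correction` option accounts for
the midline points' pinned x coordinate (symmetry forbids individual
variance there), which deflates the effective among-individual variance
by the fraction of constrained coordinates.

What the generator does **not** emulate: landmark-to-landmark error
covariance (noise is independent per coordinate; an optional smooth
correlated field would be a stress-test extension), scanner-specific
mesh artifacts (holes, smoothing), template-placement sliding inside
digitization software, and missing landmarks (rejected, not imputed —
imputation would contaminate error estimates).  Passing tests therefore
demonstrate correctness of the estimators under the additive Gaussian
design, not robustness to correlated or non-Gaussian digitization error.

## Numerical choices and problem sizes

* GPA tolerance 1e-10 (root-sum-square consensus change), max 100
  iterations; sliding 3 cycles.
* Permutation p-values use (b+1)/(n_perm+1) — never exactly zero — with
  tie counting at 1e-9 relative tolerance.
* Design-matrix ranks via SVD with a 1e-9 relative singular-value cutoff;
  a term adding no rank (confounded) or a saturated design (no residual
  df) is an error, not a silent NaN.
* Degenerate configurations (zero centroid size, coincident slider
  neighbours, empty groups, singleton replicate cells) raise errors
  naming the offending entity.
* Simulation-based tests and calibrations run on reduced problem sizes
  chosen once for statistical adequacy: templates of 50–149 points,
  8–19 individuals, 199–1999 permutations, 20 seeds for recovery means
  and 200 replicates for calibration rates; the full 289-point, 114-
  specimen default design is exercised end-to-end in the worked example
  and the pipeline tests.

## Known limitations

* Degrees of freedom follow specimen-count ranks; published tables that
  multiply df by shape dimensions will differ in df, F, and p (though
  not in SS or %Var).  Alignment conventions also differ slightly across
  morphometrics programs, so third-party tables are comparable at the
  level of variance shares, not test statistics.
* Percentages recomputed from *rounded* published sums of squares carry
  the rounding of those inputs (about ±0.1 percentage point at three
  significant figures).
* The tangent-plane estimate at patch points is a point-set
  approximation of the digitizing surface (see above).
* Repeatability assumes balanced replicates; there is no bootstrap
  confidence interval for R.
* Between-group PCA with many more variables than specimens can
  overstate group separation in-sample; the leave-one-out classifier is
  the guard against that and should be preferred over in-sample scores.
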