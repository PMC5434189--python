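# Methods

This note documents the statistical procedures the package implements, the
generative model behind the synthetic cohort, the defaults and why they were
chosen, and what the test suite does and does not establish.

## Task scoring

The gradCPT cross-fades scenes linearly over 800 ms, so trial *n* occupies
[(n−1)·800, n·800) ms and a press at RT r (measured from transition onset)
sees the current image at coherence clamp(r/800, 0, 1).  Presses are assigned
to trials by a deterministic global greedy rule: all (press, trial) pairs
with RT in the open window (0, 1600) ms are sorted by |RT − 800|, then by
earlier trial, then earlier press, and consumed greedily with each press and
trial used at most once.  The published task literature specifies the
assignment only as an "iterative algorithm" by citation; the rule here is a
documented stand-in chosen to be deterministic, invariant to input press
order, and consistent with the published worked RT examples (720 ms → 90%
coherence).  Changing the tie-break order can reassign presses only between
candidates at exactly equal |RT − 800|, which has measure zero for
continuous RTs.

Scoring conventions:

- RT mean and CV use correct-commission trials only; CV uses the sample SD
  (n−1 denominator) — the denominator is a convention, stated here because
  the source protocol does not fix it.
- HR = 1 − CE rate, FAR = OE rate; rates of exactly 0 or 1 are nudged by
  1/(2n) before Φ⁻¹ so d′ and criterion stay finite on synthetic extremes.
- Lapse runs are maximal streaks of consecutive omitted nontarget trials; a
  target trial breaks a run (withholding there is correct behavior), as does
  any trial that received a press.  Rare unassigned presses do not break
  runs; the definition is trial-based.
- Inclusion requires no pressless period of ≥ 30 s, i.e. at most 37
  consecutive pressless 800-ms trials.

## Connectivity and group maps

Residualization projects each series onto the orthogonal complement of
[1 | 6 motion | CSF | WM | global]; an intercept is always included.  No
temporal filtering or scrubbing is applied.  Seed maps report the seed's own
locations as missing rather than r = 1, and Fisher z clips |r| at 1 − 1e−7.

Group maps use a pooled-variance two-sample t (df = n − 2), or, with
covariates, the signed square root of the partial F for the group factor
from the per-location model [1 | group | covariates] — identical to the
group coefficient's t, positive when the positive group exceeds controls.
Subjects with missing covariates are dropped from covariate-adjusted maps
only.  The parametric map-level test is a deliberate convention even though
scalar behavioral comparisons use the nonparametric Mann-Whitney test.

## Cluster-extent inference

Smoothness is summarized by ACF(d) = a·exp(−d²/2b²) + (1−a)·exp(−d/c),
fitted by bounded least squares to the empirical lag correlation along the
three grid axes (lags 1..8 voxels, pooled over volumes) plus the exact
anchor ACF(0) = 1.  The effective FWHM is √2 times the ACF half-maximum
distance (the kernel-equivalent width), floored at one voxel size: a sampled
grid cannot resolve smoothness below its own resolution, and the floor makes
the white-noise case well defined.

Null fields are synthesized by frequency-domain filtering: the ACF kernel is
evaluated on wrap-around grid distances, its FFT (clipped at 0) is the power
spectrum, and white noise filtered by its square root has the target ACF.
Each iteration thresholds the unit-variance field two-sidedly at the nominal
per-voxel p, labels positive and negative exceedances separately under the
configured adjacency (face-only by default; edge and corner optional), and
records the maximum component size.  The minimum cluster extent is the
smallest k with P(max ≥ k) ≤ α.  Two-sided thresholding and the face-only
default mirror the reporting of both increased and decreased connectivity
clusters; published minimum sizes (e.g. ≥ 77 voxels at p = .01 on a
whole-brain grid) depend on that data's smoothness and grid and are not
comparable to the small synthetic grids used here — only the monotone
relationships (smoothness up → threshold up; stricter nominal p → threshold
down) are asserted.

In the pipeline the ACF is estimated from the group-residual z-maps — the
maps actually thresholded — rather than from single-subject time-series
noise.  Between-subject map variation includes a parcel-block component
(voxels in a parcel share the parcel's signal), so the map-level residuals
are the honest smoothness target; estimating the ACF there keeps the
familywise error of the null pipeline near α (verified by simulation in the
acceptance suite).

## LOSO decoding

Behavior regression: per fold the group map is recomputed on the n−1
training subjects and each reference cluster is redefined as the same-sign
suprathreshold component with maximal voxel overlap (falling back to the
reference mask when nothing overlaps).  Four features (2 seeds × 2 clusters,
mean z inside the mask) enter an OLS model fitted on training subjects; the
held-out subject's predicted score is recorded, and Pearson r between
predicted and observed scores across all subjects summarizes prediction.

Classification: features are ranked per fold by |pooled-variance t| on the
training rows (ties to the lower feature index; pooled variance floored at
1e−9 for degenerate features), and a Gaussian naive Bayes classifier
(empirical class priors, per-class ML variances floored at 1e−9, prediction
ties to the larger prior then class 0) is fitted on the top N.  The
accuracy/sensitivity/specificity curve is reported for N = 1..66 by default
(capped at the subject count); best N is the smallest N attaining maximal
accuracy.  The diagnostic odds ratio (TP·TN)/(FP·FN) receives the Haldane
+0.5 correction in every cell when any cell is zero.  The permutation p is
#{null ≥ observed}/n_perm without the +1 correction, matching the printed
28/1000 → .028 convention; p = 0 is therefore possible at finite n_perm.

A seed's correlation with its own parcel is undefined; that feature is
stored as a constant 0 so the 2 × 116 = 232 feature layout stays rectangular.
Constant features have zero between-group t and are never selected.

## Group statistics

Mann-Whitney U counts pairs with 0.5 credit per tie;
z = (U − nm/2 ∓ 0.5)/σ with the tie-corrected variance and a continuity
correction toward the null (the source protocol does not state whether its
z used the correction; the choice changes z by ≤ 0.5/σ).  When every value
is tied the variance is zero and z = 0 is returned with a degenerate flag.
The ANCOVA F for the binary group factor is the partial F of the full versus
group-free model on complete cases, computed through statsmodels OLS.

## Synthetic cohort: what it emulates and what it does not

Design constants follow the emulated study: 18 positive and 48 control
subjects; 248 volumes at TR = 2 s; 116 parcels with left/right amygdala
seeds; one 8-minute, 600-trial gradCPT run with 10% targets.  Covariates
(age, CAPS, DASS-d, mTBI count) are drawn from per-group normal laws
matching the published demographic means and SDs, with no built-in group
effect beyond sampled noise — they are controls, not signals.

Each subject's target correlation matrix starts from a compound background
(r = 0.1 everywhere, homotopic amygdala pair fixed at 0.4), sets the
amygdala–MFG and amygdala–PHG baselines to r = 0.2, adds the planted group
effects (+0.3 / −0.3 Fisher z, positive group only) and N(0, 0.04) subject
jitter on every seed-to-parcel z.  Positive definiteness is verified by
Cholesky and a violation names the offending subject.  Time series are
zero-mean multivariate normal with that correlation imposed through the
symmetric matrix square root — the simplest law consistent with a purely
correlation-based analysis — plus nine nuisance signals (six random-walk
motion drifts, three AR(1) physiological series) at amplitude 0.3 with
random parcel loadings.  Voxel grids replicate each parcel's series in its
label-map block and add spatially smoothed voxel noise; only the noise is
smoothed, so parcel-mean recovery is exact and the block signal is not
blurred across parcel boundaries.  The default voxel-noise amplitude (2.0
relative to unit parcel-signal SD) keeps the parcel-shared component of the
voxel-map sampling error small enough that the stationary-ACF null model
calibrates; the planted effects still dominate at the default group sizes.

Behavior couples to connectivity through the planted contrast
c = mean_z(seed, MFG) − mean_z(seed, PHG):
d′ = d′_base(group) + β_d·(c − c̄_group) + ε with β_d = −1.2 and
ε ~ N(0, 0.45), and CV analogously with β_cv = 0.057, SD 0.02.  The group
baselines derive from the group commission/omission rates by the
equal-variance signal-detection identity, and the subject's lapse
probability is the inverse of that identity at the subject's true d′ — so
scored d′ recovers the true d′ by construction.  β_d is the published group
d′ separation divided by the planted contrast separation (0.72/0.6); the
residual SDs are set so the d′–contrast correlation is decisively above 0.5
while keeping within-group d′ spread plausible (about 0.5, versus ≈ 0.85 in
the real cohort — a deliberate compromise, since the real spread includes
sources this generator does not model).  Lapses are modulated on the logit
scale by a stationary AR(1) attention state (coefficient 0.5 per trial),
and RT SD inflates as exp(0.25·state), producing temporally clustered
omissions and heavier CV in low-attention periods.  RTs are truncated to
(200, 1560) ms so every press falls inside the assignment window.

The paper-gap items: no quantitative connectivity effect sizes are published
(maps only), so the 0.3 z-unit default is a convention; covariate laws carry
no group signal; the generator produces post-preprocessing data by design
(no hemodynamics, motion artifacts, or atlas registration).  Passing tests
therefore demonstrate that the *procedures* are correct and calibrated on
data satisfying their assumptions — not that real fMRI data meet those
assumptions.

## Problem sizes used in the test and acceptance suites

Simulation-based checks run at sizes chosen to give decisive verdicts with
modest compute: planted-effect power uses 15 full-size cohorts (true power
under the defaults is ≈ 1, so reduced replicates do not change the verdict);
generator-level familywise-error calibration uses 25 cohorts of 9+9 subjects
on a 12×12×9 grid with 24 parcels and 300 threshold iterations; field-level
calibration uses 400 threshold iterations and 250 null fields on 16×16×12;
permutation-p uniformity uses 40 repeats of n_perm = 100 at n = 20 subjects
with 10 features.  Binomial-error bands in the assertions follow from those
counts.

## Known limitations

- The press-assignment rule is a documented reconstruction, not the
  original unpublished algorithm.
- The ACF null model assumes stationary spatial correlation; parcel-block
  synthetic data only approximates this (addressed by estimating the ACF on
  the thresholded maps, see above).
- The naive Bayes tie rules and the best-N convention (smallest N at
  maximal accuracy) matter only on exact ties.
- The generator's planted effects are strong relative to its subject noise
  (classification can saturate at 100% on default cohorts); monotonicity
  in effect size, not the absolute accuracy, is the tested property.
- Mann-Whitney uses the normal approximation throughout; exact small-sample
  p-values are only used as a test oracle.
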