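# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `aromapls`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Peak-table preprocessing

The pipeline consumes an aligned, gap-filled peak table: rows are GC-MS
injections (berry replicates plus blank runs), columns are volatile
features, entries are non-negative peak areas. Missing values are a hard
error — the table is expected to come out of alignment software already
complete.

Filtering applies two table-level rules, both expressed on the aligned
table because raw chromatograms are out of scope:

- **Detection height**: a feature is kept only if its maximum area over
  sample rows reaches `min_height` (default 2500 area units). This
  re-expresses a peak-picking minimum-height setting as a table filter.
- **Blank fold-change**: mean over sample rows must be at least
  `blank_fold` (default 10) times the mean over blank rows. A blank mean
  of exactly zero counts as an infinite ratio — absence in blanks is the
  strongest possible keep signal.

Filtering precedes TIC normalization. The order matters: blank
injections carry far less total signal than samples, so row-normalizing
them first inflates their relative values and scrambles the fold-change
ratios (the suite demonstrates both the equal-total case where the order
is immaterial and the realistic case where it is not).

TIC normalization divides each row by its own total (row sums become 1),
correcting extraction/injection throughput differences. Scaling
mean-centers each variable and, with Pareto scaling (default), divides
by the square root of its standard deviation — a compromise between no
scaling (large peaks dominate) and unit variance (noise features blow
up). No log transformation is applied. Standard deviations use the n−1
convention throughout the package. Constant variables cannot be scaled
and are dropped with a warning.

## OPLS engine

`fit_pls1` is a plain NIPALS PLS1: per component, weight w ∝ X'y (unit
norm), score t = Xw, loading p = X't/t't, inner coefficient
q = y't/t't, deflation of both blocks. For a single response no inner
iteration is needed, so each component is a closed-form step.

`fit_opls` uses the canonical orthogonal filtering: with w ∝ X'y, each
round computes p = X't/t't, strips the predictive part
w_orth = p − (w'p)w, extracts t_orth = X w_orth, and deflates X by
t_orth p_orth'. One predictive PLS component is then fitted on the
filtered matrix. Key invariants, all under test: every t_orth is
orthogonal to centered y; n_orth = 0 reproduces PLS1 exactly; training
R²Y is non-decreasing in n_orth; the collapsed coefficient vector b
reproduces the sequential filter-then-predict pipeline to 1e-10. If no
orthogonal variation remains, extraction stops early with a warning
rather than failing.

**Cross-validation** is stratified "venetian blind": within each class
(or over all samples, for unstratified use) a seeded permutation is
interleaved over `n_folds` folds (default 7, a conventional default in
chemometrics software; configurable). Each fold refits the model —
including re-centering with the training means — with the same component
structure. PRESS, Q² = 1 − PRESS/SS and the per-fold predictive weights
(sign-aligned to the full model, without which jack-knife pooling would
be meaningless) come out of the same pass. A fold whose training set
would lose an entire class level raises a stratification error.

**Orthogonal component count**: user-specified or automatic — add
components while Q² improves by at least 0.01 (cap 5 for regression, 3
inside the HDA tree). The auto rule is a data-driven surrogate for the
analyst's usual "add while cross-validation improves" practice; no
component count is ever hard-coded.

**CV-ANOVA**: F = ((SS − PRESS)/df_model)/(PRESS/df_resid) with
df_model = total components (predictive + orthogonal) and
df_resid = n − 1 − df_model; p from the upper tail of
F(df_model, df_resid). PRESS ≥ SS clamps F to 0 with p = 1. Commercial
implementations allocate degrees of freedom differently (the exact
scheme is proprietary), so F values are convention-dependent; the test
suite pins this package's convention with a hand-computed example.

**Permutation testing**: y is permuted `n_perm` times (default 200), the
model refit with identical structure and fold scheme, and
perm_p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1). The validity rule used
throughout — CV-ANOVA p < 0.05 and all permuted R² and Q² strictly below
the observed — matches standard chemometrics practice. One caveat,
visible in the tests: at a 10-vs-10 split with ~190 variables, a
one-component fit of a *permuted* response is nearly saturated, so its
*training* R² can occasionally exceed the observed R² even when the
permuted Q² distribution sits far below the observed Q². The R²
dominance part of the rule is therefore not guaranteed at small,
weakly-separated two-class splits; Q² dominance and CV-ANOVA are.

**Feature diagnostics**: VIPpred = √K·|w_pred| restricted to the
predictive component (mean squared VIP = 1 — this distinguishes it from
cumulative VIP over all components); p(corr) is the Pearson correlation
between the predictive score vector and the variable; jack-knife SE over
the G cross-validation folds uses SE² = ((G−1)/G)·Σ_g(b_g − b̄)² with a
t-quantile at G−1 degrees of freedom. Selection requires VIP and
|p(corr)| strictly above their thresholds plus a jack-knife interval
excluding zero. Zero-variance variables get an undefined p(corr) and are
flagged, never selected.

## OPLS-HDA

Distances between class groups are |Cohen's d| (pooled-sd standardized
mean difference; zero pooled sd with unequal means yields a signed
infinity sentinel) between the two groups' cross-validated OPLS-DA
predictions. Agglomeration merges the two closest current groups and
*recomputes* distances against the merged group with a fresh
group-vs-group model, rather than applying a linkage update — the
distance is then always "how separable are these two groups as they
stand". Class coding is left = −1, right = +1 regardless of group sizes,
with y centered.

Each internal node (k classes give exactly k−1) is refit as a
left-vs-right OPLS-DA with the auto component rule, feature diagnostics,
stringent selection (VIP > 1.5, |p(corr)| > 0.6, jack-knife pass) and —
when `n_perm > 0` — the full validation report. Node models re-center on
their own sample subset (a subset of a centered matrix is not centered);
the global Pareto scale is kept. Per-node seeds are derived from the
tree seed and the node index. Per-split permutation testing is off by
default (`n_perm = 0`) because the tree construction already runs ~25
cross-validated models; pass `n_perm=200` for fully validated splits.

The report for each split names the enriched side by the group means of
the variable itself; when the p(corr) sign disagrees (possible under
suppression), the row is flagged inconsistent but still reported by mean
direction. The dendrogram exports as Newick text with each child edge
carrying the parent's merge distance.

**Confusion matrix**: every sample is routed from the root; at each node
its cross-validated prediction (or, for a sample outside the node's
class set, the fitted model's prediction — the node model never saw such
samples, so no CV prediction exists) is compared with the two groups'
mean cross-validated predictions and the nearer side is taken. Using
group-mean proximity rather than the sign of ŷ keeps routing unbiased
when group sizes differ.

## Flavor regression

The response is the panel's mean flavor score per variety, replicated to
every berry of that variety (the alternative — averaging the matrix to
one row per class and leave-one-out CV — is available behind
`per_class_x`, but the replicated form is the default because it keeps
the replicate-level variance in the model). Because the response then
has only as many distinct values as classes, Q² is optimistic relative
to sample-level noise; the model warns whenever
distinct(y) < n/2. Contributors are selected at VIP > 1, |p(corr)| > 0.5
with jack-knife pass; the contribution sign is the sign of p(corr).

## Synthetic data

The generator is the package's ground-truth instrument; it emulates the
post-alignment data a study of this design produces, not the instrument
physics (no peak shapes, retention drift or spectra).

**Peak tables.** Areas are log-normal: each feature gets a log2 baseline
drawn uniformly in `baseline_mean ± 2` (default 2¹² to 2¹⁶ area units),
class effects add on the log2 scale, iid Gaussian replicate noise
(`noise_sd`, default 0.2 log2 units ≈ 15% CV) is added, and the result
is exponentiated — matching the strictly positive, right-skewed areas of
real GC-MS tables. Blank rows carry `blank_fraction` (default 2%) of
each feature's baseline, except for `n_background` designated background
features (default 10) which appear in blanks at sample level — so the
blank filter has genuine true positives and true negatives to find.

**Planted hierarchy.** `plant_hierarchy_markers` lays out marker blocks
along a class tree: a split at height h (leaves have height 0) gets
3 + 3h markers with log2 effect 2 + h, enriched in its left group, and a
coherent per-sample replicate factor on its marker set (log2 sd 0.15 at
the root, ×1.55 per level of depth). The coherent factor represents
individual berries varying in how strongly they express a volatile
signature — replicate variation in real tables is largely covariant, not
iid per feature. It is also what makes the hierarchy recoverable *as a
hierarchy*: cross-validated Cohen's d is separation over spread, and
with iid noise alone every planted split is perfectly separated, d
saturates, and the merge order degenerates to estimation noise. Ordered
effect-to-variability ratios are, in distance space, exactly what "this
tree is the ground truth" means.

**Flavor markers.** `plant_flavor_markers` gives each planted feature
per-class log2 effects proportional to the centered class flavor means
(sign-flipped for negative contributors), i.e. profiles collinear or
anti-collinear with the response.

**Sensory panels.** Latent scores per judge × variety are the variety ×
attribute mean (defaults: a 6 × 5 matrix on the 1–9 hedonic scale in
which one variety leads on flavor/taste/overall, another on color, and
taste attributes track overall acceptability while color does not), plus
a judge main effect (sd 0.8) and correlated attribute noise (sd 1.0,
correlation ≈ 0.6 within the visual and taste blocks, 0.3 across).
Scores are rounded, then clamped to 1–9 (rounding first preserves the
integer scale; clamping compresses the extremes slightly, as real
bounded scales do). Planted inconsistent judges use the scale in reverse
(score ↦ 10 − score) after rounding. Ground truth (marker layout,
background set, outlier judges) is returned beside the data, never
embedded in it.

What the generator does *not* emulate: retention-time alignment errors,
detector saturation, batch drift, judge fatigue or order effects,
non-reversal forms of judge inconsistency. Passing tests demonstrate
that the algorithms recover what was planted under this data model; they
do not certify performance on real tables with those artifacts.

## Judge screening

The published practice this package operationalizes is visual
inspection of PCA score plots. The surrogate is Hotelling T² of each
judge on the first 2 PCA components of the column-centered judge ×
(variety·attribute) score matrix, with the F-based 95% cutoff
T²_crit = A(n−1)/(n−A)·F₀.₉₅(A, n−A). Removal is *sequential*: the most
extreme judge above the cutoff is removed and the PCA recomputed until
no judge exceeds it. The one-pass variant suffers masking — a cluster of
reversed-scale judges inflates the component variances enough to shield
its own members (sensitivity ≈ 0.69 at 5 planted outliers in 55 judges,
vs ≈ 0.98 sequentially). Sequential deletion is the standard remedy and
mirrors what an analyst iterating on score plots actually does. The
number of components (2) and α (0.05) are conventions, configurable.

Tukey fences use linearly interpolated quartiles (the common
spreadsheet/statistics default; fences are convention-sensitive, so the
convention is fixed and tested), k = 1.5, applied within each variety ×
attribute cell after judge removal — the two-step order (global judges
first, then attribute-level scores) is fixed.

A leave-one-variety-out robustness report recomputes variety-level
Spearman correlations dropping each variety in turn and flags sign
flips.

## Problem sizes and determinism

Recovery rates in the acceptance script use 50 replicate simulations of
the full study design (60 samples × 200 features; 55 judges × 30
products·attributes) — enough for rate estimates with ~4% standard
error while keeping a full run under a couple of minutes. Null
calibrations use 100 permutation-test runs at n = 30 and 200 null panels
at 20 judges. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical tables,
panels, folds and permutations.

## Known limitations

- Single-response models only (no PLS2/O2PLS); no S-plots or score-plot
  ellipses beyond the screening T².
- CV-ANOVA degrees of freedom and the jack-knife variant follow the
  conventions stated above; numbers from software using different
  allocations will differ in F though rarely in conclusion.
- The HDA distance uses one distance metric (cv-prediction Cohen's d)
  and binary splits only.
- Q² on class-replicated responses is optimistic (warned, documented
  above); treat it as a class-level, not berry-level, predictivity.
- The IQR filter assumes enough scores per variety × attribute cell for
  quartiles to be meaningful (degenerate cells pass through unchanged).
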