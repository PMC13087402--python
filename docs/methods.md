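# Methods

This note records the statistical procedures qsarkit implements, the
parameter choices that matter, and the places where the design was
genuinely open.

## Assay reduction

Percent inhibition is `(1 − Abs_sample/Abs_control) × 100`. Negative values
(sample absorbance above the control, a pro-oxidant reading) are returned
as measured with a flag, never clipped, so downstream models see the data.

IC50 is reduced from a two-fold dilution series by linear interpolation of
response against log₂(concentration) between the lowest concentration whose
response reaches 50% and the next dilution below it. The log₂ axis is a
design choice, not a measured fact about any particular plate reader
workflow: on a two-fold grid it is the natural coordinate, it is exact when
a response hits 50% on the grid, and for a hyperbolic saturation curve the
interpolation error stays within one dilution step (≤ ~10% relative; the
synthetic-assay tests measure this). Series whose maximum response stays
below 50% yield an *undetermined* IC50 — mirroring how such panels are
reported — and series that start above 50% yield the lowest concentration
as a censored "≤" bound.

pIC50 = −log₁₀(IC50 in molar) = 6 − log₁₀(IC50 in µM). MIC conversion is
`µg/ml ÷ MW × 1000 = µM`. Censored "≤" MIC values keep their censor flag
through storage and conversion. A compound is classed *active* iff it has
at least one MIC record.

## Feature selection

Constant and exact-duplicate descriptor columns are dropped first (keeping
the first occurrence).

**Stepwise MLR** uses classical forward entry / backward elimination on
partial-F p-values with α_enter = 0.05 and α_remove = 0.10 — the classical
defaults, chosen because the method is standard but its thresholds are
rarely reported alongside it. Candidates that would make the design
collinear are skipped with a logged reason; when the current model already
fits exactly (zero residual within a scale-aware tolerance) no further
candidate can enter, since a variable that explains nothing additional has
no evidence in its favor. Ties break by column order. Every decision is
recorded in a replayable trace.

**CFS/best-first** scores a subset S of k features by
`merit(S) = k·mean|r_cf| / sqrt(k + k(k−1)·mean|r_ff|)` (feature–class
correlation rewarded, feature–feature redundancy penalized) and searches
forward best-first, stopping after 5 consecutive non-improving expansions
(the cited tool's convention). The search is deterministic: the frontier is
ordered by merit with subset-index tie-breaks.

The UFS variable-selection method is named in the literature this toolkit
accompanies but published without formulas; it is not implemented and is
rejected as an unsupported method name.

Selected descriptors are checked pairwise with Pearson r; independence
passes iff every |r| ≤ 0.9. Zero-variance columns make r undefined and are
reported as errors rather than silently passed.

## Regression and validation

OLS always includes the intercept; the solver is QR-based
(`numpy.linalg.lstsq`) with an explicit rank check and a condition-number
guard (> 1e10 is an error). Rank deficiency is an error naming the
dependent columns — a reported QSAR equation must be unique, so nothing is
silently pseudo-inverted.

Q² is PRESS-based: `Q² = 1 − PRESS/SStot` with SStot about the full-sample
mean. Leave-one-out predictions use the exact hat-matrix identity
`e_(i) = e_i/(1 − h_i)`; the tests verify it equals n explicit refits to
1e−10. k-fold Q² (k = 5 by default) uses a seeded uniform random partition
into near-equal folds — unstratified, since the response is continuous —
with PRESS pooled across folds rather than averaging per-fold Q²; the fold
assignment is stored in the report for replay. k = n reduces exactly to
leave-one-out.

CCC follows Lin's sample concordance correlation,
`2·cov(y,ŷ) / (var(y) + var(ŷ) + (ȳ − ŷ̄)²)`, with population (1/n)
moments. At n ≈ 10 the 1/n-vs-1/(n−1) choice is visible, which is why it is
fixed and documented.

Y-randomization permutes the response with a seeded generator, refits, and
records R² and Q² per repetition (10 by default); the control passes iff
the original model beats every shuffle on both statistics.

Acceptability thresholds are stored as named constants: R² > 0.6,
Q² > 0.5, MAE < 0.6, CCC > 0.85.

## Applicability domain

Leverages are the hat-matrix diagonal of the intercept-augmented design
(trace identity Σh_i = p+1, tested to 1e−10). The critical leverage is
h\* = 3(p+1)/n — the standard Williams-plot cutoff, and the form consistent
with the reported thresholds this toolkit reproduces (1.36 at p=4, n=11;
1.50 at p=4, n=10). Residuals are standardized by the sample (n−1) standard
deviation of the raw residuals by default; an internally studentized
variant (dividing additionally by √(1−h_i)) is available, since published
applicability-domain analyses rarely state which was used. A compound is in
domain iff h_i < h\* and |standardized residual| ≤ 3.

Note h\* > 1 whenever n < 3(p+1): at the panel sizes above, no compound can
exceed the leverage cutoff, so the ±3σ band is the binding constraint —
this is a property of the published threshold form, not a bug.

## Tree classification

Induction is C4.5-style on continuous descriptors: candidate thresholds are
midpoints between consecutive distinct sorted values; the split maximizing
information gain ratio (with positive gain, both children ≥ min_leaf) is
chosen; ties break by column order, then lower threshold. Routing sends
value ≤ threshold left. Recursion stops at purity, min_leaf (default 2, the
J48 convention; the worked examples use 1 where exact rule recovery is the
point), or no admissible positive-gain split. Trees are unpruned by
default — the published two-level tree this mirrors is structurally
unpruned — with no pruning implemented beyond the stopping rules.

Metrics: accuracy = 100·(tp+tn)/n with *active* as positive class;
precision/recall/F1 are computed per class and combined by class-support
weights, because that averaging reproduces the published worked-example
values exactly (weighted recall ≡ accuracy/100 is an algebraic identity the
tests enforce); macro averaging is available behind a flag. A class never
predicted has precision 0 plus an `undefined_precision` flag.

Classification cross-validation re-induces a tree per fold and pools
out-of-fold predictions; k-fold assignment is stratified by class (the
panels are imbalanced, e.g. 7:4) and seeded. A training fold with a single
class legitimately yields a single-leaf tree.

## Synthetic data

The generators define the study conditions the tests run under:

- `gen_regression` — default 11 compounds × 40 descriptors with 4
  informative ones carrying the published DPPH-equation coefficients as the
  planted truth, noise_sd 0 (the regime's training R² ≈ 0.999 implies
  near-noiseless responses at this scale), and a nuisance block with
  pairwise correlation 0.85 plus one Bernoulli column (mimicking binary
  atom-pair descriptors) so the |r| ≤ 0.9 independence check and the
  redundancy penalties are exercised meaningfully.
- `gen_classification` — the two-level rule with the published cutoffs
  (7.564, 11.729) as defaults, 7:4 class balance at n = 11, and a margin
  (default 0.5) kept from *both* thresholds in *both* split coordinates, so
  that "margin-separated" guarantees apply to any axis-aligned tree the
  inducer might grow, not just the canonical one.
- `gen_assay` — two-fold dilutions from a top concentration of 300 (the
  panel's test concentration) through a hyperbolic curve crossing 50% at
  the true IC50.

Every generator is a pure function of scenario + seed. What the synthetic
data does **not** emulate: the marginal distributions of real
Dragon/PaDEL/Mold² descriptor families, inter-assay variance structure, or
any chemistry. Passing tests therefore demonstrate the statistical
machinery is correct under the stated structure, not that any particular
real panel would yield these statistics.

## Problem sizes

The test suite and acceptance script run at the study's native scale
(n ≈ 11–40 compounds, up to 40 descriptors, ≤ 200 simulation replicates):
these are the sizes the small-n QSAR regime itself prescribes, and the
whole suite completes in seconds.

## Known limitations and open points

- The published descriptor matrices behind the two regression equations are
  supplementary-only; the equations are carried verbatim as fixtures and
  their printed training statistics are not refit targets.
- One source writes the Mold² connectivity descriptor of the SOD model as
  "D21" in passing; the toolkit standardizes on "D211" (the form used in
  the descriptor-definition and equation tables). Similarly "B08[C-O]"
  (ASCII hyphen) aliases to "B08[C–O]".
- Candidate-to-prototype mapping for screening is user-supplied input; the
  toolkit does not enumerate or generate candidate structures.
- No bootstrap validation or external test sets; no 4PL dose–response
  fitting; no regularized or robust regression; no multiway tree splits or
  missing-value routing.
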