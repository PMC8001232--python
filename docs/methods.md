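# Methods

## The score and its assumptions

The risk score treats each clinical variable independently: a value inside
its healthy reference interval contributes nothing; a value outside it
contributes its relative distance from the violated boundary, in percent of
that boundary. This presumes every healthy lower bound that can be violated
is strictly positive (the schema loader rejects a zero boundary with a lower
unhealthy flank), and that deviation severity is comparable across analytes
once expressed relative to the boundary. Qualitative variables have no
magnitude; they contribute 0 or 100, the only convention consistent with
their Boolean labelling.

The weighted average of deviations is normalized by the score of a fictive
worst-case patient (every variable at the extreme with the larger relative
deviation, every qualitative variable non-benign), which pins the score to
[0, 100] by construction. The decision threshold is 50%; a record at exactly
50% is labelled negative, since only scores *above* the threshold indicate
disease. Boundaries of the healthy interval itself are inclusive (a value at
the bound is healthy).

### Weights

All three weight schemes are constructive recipes with unit-sum output:

- **convergent** — uniform 1/45 by default; per-variable overrides must lie
  in [0.015, 0.05] and are rescaled to unit sum. Expresses "every variable
  matters about equally".
- **deflection** — raw weight = mean of the two relative flank widths
  (lo−elo)/lo and (ehi−hi)/hi; qualitative variables get raw weight 1 (their
  deviation spans the full 0–100 range). Expresses "variables with wider
  pathological ranges matter more", but lets a few analytes with enormous
  flanks (transaminases, bilirubin) dominate.
- **combined** — deflection raws mapped affinely onto [0.01, 0.03]
  (degenerate all-equal case: band midpoint 0.02), then rescaled. Keeps the
  deflection ordering while bounding any single variable's influence; this
  is the default scheme for the pipeline.

The per-variable healthy intervals and extremes shipped in
`default_schema.yaml` are standard adult reference intervals with plausible
physiological extremes. They are *parameters of the method*, not estimates:
any laboratory can substitute its own schema file, and all published-figure
checks in the test suite are independent of these defaults.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: 200 base
patients augmented to 900 records, 45 columns, and roughly 64.9% of records
scoring above the 50% threshold (the prevalence implied by back-solving the
benchmark confusion matrices: 584 positives of 900, consistent across all
three pooled cross-validation rows).

Records come from a two-component mixture:

- a **case-like** component (exact allocation: round(0.649·200) of the base
  records, shuffled) with mean out-of-range burden 0.95, out-of-range values
  drawn with exponentially decaying mass *from the extreme inward* (truncated
  exponential, scale 0.1, mirrored) and the larger-deviation side chosen with
  probability 0.97;
- a **healthy-leaning** component with mean burden 0.075, mild out-of-range
  values decaying *from the violated boundary outward* (scale 0.15) and no
  side preference.

Per-record burdens are Beta-distributed around the component mean
(concentration 60); in-range values follow a truncated normal over the
healthy interval (sd = width/6); qualitative values are non-benign with
probability equal to the record's burden. Setting `abnormality_burden`
explicitly switches to a homogeneous cohort with that burden for every
record, which yields the degenerate checks (burden 0 → everything in range;
burden 1 with flank scale 0 → everything at an extreme).

The severity profile of the case component was calibrated once, by design,
so that case records clear the 50% threshold under all three weighting
schemes: because a handful of wide-flank analytes dominate the normalization
denominator, a per-record score has high variance, and a case component with
mean score near the threshold would produce an unstable prevalence. A purely
boundary-decaying out-of-range law caps the mean flank position at 0.5 and
cannot reach the target prevalence at any burden, which is why the case
component's law decays from the extreme instead.

Augmentation resamples base records with replacement and adds zero-mean
Gaussian jitter with sd = 2% of the healthy-range width per numeric variable
(clipped to the extremes); qualitative values are copied. This is the
simplest classical tabular augmentation and approximately preserves each
record's label.

**What the generator does not emulate:** analyte–analyte correlation,
realistic marginal shapes of pathological values, measurement error
structure, or any real joint distribution of disease presentation. Because
the binary response is a deterministic threshold of a function of the same
variables the classifiers see, synthetic benchmark accuracies are close to
100% and say nothing about clinical performance; the benches demonstrate the
*machinery* (pooling, metric arithmetic, seeding), not attainable accuracy.

## Classification bench

Roster: logistic regression, linear discriminant, decision tree, bagged
trees (30 trees), Gaussian-kernel SVM (kernel scale √45, i.e. rbf
γ = 1/45 — the "medium Gaussian" convention at 45 features), and 10-nearest
neighbours, all via scikit-learn, plus an always-reported majority-class
baseline. Inputs are the Boolean labels; the response is the thresholded
score.

K-fold metrics pool the out-of-fold predictions of all k folds into a single
confusion matrix (pooling, not fold-averaging, is what reproduces integer
false-negative counts on a 900-record dataset); the %FN denominator is the
whole dataset for k-fold and the held-out set for holdout, matching the
published convention. Holdout splits are single, random and unstratified.

`solve_confusion` inverts the printed aggregates (size, accuracy, FN count,
precision) to the unique integer matrix, accepting either round-half-up or
truncation at the printed precision — published tables demonstrably truncate
in places (72.727 → 72.72, 89.897 → 89.89). Matching is exact at printed
precision: any looser tolerance admits spurious matrices.

## Levenberg–Marquardt regression

Networks: fully connected, tanh hidden units, linear output, seeded uniform
[−0.5, 0.5] initialization. Inputs are raw analyte values plus 0/1-encoded
qualitative variables, min–max scaled to [−1, 1] on the training partition
(the same affine map applied to validation/test). The response stays on the
0–100 score scale, so MSEs are in squared percentage points.

Each epoch computes the model Jacobian J (batched backprop) and solves
(JᵀJ + μI)Δ = Jᵀe, retrying with μ ×10 until the training SSE strictly
decreases (μ ×0.1 after acceptance; μ₀ = 10⁻³, ceiling 10¹⁰ — reaching the
ceiling stops training with a `damping_limit` diagnostic). When parameters
outnumber training samples the identical dual form
Δ = Jᵀ(JJᵀ + μI)⁻¹e is solved instead, which keeps the 8441-parameter
5×40 network trainable in seconds on one CPU; primal/dual equivalence is
property-tested. Early stopping: patience 6 on validation MSE; the report is
taken at the best-validation weights, and the reported gradient is ‖Jᵀe‖
there (verified against finite differences in the tests).

The sweep trains (1,3), (1,10), (1,20), (5,3), (5,10), (5,20), (5,40),
(10,3), (10,10), (10,20) on one fixed seeded 60/20/20 split and flags the
minimum-validation-MSE architecture. Exact published MSE/epoch values are
not reproducible without the original private data and initialization; the
test suite asserts the qualitative capacity ordering instead (the 5×40 net
beats the 1×3 net's validation MSE in a majority of 5 seeds on the default
900-record cohort, with the epoch cap at 40 — at that size an epoch costs
about a second, so the check runs in seconds).

Tolerance-based regression accuracy (share of predictions within 5 points of
the truth on the 0–100 scale) is a surrogate definition: no stated formula
links a single MSE to an accuracy percentage, so none is asserted against
published accuracy figures.

## Numerical choices and degenerate inputs

- Weight vectors must sum to 1 within 10⁻⁹ after rescaling.
- The combined scheme's all-equal-raws case maps to the band midpoint
  (the min–max map is otherwise undefined).
- Score ties at the threshold are negative; healthy-interval bounds are
  inclusive.
- Empty cohorts round-trip as two-reference-row files; a schema whose
  variables have no unhealthy flank at all is rejected at worst-case
  construction (the normalization denominator would vanish).
- Undefined metric ratios (empty denominator) are reported as missing,
  never as 0.
- Cohort CSVs print floats at 10 significant digits; write→read→write is
  byte-idempotent.

## Known limitations

- Default reference intervals are stand-ins, not the (unpublished) originals;
  scores under different schemas are not comparable.
- The generator's independence across variables makes the classification
  problem nearly separable; real cohorts will not be.
- LM training stores the full n_train × P Jacobian; very large networks or
  cohorts would need a matrix-free variant.
- Single-output networks only; the bench regresses one response.
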