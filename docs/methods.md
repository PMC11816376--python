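# Methods

This note documents the statistical machinery of `copdreadmit`, the
choices that were genuinely open, and what the synthetic validation does
and does not demonstrate.

## Problem and data model

The outcome is binary: any COPD rehospitalization within 90 days of
discharge from an index AECOPD admission.  A patient is a row of 39
variables (see `copdreadmit.schema.SCHEMA`): continuous clinical
measurements (age, BMI, pack-year index, %FEV1, %eosinophils), scores
(CAT 0–40, mMRC 0–4), utilization counts (prior-year hospitalizations,
positive cultures, stay days), dependency counts (BADL 0–5, IADL 0–8),
and 27 binary comorbidity/treatment/social indicators.  Missing data are
handled by complete-case analysis: a row with any missing required value
is dropped and counted, never imputed.

## Preprocessing and selection

* **Normalization.** Numeric variables are min-max scaled to [0, 1] with
  bounds learned on training rows only; binary variables pass through.
  At predict time, values outside the training range are clipped into
  [0, 1] — this prevents leakage and guarantees that level-1 risks and
  fuzzy inputs stay inside the partition domains.
* **Split.** A single stratified hold-out with
  `n_test = round(0.2·n)` (half-way ties to the test set, so 460
  patients split 368/92); test slots are allocated per class by largest
  remainder, keeping the class ratio within one patient.  Whether the
  original workflow stratified or seeded its split is unknown;
  stratification was chosen so that rule generation always sees both
  consequents.
* **Selection order.** Quasi-constant filter (a variable is dropped iff
  its modal value covers ≥ 98% of rows) → correlation grouping →
  recursive feature elimination.  The quasi-constant filter runs before
  the normalizer so that a constant column, which min-max scaling cannot
  handle, is removed rather than fatal; rescaling is order-inert for the
  other steps (it changes neither Pearson correlations, nor modal
  shares, nor forest splits).
* **Correlation grouping.** Variables are nodes; an edge joins two
  whose |Pearson r| > 0.8 (binary variables included — point-biserial
  reduces to Pearson on 0/1 codes).  Connected components are the
  groups; the kept member is the earliest in schema order, a
  deterministic stand-in for the unspecified "keep one per group"
  criterion.
* **RFE.** A 100-tree random forest (Gini, unbounded depth,
  `min_samples_split=2`) ranks features by mean impurity decrease; the
  least important one is removed and the forest refit, until 12 remain.
  The target count 12 is a configuration default, not a discovered
  quantity.  The ranker seed defaults to a fixed value for
  reproducibility.

## Level 1 — the three risk engines

Random forest (100 trees, Gini, unbounded depth, min split 2), Gaussian
naive Bayes (variance smoothing 1e-9), and a multilayer perceptron (one
hidden layer of 9 logistic units, Adam, L2 1e-4, constant learning rate,
≤ 1000 epochs).  The engines are deliberately pluggable: anything
honoring the probabilistic-classifier contract can replace them, so
standard scikit-learn implementations are used rather than bespoke ones
— the bespoke science of this package is level 2.  Perceptron
non-convergence within the epoch budget is logged and recorded in the
artifact metadata, not fatal.  The learning-rate value itself is the
implementation default (0.001), also recorded.

## Level 2 — Wang–Mendel rule learning and Mamdani inference

* **Partitions.** Each risk axis gets a uniform triangular partition of
  2N+1 sections over [0, 1] — fixed domains, since the inputs are
  probabilities and the label is 0/1, rather than observed min/max.
  N = 2 (5 sections) for the antecedents; N = 1 (3 sections) for the
  consequent with the central section suppressed, because a binary
  label never activates it.  End sections are half-triangles; adjacent
  triangles overlap so the active memberships form a partition of unity
  (checked to 1e-12).
* **Rule generation.** One candidate rule per training patient: each
  variable maps to its maximum-membership section (ties to the lower
  index), the consequent to the section active at the label.  The rule
  degree is the product of those memberships; the consequent factor
  equals 1 at the domain endpoints but is kept in the product for
  fidelity to the general construction.
* **Conflict resolution.** Group by antecedent tuple, keep the single
  highest-degree rule; degree ties keep the earliest training row.  The
  resulting base has unique antecedents, hence at most 5³ = 125 rules.
* **Expert rules.** A merge entry point exists for expert-authored
  rules (conflicts resolved by the same degree criterion), but the
  trained system injects none.
* **Inference.** Firing strength = min of antecedent memberships;
  implication clips the consequent set at the firing strength;
  aggregation is pointwise max; defuzzification is the centroid on a
  uniform 1001-point grid over [0, 1] (the grid moves the output by
  < 1e-3 against a 100001-point reference; the resolution is a config
  knob).  Product AND, scaled implication and mean-of-maxima are
  provided as alternates.  An input whose antecedent region is covered
  by no rule returns the training prevalence with a `no_rule_fired`
  flag — a silent 0 would bias toward "no readmission".
* **A centroid caveat.** Centroid defuzzification is not pointwise
  monotone: as a rule's firing strength drops below 1, the clipped
  triangle's centroid shifts slightly toward its interior.  On a rule
  base learned from monotone data the response along the (t,t,t)
  diagonal is exactly monotone at the section apexes and wobbles by
  ≲ 0.02 between them; the property test asserts exactly that.

## Thresholding and evaluation

The crisp risk is compared against a cutoff chosen by maximizing Mcc
over a uniform 0.001 grid on [0, 1] (decision rule: positive iff
score ≥ threshold; ties take the smallest threshold).  Zero denominator
factors give Mcc = 0 by the standard convention.  By default the cutoff
is selected on the test set — methodologically optimistic, but it is how
such systems are commonly tuned; `threshold_on="validation"` retrains on an inner 80/20 split
of the training data and picks the cutoff leakage-free.  ROC/AUC use
the trapezoidal rule (equal to the normalized Mann–Whitney U, asserted
in tests).

## Synthetic cohort generator

The generator defines the study conditions for all validation.
Marginals (invented — no real marginals are public — and chosen to be
clinically plausible): age ~ N(70, 9²) clipped [40, 95]; BMI ~ N(27, 5²)
clipped [14, 45]; PYI ~ half-normal(45); %FEV1 ~ N(45, 17²) clipped
[15, 100]; %EOS ~ logN(0.5, 0.8) clipped [0, 15]; CAT ~ round N(18, 8²)
clipped [0, 40]; mMRC categorical favoring grades 2–3; stay ~ 1 + NB
(mean 9); prior hospitalizations ~ Pois(1.2); cultures ~ Pois(0.4);
BADL/IADL from a shared latent frailty factor (ρ = 0.6 on the latent
scale, ≈ 0.56 after discretization); remaining binaries ~ Bernoulli with
documented probabilities.  Ranges are enforced by clipping, which
shifts edge moments slightly.  The outcome is
Bernoulli(logistic(β₀ + Σβᵢzᵢ)) on sample-standardized features with
nonzero β exactly on the 12 informative variables (positive on
utilization, symptom burden and dependency; negative on %FEV1 and BMI);
β₀ is calibrated by bisection so the expected prevalence matches the
target (default 0.35), leaving only binomial noise (±2% at n ≥ 2000).

What passing tests show: the pipeline recovers planted signal (selection
recall, held-out AUC), respects its structural identities, and is
deterministic.  What they do not show: performance on real AECOPD
cohorts — the generator draws features independently apart from the
frailty factor, has no missingness, no site effects, and its effect
sizes are assumptions, so the synthetic AUC is not a clinical estimate.

## Problem sizes and seeds

Default validation sizes: n = 2000 cohorts (10 seeds) for end-to-end
recovery, n = 5000 (5 seeds) for selection recall, n = 20000 for
prevalence calibration — sizes at which the planted-signal checks are
stable while the full suite stays quick.  One top-level seed fans out to
per-stage sub-seeds via a CRC32-salted `SeedSequence`
(`pipeline.derive_seed`), so any stage can be rerun reproducibly in
isolation; artifacts from identical configs are byte-identical.

## Known limitations

* Trained-model payloads inside the JSON artifact are base64-encoded
  pickles (scikit-learn estimators have no canonical JSON form); they
  round-trip bit-identically but are not portable across scikit-learn
  versions.  All other artifact fields are plain full-precision JSON.
* Rule-base compression beyond Wang–Mendel conflict resolution is out
  of scope, as are type-2 fuzzy sets and Sugeno inference.
* The number of rules surviving conflict resolution depends on how the
  training risks cluster; synthetic cohorts yield ~55–65 rules, and that
  count should not be expected to transfer to real cohorts.
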