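# Methods

`refwait` implements a pipeline for measuring the wait from a family
physician's (FP) referral to the first specialist consultation when the
referral notes themselves carry no trustworthy specialty label. It has
three scientific components: weakly supervised label inference from
administrative claims, constrained selection of one-vs-rest text
classifiers, and bootstrap estimation of wait-time quantiles. A synthetic
EMR+claims generator supplies cohorts with known ground truth so that
every stage is checkable end to end.

## Label inference from claims linkage

Specialist consult claims in administrative billing data carry a reliable
specialty code and date; free-text referral notes do not. For a patient
with exactly one referral note and exactly one consult claim in the study
year, the note almost certainly targets the claimed specialty, so the
pair yields a "gold" label without manual abstraction. Patients with any
other event multiplicity are ambiguous (k notes and k claims admit up to
k! pairings) and are excluded.

Two filters precede pairing. Notes with fewer than 6 tokens (after
lowercasing and removal of punctuation and digits) are discarded as
uninformative stubs; 6 tokens is the shortest note that can state a
complaint ("please see John for chest pain"). Specialties whose scope
overlaps many others — by default "internal" medicine — are excluded
because their claims do not identify a specific referral target. The
note count for the single-note rule is taken *after* the short-note
filter: a stub is not a true referral and should not disqualify its
patient. Aggregate count tables suppress cells below 5 as the string
`"<5"` (small-cell privacy suppression); zero-count specialties are
omitted entirely.

One boundary case is worth naming: a single-event patient whose consult
falls after December 31 has no in-year claim and cannot form a gold pair.
Label inference is therefore sound (every emitted label is correct when
no confounding events exist) but not complete for year-end referrals;
the wait-time stage, by contrast, deliberately follows referrals into
the next calendar year.

## Text model

Tokenization is a whitespace split after lowercasing and replacing every
non-letter character with a space; there is no token-length minimum. An
optional Snowball (Porter2, English) stemmer collapses inflectional
variants; the stemmer is implemented in `refwait.stemmer` as a complete,
self-contained Porter2 (regions R1/R2, steps 0–5, both exception lists).

The vocabulary keeps unigrams with total corpus frequency ≥ 5 (rarer
tokens are mostly misspellings), ordered lexicographically. Documents
become either raw count vectors or tf-idf vectors with the smoothed
convention idf(t) = ln((1+N)/(1+df(t))) + 1 followed by Euclidean
normalization; count vectors are not normalized. The vocabulary is
rebuilt on each cross-validation training fold — never on held-out
notes — so feature selection cannot leak.

## Classifier grid and evaluation

Each specialty gets an independent binary (one-vs-rest) logistic
regression. The grid crosses preprocessing {no-stem, stem},
vectorization {count, tf-idf}, penalty {ridge/L2, lasso/L1},
regularization {0.001, 0.01, 0.1, 1, 10} and class weight {none,
balanced}: 80 configurations. The regularization axis is the *inverse*
penalty strength (scikit-learn's `C`; larger = weaker penalty), the
convention of the toolkit family this kind of pipeline is built with.
Balanced weighting assigns w_c = n_total/(2·n_c), i.e. a minority class
at 10% receives 9× the majority weight.

Performance is measured by stratified 5-fold cross-validation at a fixed
0.5 decision threshold. Folds are stratified on the full multiclass gold
label, which preserves every specialty's positive rate in every fold at
once and lets all one-vs-rest tasks share one split; this also makes the
grid cheap (per specialty: 80 fits, not 80 featurizations). Specialties
with fewer positive examples than folds are skipped rather than scored.
Metrics per fold: precision (PPV), recall (sensitivity), F1,
specificity, NPV and Brier score; any zero-denominator metric is
reported as 0 with an "undefined" flag. Fold means use the population
standard deviation (ddof = 0). Solver: liblinear, tolerance 1e-6,
maximum 5000 iterations, fixed random state — runs are deterministic
given the CV seed.

A note on a tempting invariant: the number of nonzero lasso weights is
*not* globally monotone in the penalty on separable data (the active set
can reorder as C grows). The property suite checks sparsity monotonicity
at the grid values on a noisy cohort, where the penalty binds.

## Model selection and the deployment gate

Three schemes summarize the grid per specialty: highest precision
subject to recall ≥ 0.3; highest recall subject to precision ≥ 0.3; and
highest F1. The floors exist because the grid always contains
near-degenerate corners (precision 0.97 at recall 0.01) that are useless
in practice. When a floor is unsatisfiable the unconstrained argmax is
returned with a `fallback` flag. Ties break by higher precision, then
lower enumeration index.

Wait times are estimated only for specialties whose **precision-floor**
selection reaches precision ≥ 0.70 and recall ≥ 0.30: precision bounds
the contamination of the wait sample by wrong-specialty matches, which
matters more here than capturing every referral. Fallback selections are
never eligible — their recall is below the floor by construction.

## Wait times

The gated classifiers are deployed at threshold 0.5 on the full
(short-note-filtered) note stream; a note may be claimed by several
specialties or none. Per patient and specialty, the wait is the
calendar-day difference between the first positively-predicted note in
the study year (date ties broken by note id) and the first claim of that
specialty on or after it, allowing claims through the end of the
following year; consults before the referral are meaningless and
ignored. Day arithmetic is exact and leap-aware.

Quantiles (median, 75th, 90th percentile) are empirical, with 95%
percentile-bootstrap confidence intervals over B = 1000 resamples
(seeded; the CI is clipped to bracket the point estimate, which matters
only at tiny n). A prior-period value constitutes a *substantial* change
exactly when it falls outside the closed 95% CI; direction follows the
sign of (current point − prior value).

## Diagnostics

Three companion analyses: best F1 against training-set size; mean binary
accuracy ((TP+TN)/n per specialty's best-F1 classifier, averaged
unweighted across classifiers) by note length, suppressing lengths with
fewer than 5 notes under the same `<5` rule as the count table; and a
confidence-threshold sweep (default grid 0.05–0.95 in steps of 0.05)
reporting PPV, sensitivity and the implied median wait per threshold
next to a gold-only baseline median that uses no classifier. Sensitivity
is monotone in the threshold (positive sets are nested); precision is
not asserted monotone because it is not, in general.

## Synthetic cohorts

The generator emulates the structural features the pipeline relies on:

* **Specialty signal.** Each specialty owns a disjoint keyword
  vocabulary (default 40 alphabetic tokens) embedded in a shared filler
  vocabulary (default 400); a fraction `keyword_rate` (default 0.6) of
  each note's tokens come from its specialty's vocabulary. 0.6 makes the
  task learnable but not trivial at desk scale.
* **Note lengths.** A discrete mixture from 3 to 150 tokens with ~7%
  mass below 6 tokens, exercising the short-note filter.
* **Event structure.** Every patient has one referral (date uniform over
  the study year) and one same-specialty consult at referral + wait; a
  `multi_event_rate` fraction (default 0.2) additionally receives one or
  two confounding events (extra notes and/or claims, uniform specialty
  and date), which removes them from the gold-pair set.
* **Waits.** Log-normal with per-specialty median (defaults 30/60/90
  days) and log-scale sigma 0.5 — strictly positive and right-skewed,
  the shape seen in referral wait data where the 90th percentile far
  exceeds the median.

Identical seeds give byte-identical cohorts; all randomness flows
through one `numpy` generator per cohort.

What the generator does **not** emulate: real clinical language
(vocabulary separation is far cleaner than between, say,
gastroenterology and general surgery), EMR-vendor formatting, tick-box
or custom-form referrals, seasonal referral patterns, or censoring of
never-seen referrals. Passing tests therefore demonstrate the
correctness of the machinery — label derivation, leakage-free
evaluation, constrained selection, linkage and bootstrap — not the
performance the method would attain on real notes, where precision and
recall are substantially lower.

## Problem sizes and defaults

Tests and the acceptance script run the full 80-configuration grid on
cohorts of 3–5 specialties × 300–500 notes, with B in the hundreds to
1000 and 20 replicate runs for CI-coverage checks; a full study run at
these sizes takes seconds thanks to the per-fold matrix cache. The
package scales to larger corpora linearly in notes × vocabulary.

## Known limitations

* Gold-pair inference assumes the single-note/single-claim heuristic is
  correct; with confounding events present a small fraction of pairs is
  mislabeled (a patient whose true note was filtered short but who has a
  retained confounder note, for example).
* No probability recalibration: logistic regression is taken as
  adequately calibrated for thresholding.
* No censoring adjustment: referrals that never lead to a consult within
  the two-year window simply drop out, which biases waits downward for
  slow specialties.
* The suppression rule hides counts 1–4 but the table's presence/absence
  of a row still reveals whether a count is zero.
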