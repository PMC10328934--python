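# Methods

This note records the modelling choices, the generator's semantics, the
numerical conventions, and the known limits of what the test suite can show.

## Pipeline overview

Raw input is four event tables: `patients(patient_id, birth_date, sex)`,
`encounters(encounter_id, patient_id, date, type, status)`,
`diagnoses(encounter_id, patient_id, date, icd10_code)` and
`labs(patient_id, date, lab_name, raw_value, unit)`. The stages are:

1. **Cohort selection** — keep completed office visits; drop encounters
   with no diagnosis; compute *frequent* full codes (held by ≥
   `min_patients` distinct patients, inclusive threshold, counted within
   the office-visit universe); drop non-frequent codes, then encounters
   left bare, then patients left with fewer than two encounters. One pass
   in this order reaches the fixed point (dropping patients cannot
   re-introduce encounters; asserted). Frequent codes are computed on the
   whole cohort *before* splitting — the selection design this mirrors does
   the same — and the implied mild leakage affects only which labels exist.
2. **Patient-level split** — 60/20/20 by patient (largest-remainder
   rounding, seeded permutation), so no patient straddles splits.
3. **Label space** — three-character prefix grouping with dot removal and
   upper-casing; letters R, U, V, W, X, Y, Z excluded from labels (but *not*
   from input features: symptom history is predictive). Encounters whose
   only retained codes group to excluded letters are dropped and counted.
   Chronic/acute designation comes from a Chronic Condition Indicator style
   table; prefix entries win, otherwise the majority flag over the cohort's
   observed constituent full codes, ties resolving to chronic, absent
   entries flagged `unknown` and logged.
4. **Features** — age in fractional years ((encounter − birth)/365.25),
   one-hot sex over {M, F, Unknown}; binary presence per diagnosis prefix in
   `[date − w, date)` (closed at the old end, open at the index date — no
   same-day leakage); per numeric lab a presence flag plus the most recent
   in-window value, same-date ties resolved to the maximum; per categorical
   lab an any-positive flag. Diagnosis vocabulary is fixed on the training
   patients; the schema is immutable after fitting and carried by hash into
   the model bundle.
5. **Model** — per label: undersample negatives to 1:1 (all positives kept;
   identity when negatives are the minority), then max-abs scaling (LR
   only; fitted on the undersampled rows, matching the pipeline order) and
   the base classifier. LR uses the liblinear solver with an l1 or l2
   penalty (default l2, unit regularization strength); RF defaults to 200
   trees, unlimited depth, sqrt-features per split. Per-label seeds derive
   deterministically from the master seed and the label's column index, so
   training is order- and parallelism-independent. Zero-positive labels are
   flagged skipped and predict their training prevalence (zero).
6. **Calibration** — per label, stratified 5-fold CV refits the *entire*
   pipeline (undersampling included) per fold; out-of-fold scores feed an
   isotonic fit clipped to [0, 1]. When positives cannot stratify five
   folds the label falls back to as few as two folds (logged); below two
   positives it stays uncalibrated. The final model is the full-training
   refit with the CV-derived calibrator attached.
7. **Evaluation** — AUROC is the Mann–Whitney concordance (ties half
   credit), AUPRC the average-precision summation without interpolation;
   both are cross-checked in tests against hand-written brute-force
   oracles. recall@k and coverage error rank each encounter's score vector
   with a deterministic lexicographic tie-break; rows with no true label
   are excluded and counted. Undefined per-label metrics are recorded as
   missing, never zero. De-novo evaluation keeps, per (patient, label),
   encounters dated up to and **including** the first positive (same-date
   ties all eligible). Model comparisons use the paired Wilcoxon
   signed-rank test (zero differences dropped, exact null for ≤ 25 pairs,
   else normal approximation with continuity correction); chapter-level
   p-values are Benjamini–Hochberg adjusted across letters at FDR 0.05.
8. **Interpretation** — attributions are additive on *uncalibrated* scores:
   weight×value in log-odds space for LR (base = intercept), exact
   tree-path decomposition in probability space for RF (each split
   contributes the change in node positive fraction; telescopes exactly to
   the predicted probability). The isotonic calibrator is monotone and
   rank-preserving, and additivity through a step function is ill-defined,
   hence the raw-score convention; the link space is recorded in every
   result. Background samples are seeded subsamples of ≤ 1000 training
   rows.

## The synthetic generator

The generator emulates a multi-year outpatient stream: encounter counts per
patient follow a zero-truncated negative binomial (dispersion 1.2, mean 7)
whose median lands near 5; encounter dates are uniform distinct days over a
9-year window; sex is 44% M / 55.5% F / 0.5% Unknown; ages 1–85 at study
start. Each alphabet code is drawn per encounter from a logistic model
whose covariates are **exactly** the feature builder's windowed aggregates
(3650-day diagnoses, 365-day labs), so the model class is well specified
and recovery tests are meaningful:

- **Chronic** codes carry a self-weight of 2.5–3.5 × `signal_strength`, so
  once acquired they recur with high probability — persistence emerges from
  the model rather than a bolted-on rule. Acute codes have weak
  self-weights (0.2–0.6 × signal).
- Each signal label depends on three other codes (80% risk-increasing,
  magnitudes 0.4–1.0 × signal), one numeric lab (weight expressed on the
  raw canonical-unit scale, derived from a ±0.4–0.9 × signal effect per
  standard deviation), and mildly on age.
- **Null** labels have all-zero weight vectors and act as the statistical
  control arm; their baseline prevalence is drawn log-uniform on
  [0.05, 0.12] — common enough that a held-out AUROC ≈ 0.5 check has power
  at cohorts of a few thousand patients. Signal labels draw baseline
  target prevalence log-uniform on [0.01, 0.06]; realized prevalences are
  higher for chronic labels (up to ~0.4 in-cohort), a deliberate mirror of
  common chronic conditions.
- Excluded-letter codes (e.g. R07, Z79) are generated as common,
  history-independent symptom/status codes: present in the diagnosis
  stream and the feature space, never in the label space.
- Two numeric labs are emitted with a ×10 unit confusion and a name variant
  on a random 25% of events; categorical labs emit string values
  ("Positive", "NOT DETECTED", …). `harmonization_tables(truth)` returns
  the conversion table that undoes exactly this corruption, and
  `cci_table(truth)` the chronic/acute mapping.
- All randomness flows from one `numpy` generator seeded by the config;
  identical configs give byte-identical CSV output.

`effective_weights(truth)` rescales ground-truth weights to comparable
per-standard-deviation units (lab values × lab sd, age × 24 years); tests
use it to rank labels and features by actual signal content.

What the generator does **not** emulate: real ICD-10 ontology depth (a
~20-code alphabet with single-digit suffixes), medication/procedure events,
visit-type taxonomies beyond office-visit/other, coding-practice drift,
informative missingness of labs, and inter-patient correlation. Passing
recovery tests therefore demonstrates correctness of the machinery under a
well-specified mechanism, not clinical performance on real records.

## Standing experiment sizes

Chosen once as the package's study conditions: recovery experiments use
2000 patients, `signal_strength` 2.0 (the "clearly signalled" condition),
10 seeded replicates; window-monotonicity comparisons use 800 patients at
signal 1.5 with demographics+diagnoses; the acceptance script uses 2000
patients at the default signal 1.0 with a 100-tree forest; examples use
400–600 patients. Synthetic runs scale the frequent-code threshold to
`min_patients` 15–25 (the production default of 500 presumes six-figure
cohorts).

## Numerical conventions and degenerate inputs

Calendar arithmetic is in whole days; ages in fractional years. Ranking
tie-breaks are lexicographic in label order everywhere. Undersampling with
fewer negatives than positives is the identity. Single-class labels are
skipped, never fitted. Metrics TSVs are written with fixed `%.10g`
formatting so repeated runs are byte-identical. Empty cohorts return an
explicit empty result with the audit trail, not an exception. Malformed
ICD-10 codes (no leading letter, fewer than three characters after dot
removal) are rejected with the offending string.

## Known limitations

- The per-label independence of binary relevance ignores label
  co-occurrence structure; it is the price of per-label decomposability.
- Isotonic calibration is piecewise-constant; its sup-norm error shrinks
  only at the cube-root rate, so pointwise guarantees are weaker than the
  binned calibration-curve guarantees the tests assert.
- Tree-path attributions are exact and additive but are not Shapley values;
  they attribute along the realized decision path only.
- With `max_features="sqrt"` individual shallow trees may split on
  uninformative features; attribution sparsity statements hold for the
  forest in aggregate, not per tree.
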