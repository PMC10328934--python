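# multidx

Interpretable multi-label prediction of ICD-10 diagnosis codes at outpatient
office visits, from a patient's demographics, time-windowed past diagnoses
and harmonized lab results.

## The problem

At each clinic encounter a patient may receive several ICD-10 diagnosis
codes. Given only what is already in the record *before* the visit, which
diagnoses are likely today? A model that answers this can help clinicians
prepare for a visit and reduce missing or incomplete diagnosis entries in
the EHR. `multidx` is aimed at researchers working with longitudinal EHR
event tables (patients, encounters, diagnoses, labs) who want a transparent,
per-disease-decomposable alternative to sequence models.

## The model

Full ICD-10 codes are grouped under their three-character prefixes (all of
I25.x becomes the label I25); codes starting with R, U, V, W, X, Y, Z —
symptoms, external causes, health-status factors — are excluded from the
label space. For labels *l = 1, …, L* the package uses **binary relevance**:
one independent binary classifier *M_l* per label, each trained on the same
feature vector

    x = demographics ⊕ diag-history ⊕ lab-history      (early fusion)

where the diagnosis block is binary presence of each three-character prefix
within a look-back window (90/180/365/3650 days) ending strictly before the
index date, and the lab block holds, per harmonized lab, a presence flag and
the most recent in-window value (30/90/180/365 days). Each per-label
pipeline is

    undersample negatives to 1:1  →  [max-abs scale  →]  LR or RF

and the score scale distorted by undersampling is repaired by **isotonic
calibration** fitted on out-of-fold scores from a stratified 5-fold CV that
refits the whole pipeline per fold. Evaluation reports per-label AUROC and
AUPRC, plus the multi-label ranking metrics recall@k and coverage error,
under two protocols: *overall* (every test encounter) and *de novo* (for
each label, only encounters up to the patient's first occurrence of that
label — repeat occurrences are easy and are excluded). Per-label additive
feature attributions (weight×value in logit space for LR, exact tree-path
decomposition in probability space for RF) make every prediction
inspectable.

Because outpatient EHR streams of this kind are not publicly available, the
package ships a first-class synthetic generator (`multidx.synthetic`) whose
per-label logistic ground truth uses exactly the windowed features the
feature builder produces — so recovery, calibration and leakage properties
are all testable against a known mechanism.

## Worked example

```bash
python examples/end_to_end_prediction.py
```

```
labels: 20   features: 44
{'train': 2141, 'val': 814, 'test': 710} encounters per split
coverage_error           11.576
median_auprc_overall     0.712
median_auroc_denovo      0.708
median_auroc_overall     0.878
recall_at_10             0.818
recall_at_5              0.564
```

On this 600-patient simulated cohort the calibrated logistic model reaches a
median test AUROC of 0.878 across the 20 disease labels; restricted to each
patient's first occurrence of a label (de novo) it drops to 0.708, because
repeat occurrences of chronic conditions are the easy cases. `recall@10 =
0.818` means that, averaged over test encounters, 82% of an encounter's true
labels appear among the 10 top-scored ones; a coverage error of 11.6 says
the worst-ranked true label sits at mean rank ~12 of 20.

Other entry points: `examples/simulate_cohort.py` (generator + selection
cascade), `examples/compare_classifiers.py` (LR vs RF with paired Wilcoxon
tests and Benjamini–Hochberg-adjusted chapter summaries),
`examples/explain_label.py` (attributions vs ground-truth weights), and the
`multidx` CLI (`simulate`, `build-cohort`, `run`, `explain`).

## Caveats

- The frequent-code threshold is computed on the whole cohort before the
  patient split, mirroring a selection-before-split design; the mild
  information leakage this implies affects label-universe choice only, not
  model fitting.
- Synthetic cohorts are a few thousand patients; the default
  frequent-code/lab thresholds used in examples are scaled down accordingly
  (`min_patients` ≈ 15–25 instead of the production 500).
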