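# ecgpain

ECG-only pain recognition as a tested, reusable pipeline. The package covers
the full analysis chain for a cold-pressor (CPT) protocol:

1. **`ecgpain.synth`** — synthetic protocol-structured ECG cohorts
   (36 participants × 2 sessions by default) with analytic ground-truth
   fiducials, realistic noise (baseline wander, powerline, broadband) and a
   controllable CPT effect on heart rate, S/T/R amplitudes and the T-offset
   level. The study population this emulates is not publicly available, so
   all effect sizes are synthetic and documented.
2. **`ecgpain.preprocess`** — mean centering, zero-phase Butterworth
   band-pass (0.5–40 Hz, overall transfer-function degree 4) and
   trigger-based segmentation into the five protocol epochs
   (baseline, warm1, cpt, warm2, rest).
3. **`ecgpain.delineate`** — Pan-Tompkins-style R-peak detection and
   P/QRS/T delineation (peaks plus P/R/T onsets and offsets); incomplete
   beats are dropped and counted.
4. **`ecgpain.features`** — 20 s sliding windows with 75 % overlap, the 21
   morphological features per window, and normalization by the
   baseline-epoch mean per participant-session.
5. **`ecgpain.experiments`** — three train/test designs (dependent
   5×2-fold CV, session-independent, participant-independent LOOCV), an
   eight-classifier roster (AdaBoost, decision tree, kNN, LDA, logistic
   regression, random forest, linear/RBF SVM) with library-default
   hyperparameters, and six metrics (accuracy, balanced accuracy, F1, MCC,
   precision, recall) computed in closed form.
6. **`ecgpain.importance`** — family-appropriate feature importance
   (coefficients / impurity decrease / permutation) min-max scaled to
   [0, 1], with per-model and consensus rankings.
7. **`ecgpain.cli`** — `simulate`, `preprocess`, `delineate`, `features`,
   `run`, `importance`, `report` commands over a plain-text cohort
   directory (CSV signals, JSON annotations).

## CLI quick start

```sh
ecgpain simulate --out cohort --participants 4 --sessions 2 --seed 1 --epoch-scale 0.5
ecgpain run --cohort cohort --seed 1          # preprocess → delineate → features → experiments → importance
ecgpain report --cohort cohort                # metric tables + importance heatmaps
```

`run` writes `cohort/results/summary.csv` (8 models × selected approaches ×
6 metrics), per-evaluation detail, and per-approach importance tables.
Everything is deterministic given the seeds in the manifest.

## Notes

- Distances are reported in samples; the sampling rate (default 1000 Hz)
  is carried alongside for unit conversion.
- Epoch intervals and windows are half-open `[start, end)` with 0-based
  sample indexing.
- The wave onset/offset ground-truth convention is the point where a wave
  component falls to 5 % of its peak height (configurable); the delineator
  places edges at a configurable fraction of the local wave prominence
  (default 10 %).
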