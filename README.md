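# qsdar

Spectral-descriptor activity modelling (QSDAR) for virtual screening of
natural-product libraries, with a docking-score pIC50 proxy and a
Tanimoto/probability applicability domain.

## The problem

Screening large natural-product libraries against a protein target (the
motivating case is the PD-1/PD-L1 immune checkpoint) usually requires
structures, docking and descriptor pipelines. QSDAR — Quantitative
Spectrometric Data–Activity Relationship modelling — instead predicts
activity from spectra: ¹H NMR chemical shifts and coupling constants are
binned into fixed-length descriptor vectors and fed to ordinary machine
learning models. Because a spectrum can be measured (or predicted) without
knowing the structure, this extends activity prediction to compounds and
extracts whose structures are not yet elucidated.

This package implements that workflow end to end:

1. **Activity proxy** — docking free energies ΔG_B (kcal/mol) are sanitised
   (only −20 ≤ ΔG_B ≤ −2 is plausible) and converted to pIC50 either
   thermodynamically, pIC50 = −ΔG_B / (ln 10 · R · T), or through a linear
   map calibrated on experimental pIC50 values. A compound is *active* when
   IC50 ≤ 10 µM, i.e. pIC50 ≥ 5.
2. **Spectral encoding** — a peak list becomes a 570-vector (285 chemical-
   shift bins at 0.05 ppm + 285 coupling bins at 0.1 Hz), a 250-vector
   (5 atom-type channels × 50 shift bins), or their 820-concatenation.
3. **Modelling** — `QSDARModel(X, y, config).fit()` returns a
   `QSDARResults` with predictions, probabilities and a `summary()` table;
   random forest, LightGBM, SVM and MLP backends; top-k feature selection by
   random-forest importance; 10-fold CV, OOB and external-test evaluation
   with self-implemented SE/SP/Q/MCC, R²/MAE/RMSE and rank-based ROC AUC.
4. **Applicability domain** — a prediction is in-domain when the maximum
   Tanimoto similarity to the training set is ≥ 0.90 **or** the
   predicted-class probability is ≥ 0.8; confidently wrong predictions
   (probability > 0.8) are annotated with their nearest training neighbour.
5. **Synthetic benchmark** — a generator produces libraries with the
   statistical structure the analysis assumes (≈40 % actives, ΔG_B within
   the plausible window, a weak pIC50/ΔG_B correlation of |R| ≈ 0.32, and
   peak lists whose aromatic-region occupancy carries a tunable activity
   signal), so everything is testable without external data.

## Worked example

```python
from qsdar import SyntheticConfig
from qsdar.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticConfig(n_molecules=2000, spectral_signal_strength=2.0,
                              seed=11),
    test_ratio=0.1, top_k=200, seed=11)
run = run_pipeline(cfg, "runs/demo")
print(run.state.results.summary([run.cv_report, run.test_report]))
```

prints

```
QSDAR model results
=======================================================
algo: gbm   task: classification   trees: 1000   seed: 412
n obs: 1800   n features: 200
-------------------------------------------------------
         cv10  n=1800    SE=0.929 SP=0.973 Q=0.956 MCC=0.907 AUC=0.991
external_test  n=200     SE=0.965 SP=0.965 Q=0.965 MCC=0.929 AUC=0.990
=======================================================
```

Read it as: on a 2000-molecule synthetic library with a clear spectral
activity signal, the LightGBM classifier trained on the 200 most important
of the 570 spectral descriptors recovers the activity class with MCC 0.91
in ten-fold cross-validation and MCC 0.93 on the held-out tenth. The run
directory contains the sanitised activity table, the feature matrix, the
model report, the applicability-domain report (here all 200 test molecules
are in-domain) and the high-confidence-error list (7 molecules), plus a
manifest with the row counts of every stage.

The same pipeline is available from the shell:

```bash
qsdar run -o runs/demo --seed 11
qsdar simulate --n 5000 -o work/
qsdar filter --scores work/library.csv --out work/activity.csv
qsdar encode --peaks work/peaks.csv --encoding spinus570 --out work/features.csv
qsdar train --features work/features.csv --labels work/library.csv -o work/report.json
```

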