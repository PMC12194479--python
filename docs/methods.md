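# Methods

## Overview

The package models binary bioactivity (active ⇔ IC50 ≤ 10 µM ⇔ pIC50 ≥ 5)
from fixed-length encodings of ¹H NMR peak lists, with the activity labels
themselves derived from docking free energies. Four stages carry the
science: the docking-score activity proxy, the spectral encoders, the
model/evaluation layer, and the applicability domain. A synthetic-data
generator supplies libraries with the statistical structure these stages
assume.

## Activity proxy

Docking scores outside [−20, −2] kcal/mol are treated as artefacts and
flagged (boundary values kept; non-finite values become per-record errors,
never silent drops). Filtering is idempotent.

Two ΔG_B → pIC50 modes:

* **Thermodynamic** (default): pIC50 = −ΔG_B / (ln 10 · R · T) with
  R = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298.15 K, so one pIC50 unit is
  ln 10 · R · T = 1.364243 kcal/mol and the 10 µM class boundary sits at
  ΔG_B ≈ −6.821 kcal/mol. This identifies the docking score with a binding
  free energy and IC50 with the dissociation constant — a deliberate
  simplification (no enzyme/substrate correction) that preserves exact
  monotonicity.
* **Calibrated**: an ordinary least-squares line pIC50 = a·ΔG_B + b fitted
  on pairs with experimental pIC50; reported with its Pearson R. Useful when
  docking scores are systematically offset from the thermodynamic scale, as
  literature calibration sets typically show. A constant-ΔG design is a hard
  error.

IC50 is molar internally; µM/nM formatting is presentation only.

## Spectral encodings

Only the code lengths (285 + 285 = 570; 5 × 50 = 250; 820 concatenated) are
contractual; bin edges are configuration:

* `spinus570`: shifts over [−1.0, 13.25) ppm at 0.05 ppm/bin, couplings over
  [0, 28.5) Hz at 0.1 Hz/bin. The ranges cover the standard ¹H shift and
  J-coupling scales with uniform bins whose counts land exactly on 285 each.
* `gnn250`: channels H, C, N, O, other with 50 uniform shift bins each
  (H [−1, 14) ppm; C [0, 250); N and O [0, 500); other [−50, 450)); unknown
  elements route to the catch-all channel.

Intensity is the nucleus count, so integration information survives and the
shift half of the 570-code sums exactly to the proton count (a conservation
law the tests enforce). Each coupling constant counts once per peak that
lists it; whether coupled partners should share one count is genuinely
ambiguous in practice, and per-peak counting was chosen as the convention
that needs no pairing information. Out-of-range values accumulate in the
nearest terminal bin with a warning rather than being dropped — conserving
mass was judged more important than strict range semantics. Encoders are
pure and permutation-invariant in the peak order.

## Models and evaluation

`QSDARModel` wraps a feature matrix + targets; `fit()` returns a
`QSDARResults`. Backends: scikit-learn random forest (1000 trees, OOB
available), LightGBM (500 trees regression / 1000 classification,
deterministic single-thread mode), RBF SVM (epsilon-SVR / probability SVC),
and an MLP with 4 × 150 rectified-linear hidden units, batch 128, Adam,
500 epochs. Defaults follow the tree counts and network layout standard for
this workflow; `tuned_params` passes through per-backend hyperparameters
(tree depth, leaf count, feature fraction, C, layer layout) for small-grid
searches.

Feature selection is top-k by random-forest impurity importance with ties
broken by lower index (stable argsort), so selection is deterministic;
selecting k = p reproduces the full model exactly.

Metrics are implemented from their definitions, not delegated: SE, SP, Q and
MCC from the confusion matrix (MCC = 0 when any denominator factor is zero —
the common convention for degenerate matrices); R² = 1 − SS_res/SS_tot with
R² flagged undefined for an exactly constant target (detected by zero range,
not by SS_tot, to avoid float-rounding artefacts); AUC as the Mann–Whitney
rank statistic with midranks on ties, which equals the probability that a
random positive outscores a random negative. The test suite cross-checks
them against scikit-learn and against brute-force pair counting.

Cross-validation pools out-of-fold predictions (stratified 10-fold for
classification) and computes metrics once on the pooled vector; OOB
evaluation is restricted to the random forest, the one bagging backend.
Probabilities are used raw (no calibration step).

## Applicability domain

In-domain ⇔ max Tanimoto to the training set ≥ 0.90 **or** predicted-class
probability ≥ 0.8 (both inclusive). "Probability" means the probability of
the class actually predicted (the max over classes). The domain fingerprint
is the 2048-bit path-based fingerprint by default and is configurable; the
similarity search is an exact maximum with first-by-order tie-breaking.
The high-confidence-error report uses a *strict* probability threshold
(> 0.8), deliberately different from the inclusive domain rule, and
annotates each confidently wrong prediction with its nearest training
molecule and that neighbour's cross-validated prediction — automating the
usual manual outlier rationale ("a near-identical training compound carries
the opposite label").

Stratified evaluation guarantees the in-domain and out-of-domain confusion
matrices sum to the overall matrix; an empty stratum yields flagged-`None`
metrics rather than an error.

## Synthetic generator

The generator emulates the study conditions the analysis assumes:

* prevalence: 40 % actives by default (the plausible screening-library
  range is ~39–41 %), drawn as an exact stratified assignment so the
  realised fraction never drifts;
* potency: class-conditional truncated normals, actives N(6.0, 0.8) on
  [5, ∞), inactives N(4.0, 0.8) below 5 — the simplest mixture with the
  right class boundary and a realistic ~2-log-unit spread; the truncation
  makes class ⇔ pIC50 ≥ 5 exact;
* energies: ΔG_B = −1.364243·pIC50 + ε, ε ~ N(0, noise_sd_dg²), clipped to
  [−20, −2] kcal/mol. The default noise (3.2 kcal/mol) reproduces a weak
  (|R| ≈ 0.3) potency/score correlation of the kind literature calibration
  sets show;
* calibration pairs: a bivariate normal with Pearson correlation exactly
  −|target_r| (stronger binding ↔ higher potency; the recovery quantity is
  |R|), pIC50 marginal N(6.0, 0.8), ΔG_B spread 1.5 kcal/mol about the
  thermodynamic mean;
* spectra: 5–25 peaks per molecule over aliphatic (0.5–3 ppm),
  heteroatom-adjacent (3–5.5 ppm) and aromatic (6.5–8.5 ppm) regions plus
  10 % uniform decoys; actives get extra aromatic probability
  (0.15 + 0.25·signal, capped at 0.85), aromatic peaks get ortho-range
  couplings (6–9 Hz), others 0–18 Hz; proton counts 1–3;
* structures: enumeration of ~470 valid natural-product-like
  scaffold/substituent combinations (coumarins, flavonoids, alkaloid cores,
  terpenoid rings, glycosides, quinones, biphenyls), with heavy-atom MW and
  logP computed from the actual structures; NP-likeness and the quantum
  descriptor stub (frontier orbital energies with an exact gap identity,
  non-negative dipoles) are drawn from simple distributions.

One global seed derives all per-stage seeds by fixed offsets; identical
configs give byte-identical output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real NMR physics (no second-order effects,
solvent shifts or linewidths), any real database's chemical-space
distribution, and any structural relationship between a molecule's SMILES
and its spectrum (structures and spectra are independently drawn, so the
spectral signal is injected by construction, not emergent from chemistry).
Recovery results on synthetic libraries demonstrate that the pipeline is
correctly wired and can learn a signal of the injected form; they say
nothing about attainable accuracy on experimental spectra.

## Problem sizes and numerical choices

The signal-recovery experiments use n = 5000 molecules with signal strength
3.0 — large enough that the permutation-null MCC concentrates within ±0.05
of zero (sd ≈ n^(−1/2)) while a ten-fold LightGBM cross-validation stays in
the tens of seconds. The calibration-recovery check averages |R| over 50
seeds at n = 172, matching the size of a typical literature calibration
set. The train/test split uses round(N·ratio) (half-up) test molecules, so
a 1202-of-120,935 ratio reproduces the 119,733/1,202 partition exactly.
LightGBM runs single-threaded and deterministic; all estimators take
explicit seeds.

## Known limitations

* The descriptor-block registry records what RDKit actually produces
  (GETAWAY = 273 values, full 1D&2D list = 210 in the installed version);
  published block counts vary with toolkit version and the lengths are
  treated as metadata, except the fingerprint lengths and the 80/210/5
  blocks, which are stable contracts.
* The thermodynamic proxy overestimates potency for docking scores that are
  systematically more negative than experimental binding free energies; the
  calibrated mode exists for exactly that case.
* The SVM backend exposes probabilities via Platt scaling, which is known
  to be poorly calibrated on small data; domain decisions with `svm` should
  prefer the Tanimoto branch.
* `screen` re-encodes query peak lists with the training configuration; it
  does not check that the query spectra were predicted with the same tool
  as the training spectra.
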