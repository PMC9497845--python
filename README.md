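# lsdl-spectra

Amplitude-band decomposition and classifier benchmarking for labeled FTIR
absorbance spectra, with a synthetic cohort generator so the whole pipeline is
testable without patient data.

The pipeline mirrors a urine-FTIR cancer-prediction workflow:

1. **spectra_io** — labeled spectra as CSV matrices or JCAMP-DX (AFFN subset);
   replicate averaging and dataset concatenation. Wavenumber axes are stored
   descending (4000 → 650 cm⁻¹).
2. **synthetic** — Gaussian-peak cohorts (default 31 noncancer / 22 cancer
   subjects, Gleason distribution 4/5/13) with a class effect planted in a
   chosen absorbance amplitude band, plus baseline drift, noise and
   per-acquisition jitter. Dataset 1 averages three acquisitions per subject;
   dataset 2 keeps a single acquisition; dataset 3 concatenates both.
3. **lsdl** — the threshold learner: amplitude-band decomposition (`upper` /
   `lower` level schemes), a normalized-Euclidean-distance performance index
   between class centroids in feature space, and a coarse-to-fine level search
   (4 iterations × 16 levels, interval halving) with "n/a" bookkeeping for
   candidates that leave any signal under the minimum sample count.
4. **features** — the 12-feature battery (MAV, WL, SSC, ZC, 4thAR, SampEN,
   Ceps, MFL, HFD, DFA, MF, SP); after decomposition ZC/DFA/MF are redundant
   and the reduced 9-feature battery is used.
5. **balancing** — SMOTE oversampling to stated per-class targets
   (31/22 → 62; grade 9/13 → 40), synthetic rows flagged.
6. **modeling** — nine classifiers (DT, LDA, QDA, KNN K=1, linear/quadratic/
   cubic/fine-Gaussian SVM, LR) under stratified 10-fold CV; pooled
   out-of-fold Acc/Sens/Spec/AUC in percent; PCA projection at 98% explained
   variance.

## CLI

```bash
lsdl-spectra simulate  --seed 1 --out runs/sim          # write synthetic cohorts as CSV
lsdl-spectra decompose --spectra runs/sim/dataset1.csv --out runs/lsdl1
lsdl-spectra features  --spectra runs/sim/dataset1.csv --model runs/lsdl1/model.json --out feats.csv
lsdl-spectra balance   --features feats.csv --target majority --out balanced.csv
lsdl-spectra evaluate  --features balanced.csv --out metrics.csv
lsdl-spectra reproduce --seed 1 --out runs/full         # full benchmark, all tables
```

`reproduce` learns a threshold model per origin dataset (never on the
concatenation), evaluates raw vs decomposed features for the cancer exercise
and decomposed features only for the grade exercise, and writes the nine
metrics tables, threshold search tables, PCA scores/plots and a provenance
report. `--leakage-safe` moves SMOTE inside the training folds (the default
mirrors the reported workflow of balancing before cross-validation, which
leaks; both modes are logged loudly). Exit codes: 0 ok, 2 config error,
3 stage failure.

Configuration is a YAML file (see `RunConfig` / `CohortSpec` / `EffectSpec` /
`FeatureConfig` / `BalanceSpec` / `CVConfig`); one master seed derives every
stage seed. The default grid uses an 8 cm⁻¹ step to keep desk-scale runs
fast; pass a finer grid through the config for instrument-like resolution.

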