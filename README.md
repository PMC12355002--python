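# afecv

Spectral and vectorcardiographic analysis of atrial-fibrillation ECGs, with
a LASSO-logistic pipeline for predicting sinus-rhythm (SR) maintenance
after electrical cardioversion (ECV).

## The problem

Electrical cardioversion restores sinus rhythm in most patients with
atrial fibrillation (AF), but the arrhythmia recurs within months in
roughly half of them. A cardioversion whose effect will not last exposes
the patient to anesthesia and thromboembolic risk for no benefit, so a
pre-procedural estimate of the chance that SR will hold is clinically
valuable. Two families of ECG markers carry that information:

* **Atrial activity.** After the ventricular QRS-T complexes are removed,
  the remaining fibrillatory (f-) waves are characterized in the 3–15 Hz
  band by their **dominant frequency** (DF, frequency of the highest
  spectral peak — lower DF means slower, more organized fibrillation),
  **regularity index** (RI, fraction of band energy at the DF peak),
  **organizational index** (OI, fraction of band energy at the DF peak
  plus its harmonics) and **Q2**, the quality factor of the DF peak
  measured 2 dB below its maximum (DF divided by the −2 dB peak width).
* **Ventricular activity.** The 12-lead ECG is reduced to orthogonal
  vectorcardiographic (VCG) leads X/Y/Z by the Kors regression transform;
  after 0.5–40 Hz band-pass filtering and R-peak-aligned beat averaging,
  three slope features are read from the central-difference derivative in
  morphology-adapted windows: **dXmean** (before the QRS), **dYmean**
  (inside the QRS) and **dZmean** (between QRS offset and T-wave onset).

The modelling stage standardizes the features, splits patients 60/40 into
training and testing parts, selects features by L1-penalized (LASSO)
logistic regression with stratified 5-fold cross-validation, refits each
candidate support without penalty, chooses the final model by AIC (training
AUC as a tie-break), and reports the test-set AUC.

Because no patient data are distributed with studies of this kind, the
package ships a first-class synthetic-data module: AF ECGs composed of a
sawtooth-harmonic f-wave with known dominant frequency, a Gaussian-bump
QRS-T train with analytically known fiducials at irregular (log-normal) RR
intervals, and white noise; and patient cohorts whose binary outcome is
drawn from a logistic model with known per-feature log-odds ratios. Every
stage of the pipeline is therefore testable against exact ground truth.

## Worked example

```python
from afecv import (AfEcgConfig, FWaveConfig, generate_af_ecg, detect_qrs,
                   delineate_qrst, extract_spectral_features)
from afecv.vcg import extract_vcg_features

cfg = AfEcgConfig(seed=42, fwave=FWaveConfig(f0=6.5))
rec, truth = generate_af_ecg(cfg)             # 12-lead, 10 s @ 1000 Hz
ann = delineate_qrst(rec, detect_qrs(rec, "II"), "II")
spec = extract_spectral_features(rec, ann, cancel_before_wt=True)
vcg = extract_vcg_features(rec, ann)
```

prints (via the obvious formatting loop):

```
  V1_WT_DF: 6.475
  V1_WT_Q2: 88.694
  V2_WT_RI: 0.440
 aVR_WT_OI: 0.485
  II_SP_DF: 6.475
    dXmean: -2.987 mV/s
    dYmean: -35.598 mV/s
    dZmean: -2.259 mV/s
```

Both DF estimates land within 0.03 Hz of the configured 6.5 Hz f-wave
frequency — the QRST cancellation and the wavelet band-limiting recover the
atrial rate despite the ventricular complexes being an order of magnitude
larger. The naming convention is `Lead_Method_Parameter`: `WT` features
come from the maximal-overlap-wavelet band (≈3.9–15.6 Hz, level-7 detail
bands 6+7), `SP` features from the direct amplitude spectrum of the
cancelled signal.

Fitting the prediction model on a synthetic 80-patient cohort:

```python
from afecv import SinusRhythmModel
from afecv.synth import default_cohort_config, generate_cohort

cohort = generate_cohort(default_cohort_config(n_patients=80, seed=7))
results = SinusRhythmModel(cohort.table).fit(seed=7)
print(results.summary())
```

```
Sinus-rhythm maintenance model (LASSO-selected, ML refit)
==========================================================
n train / test:      48 / 32 (seed 7)
penalty (CV-opt):    lambda = 0.04216
selected features:   V1_WT_DF, V1_WT_Q2, V2_WT_RI, dYmean, dZmean, age
AIC (train):         40.96
AUC train / test:    0.958 / 0.695
----------------------------------------------------------
term                coef        se        OR
const              0.136     0.512
V1_WT_DF          -1.490     0.837     0.225
V1_WT_Q2          -0.783     0.547     0.457
V2_WT_RI           0.852     0.537     2.344
dYmean            -3.940     1.582     0.019
dZmean            -3.010     1.108     0.049
age                2.015     0.903     7.504
```

Coefficients are log-odds of SR maintenance per SD of each feature
(odds ratios in the last column); the gap between training and test AUC at
n = 80 is the expected small-sample optimism. `results.plot_roc()` draws
the test-set ROC curve; `results.predict(new_table)` scores new patients.

A command-line interface covers the same chain on CSV files:

```bash
afecv simulate ecg --n 5 --seed 1 --out recs/
afecv delineate --in recs/rec000.csv --out ann.csv
afecv features spectral --in recs/rec000.csv --ann ann.csv --out spec.csv
afecv features vcg --in recs/rec000.csv --ann ann.csv --out vcg.csv
afecv simulate cohort --n 80 --seed 1 --out cohort.csv
afecv model fit --in cohort.csv --seed 1 --out report.json
afecv run --seed 1 --out study/          # full 80-record pipeline
```

## Layout

```
src/afecv/
  recording.py   EcgRecording / BeatAnnotation / AtrialSignal containers
  synth.py       AF ECG and cohort generators with ground truth
  delineate.py   QRS detection, QRST delineation, zero-replacement
  spectral.py    amplitude spectrum, MODWT band, DF/RI/OI/Q2, features
  vcg.py         Kors transform, beat averaging, slope features
  model.py       SinusRhythmModel / SinusRhythmResults (selection protocol)
  pipeline.py    simulate_study / run_pipeline orchestration
  io.py, cli.py  CSV formats and the `afecv` command
docs/methods.md  model assumptions, parameter choices, limitations
```
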