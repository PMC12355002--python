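# Methods

This note records the models behind `afecv`, the parameter choices that
matter, and what the synthetic data do and do not establish.

## Synthetic AF ECG

The generator composes each lead as *QRS-T train + f-wave + white noise*.

**Fibrillatory wave.** A sawtooth-like harmonic series: harmonic k at
frequency k·f0 with amplitude `harmonic_amps[k-1]` (default 0.08, 0.04,
0.02 mV — a 1/k decay; f-wave amplitudes of 0.05–0.15 mV follow common AF
practice, as no population statistics are available to copy). Slow
sinusoidal frequency modulation makes the line spectrum realistic; the
phase term is scaled so that the instantaneous frequency oscillates in
exactly f0 ± `fm_depth` (defaults: depth 0.1 Hz, rate 0.1 Hz — a mild
wander that leaves the dominant peak identifiable, as in real AF where the
atrial rate drifts by tenths of a hertz over seconds). An optional
random-walk phase jitter is off by default, so the generator is
deterministic given its config.

**Ventricular activity.** Each beat is a sum of four Gaussian bumps
(Q, R, S, T) with fixed centres/widths and per-lead gains; fiducials are
fixed offsets from the R peak that bracket essentially all bump energy:
QRS onset −65 ms, offset +65 ms, T end +360 ms (QT ≈ 425 ms, QTc ≈ 490 ms
at the default 80 bpm — long-normal, as expected in an elderly AF
population). The eight independent leads (I, II, V1–V6) are synthesized
directly and the four derived limb leads follow the Einthoven/Goldberger
identities, so the clean 12-lead set is internally consistent; white noise
(default SD 0.02 mV) is then added per lead independently. Beats are
placed at log-normal RR intervals (mean 0.75 s, CV 0.18 — AF-grade
irregularity with negligible autocorrelation) and snapped to the sample
grid so the ground-truth fiducials are exact.

**Cohort.** Features are drawn as independent Gaussians (or Bernoullis),
and the outcome (1 = SR maintenance at 3 months) follows
`Bernoulli(logistic(intercept + beta · z))` where z are the features
standardized with their *generating* parameters — `beta` is therefore
exactly the log-odds ratio per SD, which the recovery tests refit. The
default study-like cohort uses the published univariate effect directions
(DF-type features favourable to maintenance, dY/dZ slopes protective when
low) at half their univariate magnitude for joint use, and null clinical
covariates.

What the generator does *not* emulate: per-lead QRS morphology changes
(only gains differ), ectopy, baseline wander (available behind a flag but
off), electrode artefacts, respiration, or correlated features in the
cohort. Passing tests therefore demonstrate correctness of the signal
processing and estimation machinery under controlled conditions, not
clinical performance on real recordings.

## Delineation and QRST cancellation

The detector band-passes 10–30 Hz, squares, smooths over 120 ms and
thresholds at 20% of the 99th-percentile envelope with a 200 ms refractory
constraint; R peaks are refined to the local extremum of the band-passed
signal. QRS borders come from a derivative-threshold search: the absolute
smoothed derivative must stay below max(3% of the beat's peak derivative,
2× the record's median absolute derivative) for 10 ms — the median floor
keeps the search from drifting into f-wave slopes. The T-wave end uses an
apex-anchored rule: the T apex is located on a 6 Hz zero-phase low-pass
(a symmetric filter does not move a symmetric peak, so the apex is immune
to smearing and to f-wave interference), and T end is placed at
`apex + 0.8 · (apex − QRS offset)` — a ≈3σ endpoint for a roughly
symmetric T. A slope-threshold T-end search was tried first and abandoned:
the low-pass needed to suppress f-waves (which share the T band) smears
the T tail by 50–100 ms, biasing any threshold crossing. When no T apex
stands out (amplitude ≤ 2× the median of the low-passed signal), the
fallback is `offset + 0.35 · RR`. Consecutive segments are clipped to
non-overlap.

Cancellation zero-replaces the closed interval [QRS onset, T end]
(0-based samples) and mean-centers each remaining maximal segment;
segments shorter than 50 ms are zeroed instead (too short to estimate a
mean). Fiducials are computed once on a reference lead (default II) and
reused across leads. On default synthetic records the residual ventricular
energy in 3–15 Hz is ~0.5% of the ventricular-only band energy.

## Spectral analysis

One full-length DFT magnitude of the whole series (zeros included), with
8× zero-padding purely to refine the frequency grid for peak readout — no
Welch averaging, since 10 s yields a single 0.1 Hz-resolution spectrum and
the parameters are defined on one spectrum. Energy is the sum of squared
amplitudes over bins. RI/OI integrate a ±0.5 Hz window around the DF (and
its 2nd/3rd harmonics for OI, truncated at 15 Hz); the half-width is
configurable and the index identities hold for 0.25/0.5/1.0 Hz. Q2 locates
the −2 dB (amplitude scale by default; power-scale by flag) crossings by
linear interpolation between bins; a peak running into a band edge is
flagged. Ties in the DF argmax resolve to the lower frequency.

The wavelet path computes a shift-invariant (maximal-overlap) wavelet
multiresolution analysis at level 7 with the length-8 least-asymmetric
filter, via `pywt.mra(..., transform='swt')` with symmetric padding to a
multiple of 2^7, and sums detail levels 7 and 6 (≈3.9–15.6 Hz at 1000 Hz —
the atrial band; the level-7 smooth is excluded because it contains DC).
WT features default to the raw lead; the pipeline applies QRST
cancellation first (`cancel_before_wt=True`), because on leads with weaker
f-waves (V2, aVR) the raw ventricular energy inside 3.9–15.6 Hz can
otherwise dominate the band.

## Vectorcardiography

Kors regression matrix by default (better validated against true Frank
leads than the inverse Dower alternative, which is also provided);
0.5–40 Hz zero-phase 4-pole Butterworth; beats averaged over
[R − 0.3 s, R + 0.5 s] windows with median per-beat fiducials; central
differences with one-sided endpoints. Slope windows anchor at the maximal
absolute derivative in each axis's region (pre-QRS for X, QRS for Y,
QRS-offset-to-T-onset for Z, with T onset estimated as
offset + 0.25 · median RR since the delineator marks T end) and expand
while the derivative stays ≥ α = 0.5 of the regional maximum; features are
the *signed* mean derivative over the window (an `--abs` flag gives the
unsigned variant). Feature values scale exactly linearly with the
recording, and the test suite reports their sensitivity to
α ∈ {0.3, 0.5, 0.7}.

## Modelling protocol

Split first (stratified, train size = round(0.6·n)), then standardize
continuous columns on the training part only and apply those parameters to
the test part; binary columns pass through. The L1 path uses a 40-point
log-spaced penalty grid from just above the data's λ_max down to
10⁻³·λ_max (liblinear, C = 1/(n·λ)); the CV criterion is mean validation
binomial deviance over stratified, seeded 5 folds. The selection rule
defaults to **1-SE** (sparsest penalty within one between-fold standard
error of the minimum): with the minimum-deviance rule the selected set
retains a median of three null features out of seven in 400-patient
simulations, defeating the purpose of a selection stage; the 1-SE rule
keeps all strong features and almost no nulls. `rule="min"` is available.
Perfectly duplicated columns are dropped from the path (the L1 solution is
otherwise non-unique).

Candidate models are the distinct supports along the path; each is refitted
by unpenalized maximum likelihood (AIC is only well defined for ML fits).
The final model minimizes AIC; among candidates within 2 AIC points,
higher training AUC wins — with AUC differences under 0.01 treated as
ties resolved toward the smaller support, because a nested superset's
in-sample AUC is almost surely trivially higher and the parsimony penalty
could otherwise never act. Perfect separation falls back to a
ridge-stabilized fit, flagged in the results. Test-set AUC is the
Mann–Whitney statistic (ties counted ½) of the linear score, so it is
invariant to monotone transforms. Univariate odds ratios are per-SD with
Wald 95% CIs; baseline group comparisons use Student's t under a
Shapiro–Wilk normality screen (else Mann–Whitney U) for continuous
variables and χ² (Fisher's exact when any expected cell count is below 5)
for binary ones.

## Numerical and degenerate-input conventions

All-zero or flat records yield an empty detection list, not an error; an
all-zero band spectrum raises a no-dominant-peak error that feature
extraction re-raises with context. A flat derivative region returns the
whole region as the slope window with a warning. CV folds are clamped to
the minority-class count with a warning. Seeds: every artifact takes one
master seed, split deterministically into per-component streams
(`numpy.random.SeedSequence.spawn`), so identical configs reproduce
byte-identical outputs.

## Problem sizes

The shipped checks use the study's natural scales: 10 s, 1000 Hz, 12-lead
records; 100 records for dominant-frequency recovery; 1000 random spectra
for the index identities; cohorts of 80 (study scale), 400 (selection) and
10 000 (consistency); 20 seeds for the selection and sign-pattern checks;
and the 80-record end-to-end study. The acceptance script completes in
about a minute on one CPU.

## Known limitations

Independent cohort features ignore the real correlation between spectral
indices; the QRS-T template family cannot produce biphasic T waves or
bundle-branch morphologies, so the delineator's tolerances are calibrated
on a narrower morphology class than clinical data; the T-end rule assumes
an approximately symmetric T wave; and with 32-patient test sets the test
AUC itself carries a sampling SD near 0.09, which is why the end-to-end
check compares it against a Monte-Carlo interval of the generating model's
achievable AUC rather than a point value.
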