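"""Synthetic AF ECG and patient-cohort generators with known ground truth.

The ECG generator composes three parts that mirror what a surface ECG of
atrial fibrillation contains:

* a fibrillatory wave — a sawtooth-like harmonic series at a dominant
  frequency f0 in the atrial band, optionally frequency-modulated, which is
  what the spectral pipeline must recover;
* a ventricular QRS-T train — per-lead sums of Gaussian bumps placed at
  irregular (log-normal) RR intervals, with analytically known fiducials;
* additive white measurement noise (plus an optional baseline-wander tone).

The cohort generator draws a patient-by-feature table and a binary outcome
(1 = sinus-rhythm maintenance at 3 months) from a logistic model with
configurable per-feature log-odds ratios, so that estimation stages can be
tested against the exact generating coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import (
    STANDARD_LEADS,
    BeatAnnotation,
    EcgRecording,
)

__all__ = [
    "FWaveConfig",
    "QrstTemplate",
    "AfEcgConfig",
    "GroundTruth",
    "FeatureSpec",
    "CohortConfig",
    "SyntheticCohort",
    "generate_fwave",
    "generate_af_ecg",
    "generate_cohort",
    "default_cohort_config",
]


# --------------------------------------------------------------------------
# fibrillatory wave
# --------------------------------------------------------------------------

@dataclass
class FWaveConfig:
    """Sawtooth-harmonic model of the fibrillatory wave.

    ``harmonic_amps[k]`` is the amplitude (mV) of the harmonic at
    ``(k + 1) * f0``; a 1/k decay imitates the sawtooth shape of f-waves.
    ``fm_depth``/``fm_rate`` add slow sinusoidal frequency modulation
    (Hz of peak deviation / Hz of modulation), the standard way to make a
    simulated f-wave spectrally realistic rather than a pure line spectrum.
    ``phase_jitter`` (Hz RMS) enables a stochastic random-walk phase
    perturbation; only then does the seed matter.
    """

    f0: float = 6.0
    harmonic_amps: tuple = (0.08, 0.04, 0.02)
    fm_depth: float = 0.10
    fm_rate: float = 0.10
    phase0: float = 0.0
    phase_jitter: float = 0.0

    def __post_init__(self):
        if not (3.0 <= self.f0 <= 12.0):
            raise ValueError(f"f0 must lie in [3, 12] Hz, got {self.f0}")
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.fm_depth < 0:
            raise ValueError("fm_depth must be >= 0")
        if self.fm_depth > 0 and self.fm_rate <= 0:
            raise ValueError("fm_rate must be > 0 when fm_depth > 0")


def generate_fwave(cfg: FWaveConfig, duration: float, fs: float,
                   seed: int | None = None) -> np.ndarray:
    """Generate the atrial (f-wave) signal in mV.

    The instantaneous cycle count of harmonic k is
    ``k*(f0*t + (fm_depth / (2*pi*fm_rate))*sin(2*pi*fm_rate*t))`` so the
    instantaneous frequency of the fundamental oscillates in
    ``f0 +/- fm_depth`` exactly.  Deterministic unless ``phase_jitter > 0``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    n = round(duration * fs)
    t = np.arange(n) / fs
    base = cfg.f0 * t
    if cfg.fm_depth > 0:
        base = base + (cfg.fm_depth / (2 * np.pi * cfg.fm_rate)) * np.sin(
            2 * np.pi * cfg.fm_rate * t)
    if cfg.phase_jitter > 0:
        rng = np.random.default_rng(seed)
        # integrate white frequency jitter (SD phase_jitter Hz per sample)
        base = base + np.cumsum(rng.normal(0.0, cfg.phase_jitter, n)) / fs
    sig = np.zeros(n)
    for k, amp in enumerate(cfg.harmonic_amps, start=1):
        if amp:
            sig += amp * np.sin(2 * np.pi * k * base + cfg.phase0)
    return sig


# --------------------------------------------------------------------------
# ventricular template and full recording
# --------------------------------------------------------------------------

# Gaussian bump centres/widths in seconds relative to the R peak and the
# canonical (lead II) amplitudes in mV.  Fiducials are fixed offsets chosen
# to bracket essentially all bump energy (>=2 sigma beyond the outer bumps).
_BUMPS = {          # centre s, sigma s, amplitude mV
    "Q": (-0.040, 0.010, -0.10),
    "R": (0.000, 0.012, 1.00),
    "S": (0.040, 0.010, -0.20),
    "T": (0.230, 0.045, 0.30),
}
_QRS_ON_OFFSET = -0.065     # s before R
_QRS_OFF_OFFSET = 0.065     # s after R
_T_END_OFFSET = 0.360       # s after R

#: QRS-T gain per independent lead (unitless multiplier of the canonical
#: template); rough precordial progression, no per-lead morphology change.
DEFAULT_QRST_LEAD_GAINS = {
    "I": 0.5, "II": 1.0, "V1": 0.6, "V2": 0.9,
    "V3": 1.1, "V4": 1.2, "V5": 1.0, "V6": 0.8,
}

#: f-wave gain per independent lead; largest in V1 as on real AF ECGs.
DEFAULT_FWAVE_LEAD_GAINS = {
    "I": 0.3, "II": 0.5, "V1": 1.0, "V2": 0.8,
    "V3": 0.5, "V4": 0.4, "V5": 0.35, "V6": 0.3,
}


@dataclass
class QrstTemplate:
    """Per-lead QRS-T shape: one canonical sum of Gaussian bumps scaled by a
    per-lead gain.  ``amp_scale`` scales the whole ventricular complex;
    ``t_amp_scale`` additionally scales only the T bump (it shapes the
    QRS-to-T slope that the VCG dZmean feature measures)."""

    lead_gains: dict = field(
        default_factory=lambda: dict(DEFAULT_QRST_LEAD_GAINS))
    amp_scale: float = 1.0
    t_amp_scale: float = 1.0

    @property
    def span(self) -> float:
        """Seconds from QRS onset to T end."""
        return _T_END_OFFSET - _QRS_ON_OFFSET

    def waveform(self, t_rel: np.ndarray, lead: str) -> np.ndarray:
        """Template voltage at times ``t_rel`` (s, relative to R peak)."""
        g = self.lead_gains[lead] * self.amp_scale
        out = np.zeros_like(t_rel, dtype=float)
        for name, (c, w, a) in _BUMPS.items():
            amp = a * g * (self.t_amp_scale if name == "T" else 1.0)
            out += amp * np.exp(-0.5 * ((t_rel - c) / w) ** 2)
        return out


@dataclass
class AfEcgConfig:
    """Everything needed to simulate one 12-lead AF recording.

    Defaults follow a standard resting acquisition: 10 s at 1000 Hz, mean RR
    0.75 s (80 bpm) with coefficient of variation 0.18 (AF irregularity),
    0.02 mV white noise.
    """

    duration: float = 10.0
    fs: float = 1000.0
    rr_mean: float = 0.75
    rr_cv: float = 0.18
    qrst_template: QrstTemplate = field(default_factory=QrstTemplate)
    fwave: FWaveConfig = field(default_factory=FWaveConfig)
    fwave_lead_gains: dict = field(
        default_factory=lambda: dict(DEFAULT_FWAVE_LEAD_GAINS))
    noise_sd: float = 0.02
    baseline_wander_amp: float = 0.0   # mV at 0.25 Hz, off by default
    seed: int = 0

    def __post_init__(self):
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or self.duration <= 0:
            raise ValueError("duration * fs must be a positive integer")
        if not (0.3 <= self.rr_mean <= 2.0):
            raise ValueError("rr_mean must lie in [0.3, 2.0] s")
        if self.rr_cv <= 0:
            raise ValueError("rr_cv must be positive (AF is irregular)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rr_mean < self.qrst_template.span * 0.75:
            raise ValueError(
                f"rr_mean {self.rr_mean} s too small to fit a "
                f"{self.qrst_template.span:.2f} s QRS-T template")


@dataclass
class GroundTruth:
    """What the generator knows exactly: the atrial-only signal per lead,
    every placed beat's fiducials, and the generating config."""

    true_fwave: np.ndarray          # (n_leads, n_samples) mV
    true_beats: BeatAnnotation
    config: AfEcgConfig


def _lognormal_rr(rng: np.random.Generator, mean: float, cv: float,
                  n: int) -> np.ndarray:
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def _derive_limb_leads(ind: dict) -> dict:
    """Fill III, aVR, aVL, aVF from I and II (Einthoven/Goldberger)."""
    out = dict(ind)
    out["III"] = ind["II"] - ind["I"]
    out["aVR"] = -(ind["I"] + ind["II"]) / 2.0
    out["aVL"] = ind["I"] - ind["II"] / 2.0
    out["aVF"] = ind["II"] - ind["I"] / 2.0
    return out


def generate_af_ecg(cfg: AfEcgConfig) -> tuple[EcgRecording, GroundTruth]:
    """Simulate a 12-lead AF ECG and return it with its ground truth.

    The recording is (per lead) QRS-T template train + gain * f-wave +
    white noise; limb leads III/aVR/aVL/aVF are derived from I and II before
    noise is added, so the clean leads satisfy the Einthoven identities.
    Bit-identical for identical config (the seed lives in the config).
    """
    n = round(cfg.duration * cfg.fs)
    t = np.arange(n) / cfg.fs
    ss = np.random.SeedSequence(cfg.seed)
    rr_rng, noise_rng, fwave_rng = (np.random.default_rng(s)
                                    for s in ss.spawn(3))

    # --- beat placement ---------------------------------------------------
    max_beats = int(cfg.duration / cfg.rr_mean * 3) + 10
    rr = _lognormal_rr(rr_rng, cfg.rr_mean, cfg.rr_cv, max_beats)
    first_r = -_QRS_ON_OFFSET + 0.05          # first onset just inside record
    r_times = first_r + np.concatenate(([0.0], np.cumsum(rr)))
    r_times = r_times[r_times + _T_END_OFFSET < cfg.duration - 1.0 / cfg.fs]
    # snap beats to the sample grid so the fiducials are exact
    r_times = np.round(r_times * cfg.fs) / cfg.fs

    tpl = cfg.qrst_template
    ventr = {}
    for lead in DEFAULT_QRST_LEAD_GAINS:
        sig = np.zeros(n)
        for r in r_times:
            lo = max(0, int((r - 0.15) * cfg.fs))
            hi = min(n, int((r + 0.60) * cfg.fs))
            sig[lo:hi] += tpl.waveform(t[lo:hi] - r, lead)
        ventr[lead] = sig
    ventr = _derive_limb_leads(ventr)

    # --- f-wave -----------------------------------------------------------
    base_fw = generate_fwave(
        cfg.fwave, cfg.duration, cfg.fs,
        seed=int(fwave_rng.integers(2 ** 31)))
    gains = dict(cfg.fwave_lead_gains)
    fw_ind = {lead: gains[lead] * base_fw for lead in DEFAULT_QRST_LEAD_GAINS}
    fw = _derive_limb_leads(fw_ind)

    # --- compose ----------------------------------------------------------
    signals = np.empty((len(STANDARD_LEADS), n))
    true_fw = np.empty_like(signals)
    wander = (cfg.baseline_wander_amp *
              np.sin(2 * np.pi * 0.25 * t) if cfg.baseline_wander_amp else 0.0)
    for i, lead in enumerate(STANDARD_LEADS):
        clean = ventr[lead] + fw[lead] + wander
        noise = (noise_rng.normal(0.0, cfg.noise_sd, n)
                 if cfg.noise_sd > 0 else 0.0)
        signals[i] = clean + noise
        true_fw[i] = fw[lead]

    r_idx = np.round(r_times * cfg.fs).astype(np.int64)
    beats = BeatAnnotation(
        qrs_onset=np.clip(r_idx + round(_QRS_ON_OFFSET * cfg.fs), 0, n - 1),
        r_peak=r_idx,
        qrs_offset=np.clip(r_idx + round(_QRS_OFF_OFFSET * cfg.fs), 0, n - 1),
        t_end=np.clip(r_idx + round(_T_END_OFFSET * cfg.fs), 0, n - 1),
    )
    rec = EcgRecording(signals, cfg.fs, STANDARD_LEADS)
    return rec, GroundTruth(true_fwave=true_fw, true_beats=beats, config=cfg)


# --------------------------------------------------------------------------
# synthetic patient cohort
# --------------------------------------------------------------------------

@dataclass
class FeatureSpec:
    """One cohort column: continuous ~ Normal(mean, sd) or binary ~
    Bernoulli(p)."""

    name: str
    kind: str = "continuous"            # "continuous" | "binary"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "continuous" and self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.kind == "binary" and not (0 < self.p < 1):
            raise ValueError(f"{self.name}: p must be in (0, 1)")


@dataclass
class CohortConfig:
    """Generating model of the synthetic cohort.

    ``beta[j]`` is the log-odds ratio of feature j on the standardized scale
    (continuous features are z-scored with their generating mean/sd before
    entering the linear predictor; binary features enter as 0/1).  The
    outcome is 1 = sinus-rhythm maintenance.
    """

    n_patients: int
    feature_specs: list
    beta: tuple
    intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if len(self.beta) != len(self.feature_specs):
            raise ValueError(
                f"{len(self.beta)} betas for {len(self.feature_specs)} features")


@dataclass
class SyntheticCohort:
    """Generated table plus the generating coefficients for recovery tests."""

    table: pd.DataFrame                 # features + 'outcome'
    beta: np.ndarray                    # per standardized feature
    intercept: float
    feature_specs: list

    @property
    def feature_names(self) -> list:
        return [s.name for s in self.feature_specs]


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Draw features and a Bernoulli outcome from the logistic model."""
    rng = np.random.default_rng(cfg.seed)
    cols, z = {}, []
    for spec in cfg.feature_specs:
        if spec.kind == "continuous":
            x = rng.normal(spec.mean, spec.sd, cfg.n_patients)
            z.append((x - spec.mean) / spec.sd)
        else:
            x = rng.binomial(1, spec.p, cfg.n_patients).astype(float)
            z.append(x)
        cols[spec.name] = x
    eta = cfg.intercept + np.column_stack(z) @ np.asarray(cfg.beta, float)
    pr = 1.0 / (1.0 + np.exp(-eta))
    outcome = rng.binomial(1, pr)
    table = pd.DataFrame(cols)
    table["outcome"] = outcome
    return SyntheticCohort(table, np.asarray(cfg.beta, float),
                           cfg.intercept, list(cfg.feature_specs))


def default_cohort_config(n_patients: int = 80, seed: int = 0) -> CohortConfig:
    """Study-like cohort: the 5 spectral + 3 VCG features plus two clinical
    covariates.

    Feature scales imitate plausible pre-cardioversion measurements (DF in
    Hz, indices in (0,1), slopes in mV/s, age in years, LA diameter in mm);
    effect directions and magnitudes follow the reported univariate odds
    ratios for sinus-rhythm maintenance (e.g. OR 3.54 per SD for II_SP_DF,
    OR 0.18 for dZmean), scaled down jointly so the combined model keeps a
    realistic discrimination; the clinical covariates carry no effect.
    """
    specs = [
        FeatureSpec("II_SP_DF", mean=6.3, sd=1.0),
        FeatureSpec("V1_WT_DF", mean=6.3, sd=1.0),
        FeatureSpec("V1_WT_Q2", mean=12.0, sd=4.0),
        FeatureSpec("V2_WT_RI", mean=0.45, sd=0.12),
        FeatureSpec("aVR_WT_OI", mean=0.55, sd=0.12),
        FeatureSpec("dXmean", mean=0.5, sd=0.8),
        FeatureSpec("dYmean", mean=8.0, sd=3.0),
        FeatureSpec("dZmean", mean=-2.0, sd=1.5),
        FeatureSpec("age", mean=70.2, sd=10.6),
        FeatureSpec("la_diameter", mean=44.7, sd=6.3),
    ]
    # half the univariate log-ORs, joint use; zeros on the clinical columns
    univ = {
        "II_SP_DF": math.log(3.54), "V1_WT_DF": math.log(0.21),
        "V1_WT_Q2": math.log(0.28), "V2_WT_RI": math.log(2.84),
        "aVR_WT_OI": math.log(3.54), "dXmean": math.log(2.84),
        "dYmean": math.log(0.23), "dZmean": math.log(0.18),
        "age": 0.0, "la_diameter": 0.0,
    }
    beta = tuple(0.5 * univ[s.name] for s in specs)
    return CohortConfig(n_patients=n_patients, feature_specs=specs,
                        beta=beta, intercept=0.2, seed=seed)
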