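"""End-to-end orchestration: simulate a study, extract features, fit.

``simulate_study`` generates a cohort of synthetic AF recordings whose
generator parameters vary across patients (dominant frequency, harmonic
content, frequency-modulation depth, QRS-T amplitudes, heart rate), runs
the full feature-extraction chain on every record, appends clinical
covariates, and draws the binary outcome from a known logistic model on the
standardized measured features — so the whole pipeline can be exercised and
its modelling stage judged against a known generating model.

``run_pipeline`` wraps simulation + modelling behind a validated
configuration and writes CSV/JSON reports; rerunning with the same
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delineate import delineate_qrst, detect_qrs
from .model import SinusRhythmModel, standardize
from .spectral import extract_spectral_features
from .synth import AfEcgConfig, FWaveConfig, QrstTemplate, generate_af_ecg
from .vcg import extract_vcg_features

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyTruth", "simulate_study", "extract_features",
           "run_pipeline", "DEFAULT_STUDY_BETA"]

FEATURE_COLUMNS = ["V1_WT_DF", "V1_WT_Q2", "V2_WT_RI", "aVR_WT_OI",
                   "II_SP_DF", "dXmean", "dYmean", "dZmean"]
CLINICAL_COLUMNS = ["age", "la_diameter"]

#: Generating log-odds ratios (per SD of the measured feature) of the
#: simulated study outcome.  Directions follow the reported univariate
#: pattern (higher dominant frequency favours maintenance in the printed
#: table; lower dY/dZ slopes favour recurrence); clinical covariates are
#: null effects.  Magnitudes are half the univariate log-ORs so the joint
#: model keeps a realistic discrimination.
DEFAULT_STUDY_BETA = {
    "V1_WT_DF": 0.5 * math.log(0.21),
    "V1_WT_Q2": 0.5 * math.log(0.28),
    "V2_WT_RI": 0.5 * math.log(2.84),
    "aVR_WT_OI": 0.5 * math.log(3.54),
    "II_SP_DF": 0.5 * math.log(3.54),
    "dXmean": 0.5 * math.log(2.84),
    "dYmean": 0.5 * math.log(0.23),
    "dZmean": 0.5 * math.log(0.18),
    "age": 0.0,
    "la_diameter": 0.0,
}


@dataclass
class RunConfig:
    """Validated configuration of the full pipeline.

    Defaults are the protocol's stated constants: 10 s records at 1000 Hz,
    3-15 Hz atrial band, MODWT level 7, 0.5-40 Hz ventricular band-pass,
    60/40 split, 5 CV folds.
    """

    out_dir: str = "afecv_run"
    n_records: int = 80
    duration: float = 10.0
    fs: float = 1000.0
    band: tuple = (3.0, 15.0)
    modwt_level: int = 7
    modwt_wavelet: str = "sym4"
    peak_halfwidth: float = 0.5
    vcg_matrix: str = "kors"
    window_alpha: float = 0.5
    bandpass: tuple = (0.5, 40.0)
    train_frac: float = 0.6
    n_folds: int = 5
    lambda_ratio: float = 1e-3
    n_lambdas: int = 40
    delineation_lead: str = "II"
    use_ground_truth_beats: bool = False
    cancel_before_wt: bool = True
    seed: int = 0
    beta: dict = field(default_factory=lambda: dict(DEFAULT_STUDY_BETA))
    intercept: float = 0.2

    def __post_init__(self):
        if self.n_records < 10:
            raise ValueError("n_records must be >= 10")
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(f"band {self.band} outside (0, fs/2)")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.modwt_level < 2:
            raise ValueError("modwt_level must be >= 2")
        unknown = set(self.beta) - set(FEATURE_COLUMNS + CLINICAL_COLUMNS)
        if unknown:
            raise ValueError(f"beta refers to unknown features {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("band", "bandpass"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(d["band"])
        d["bandpass"] = list(d["bandpass"])
        return d


@dataclass
class StudyTruth:
    """Generator-side knowledge of the simulated study: per-record f-wave
    dominant frequencies, the generating coefficients on the standardized
    measured features, and the linear predictor used to draw outcomes."""

    f0: np.ndarray
    beta: dict
    intercept: float
    eta: np.ndarray


def _patient_ecg_config(rng: np.random.Generator, cfg: RunConfig,
                        seed: int) -> AfEcgConfig:
    """Per-patient variation of the ECG generator's parameters."""
    f0 = float(np.clip(rng.normal(6.3, 0.9), 4.2, 9.0))
    amp1 = float(rng.uniform(0.06, 0.12))
    ratio = float(rng.uniform(0.25, 0.6))
    fm_depth = float(rng.uniform(0.05, 0.35))
    fwave = FWaveConfig(f0=f0,
                        harmonic_amps=(amp1, amp1 * ratio,
                                       amp1 * ratio ** 2),
                        fm_depth=fm_depth, fm_rate=0.1,
                        phase0=float(rng.uniform(0, 2 * np.pi)))
    tpl = QrstTemplate(amp_scale=float(np.clip(rng.normal(1.0, 0.15),
                                               0.6, 1.5)),
                       t_amp_scale=float(np.clip(rng.normal(1.0, 0.20),
                                                 0.4, 1.8)))
    return AfEcgConfig(
        duration=cfg.duration, fs=cfg.fs,
        rr_mean=float(np.clip(rng.normal(0.75, 0.08), 0.55, 1.1)),
        rr_cv=float(np.clip(rng.normal(0.18, 0.04), 0.08, 0.35)),
        qrst_template=tpl, fwave=fwave, seed=seed)


def extract_features(rec, truth, cfg: RunConfig) -> dict:
    """Delineate one record and return its 5 spectral + 3 VCG features."""
    if cfg.use_ground_truth_beats:
        ann = truth.true_beats
    else:
        peaks = detect_qrs(rec, cfg.delineation_lead)
        ann = delineate_qrst(rec, peaks, cfg.delineation_lead)
    spec = extract_spectral_features(
        rec, ann, band=cfg.band, peak_halfwidth=cfg.peak_halfwidth,
        cancel_before_wt=cfg.cancel_before_wt)
    vcg = extract_vcg_features(rec, ann, matrix=cfg.vcg_matrix,
                               alpha=cfg.window_alpha)
    return {**spec.to_dict(), **vcg.to_dict()}


def simulate_study(cfg: RunConfig) -> tuple[pd.DataFrame, StudyTruth]:
    """Simulate ``n_records`` patients end to end.

    Returns the cohort table (8 measured ECG features + 2 clinical
    covariates + outcome) and the ground truth of the generating model.
    The outcome is drawn from logistic(intercept + beta . z) where z are
    the measured features standardized over the simulated cohort, so the
    generating coefficients are exactly known on the scale the modelling
    stage uses.
    """
    ss = np.random.SeedSequence(cfg.seed)
    param_rng, clin_rng, outcome_rng = (np.random.default_rng(s)
                                        for s in ss.spawn(3))
    record_seeds = param_rng.integers(2 ** 31, size=cfg.n_records)

    rows, f0s = [], []
    for i in range(cfg.n_records):
        ecg_cfg = _patient_ecg_config(param_rng, cfg, int(record_seeds[i]))
        rec, truth = generate_af_ecg(ecg_cfg)
        feats = extract_features(rec, truth, cfg)
        rows.append(feats)
        f0s.append(ecg_cfg.fwave.f0)
    table = pd.DataFrame(rows)
    table["age"] = clin_rng.normal(70.2, 10.6, cfg.n_records).round(1)
    table["la_diameter"] = clin_rng.normal(44.7, 6.3, cfg.n_records).round(1)

    std, _ = standardize(table)
    beta = np.array([cfg.beta.get(c, 0.0) for c in table.columns])
    eta = cfg.intercept + std.to_numpy(float) @ beta
    table["outcome"] = outcome_rng.binomial(1, 1 / (1 + np.exp(-eta)))
    truth = StudyTruth(f0=np.asarray(f0s), beta=dict(cfg.beta),
                       intercept=cfg.intercept, eta=eta)
    return table, truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate, model, and write reports into ``cfg.out_dir``.

    Writes ``cohort.csv`` (features + outcome), ``model_report.json`` and
    ``roc_test.csv``; returns the report dict.  Deterministic for a fixed
    config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating %d records (seed %d)", cfg.n_records, cfg.seed)
    table, truth = simulate_study(cfg)
    table.to_csv(out / "cohort.csv", index=False, float_format="%.6g")

    model = SinusRhythmModel(table, outcome="outcome")
    results = model.fit(train_frac=cfg.train_frac, n_folds=cfg.n_folds,
                        seed=cfg.seed)
    report = {
        "version": __version__,
        "config": cfg.to_dict(),
        "n_records": cfg.n_records,
        "generating_beta": truth.beta,
        "model": results.to_report(),
    }
    with open(out / "model_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    results.roc_test.to_csv(out / "roc_test.csv", index=False,
                            float_format="%.6g")
    logger.info("selected %s; test AUC %.3f",
                results.selected_features, results.auc_test)
    return report
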