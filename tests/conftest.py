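import numpy as np
import pytest

from afecv.delineate import delineate_qrst, detect_qrs
from afecv.synth import AfEcgConfig, FWaveConfig, generate_af_ecg


@pytest.fixture(scope="session")
def af_record():
    """Default-condition AF recording (f0 = 6.5 Hz, default noise)."""
    cfg = AfEcgConfig(seed=3, fwave=FWaveConfig(f0=6.5))
    return generate_af_ecg(cfg)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free AF recording with mild RR irregularity."""
    cfg = AfEcgConfig(seed=5, noise_sd=0.0, rr_cv=0.10, rr_mean=0.8,
                      fwave=FWaveConfig(f0=6.5))
    return generate_af_ecg(cfg)


@pytest.fixture(scope="session")
def template_record():
    """Ventricular-only record: no f-wave, no noise (pure template train)."""
    cfg = AfEcgConfig(seed=7, noise_sd=0.0, rr_cv=0.10, rr_mean=0.8,
                      fwave=FWaveConfig(f0=6.0, harmonic_amps=(0.0,)))
    return generate_af_ecg(cfg)


@pytest.fixture(scope="session")
def af_annotation(af_record):
    rec, _ = af_record
    return delineate_qrst(rec, detect_qrs(rec, "II"), "II")


def match_beats(detected, truth_peaks, tol):
    """Greedy matching of detected to true peaks within tol samples;
    returns (n_matched, n_detected, n_true)."""
    detected = np.asarray(detected)
    used = np.zeros(len(truth_peaks), dtype=bool)
    matched = 0
    for p in detected:
        d = np.abs(truth_peaks - p)
        d[used] = tol + 1
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            matched += 1
    return matched, len(detected), len(truth_peaks)
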