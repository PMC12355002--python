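"""Vectorcardiographic slope features of ventricular activity.

The 12-lead ECG is reduced to three orthogonal leads X (right-left),
Y (head-feet) and Z (front-back) by a published linear transform of the 8
independent leads; the default is the Kors regression matrix, with the
inverse Dower matrix available.  After 0.5-40 Hz band-pass filtering an
average beat is built by aligning beats on the R peak, the beat is
differentiated by central differences, and three features are extracted as
the mean derivative inside per-axis windows that adapt to the beat's
morphology:

* dXmean — in the interval preceding the QRS onset,
* dYmean — inside the QRS complex,
* dZmean — between the QRS offset and the T-wave onset.

Each window is anchored at the sample of maximal absolute derivative in its
admissible region and expanded while the derivative stays above a fraction
``alpha`` of that maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import BeatAnnotation, EcgRecording

logger = logging.getLogger(__name__)

__all__ = [
    "VcgBeat", "VcgFeatureSet", "SlopeWindow", "DegenerateRegionError",
    "derive_vcg", "bandpass", "average_beat", "central_difference",
    "optimize_window", "vcg_slope_features", "extract_vcg_features",
    "KORS_MATRIX", "INVERSE_DOWER_MATRIX",
]

_VCG_INPUT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Kors regression matrix, rows X/Y/Z, columns I, II, V1..V6.
KORS_MATRIX = np.array([
    [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
    [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
    [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
])

#: Inverse Dower matrix, same layout.
INVERSE_DOWER_MATRIX = np.array([
    [0.156, -0.010, -0.172, -0.074, 0.122, 0.231, 0.239, 0.194],
    [-0.227, 0.887, 0.057, -0.019, -0.106, -0.022, 0.041, 0.048],
    [0.022, 0.102, -0.229, -0.310, -0.246, -0.063, 0.055, 0.108],
])

_MATRICES = {"kors": KORS_MATRIX, "dower": INVERSE_DOWER_MATRIX}

#: Averaged-beat window around the R peak, seconds.
BEAT_WINDOW = (-0.3, 0.5)

#: Window-expansion threshold as a fraction of the regional maximum slope.
DEFAULT_ALPHA = 0.5


class DegenerateRegionError(ValueError):
    """An axis's admissible search region is empty."""


@dataclass
class SlopeWindow:
    """Half-open sample range [start, end) inside the averaged beat."""

    axis: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must precede end")


@dataclass
class VcgBeat:
    """One averaged beat in X/Y/Z with fiducials as window offsets."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    qrs_onset: int
    qrs_offset: int
    t_onset: int
    n_beats_averaged: int = 1

    def __post_init__(self):
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("axis series must have equal length")
        if not (0 <= self.qrs_onset < self.qrs_offset < self.t_onset
                <= len(self.x)):
            raise ValueError("fiducials must be ordered and in range")
        if self.n_beats_averaged < 1:
            raise ValueError("need at least one averaged beat")

    def axis(self, name: str) -> np.ndarray:
        return {"X": self.x, "Y": self.y, "Z": self.z}[name]


@dataclass
class VcgFeatureSet:
    dXmean: float
    dYmean: float
    dZmean: float
    windows: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"dXmean": self.dXmean, "dYmean": self.dYmean,
                "dZmean": self.dZmean}


def derive_vcg(rec: EcgRecording, matrix: str = "kors"
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthogonal X, Y, Z leads by linear transform of the 8 independent
    leads; raises MissingLeadError if any of I, II, V1-V6 is absent."""
    try:
        m = _MATRICES[matrix]
    except KeyError:
        raise ValueError(f"unknown VCG matrix {matrix!r}; "
                         f"choose from {sorted(_MATRICES)}") from None
    stack = np.vstack([rec.lead(name) for name in _VCG_INPUT_LEADS])
    xyz = m @ stack
    return xyz[0], xyz[1], xyz[2]


def bandpass(sig: np.ndarray, fs: float, lo: float = 0.5,
             hi: float = 40.0) -> np.ndarray:
    """Zero-phase 0.5-40 Hz band-pass (4-pole Butterworth, forward-backward
    application so the passband has no phase shift)."""
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid corner frequencies ({lo}, {hi}) at fs={fs}")
    sos = sps.butter(2, [lo, hi], "bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(sig, float))


def central_difference(sig: np.ndarray, fs: float) -> np.ndarray:
    """Derivative in mV/s: d[n] = (sig[n+1] - sig[n-1]) * fs / 2 for
    interior samples, one-sided differences at the endpoints."""
    x = np.asarray(sig, float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) * fs / 2.0
    d[0] = (x[1] - x[0]) * fs
    d[-1] = (x[-1] - x[-2]) * fs
    return d


def average_beat(xyz, ann: BeatAnnotation, fs: float,
                 window: tuple = BEAT_WINDOW,
                 t_onset_rr_fraction: float = 0.25) -> VcgBeat:
    """Pointwise mean across beats aligned on the R peak.

    Beats whose window [r - 0.3 s, r + 0.5 s] leaves the record are dropped.
    Averaged-beat fiducials are the medians of the per-beat offsets; the
    T-wave onset is estimated as qrs_offset + 0.25 * median RR since the
    delineator marks T end, not T onset.
    """
    x, y, z = (np.asarray(a, float) for a in xyz)
    n = len(x)
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    width = pre + post

    kept, on_off, off_off = [], [], []
    for i in range(len(ann)):
        r = int(ann.r_peak[i])
        if r - pre < 0 or r + post > n:
            continue
        kept.append(r)
        on_off.append(int(ann.qrs_onset[i]) - r + pre)
        off_off.append(int(ann.qrs_offset[i]) - r + pre)
    if not kept:
        raise ValueError("no usable beats inside the record")

    def stackmean(sig):
        return np.mean([sig[r - pre: r + post] for r in kept], axis=0)

    qrs_on = int(np.clip(np.median(on_off), 0, width - 3))
    qrs_off = int(np.clip(np.median(off_off), qrs_on + 1, width - 2))
    rr_med = (float(np.median(np.diff(kept))) if len(kept) > 1
              else 0.8 * fs)
    t_on = int(np.clip(qrs_off + round(t_onset_rr_fraction * rr_med),
                       qrs_off + 1, width))
    return VcgBeat(stackmean(x), stackmean(y), stackmean(z), fs=fs,
                   qrs_onset=qrs_on, qrs_offset=qrs_off, t_onset=t_on,
                   n_beats_averaged=len(kept))


def _region(beat: VcgBeat, axis: str) -> tuple[int, int]:
    """Admissible half-open search region [lo, hi) per axis."""
    if axis == "X":
        lo, hi = 0, beat.qrs_onset
    elif axis == "Y":
        lo, hi = beat.qrs_onset, beat.qrs_offset + 1
    elif axis == "Z":
        lo, hi = beat.qrs_offset + 1, beat.t_onset + 1
    else:
        raise ValueError(f"unknown axis {axis!r}")
    hi = min(hi, len(beat.x))
    if hi - lo < 1:
        raise DegenerateRegionError(
            f"empty search region for axis {axis} (fiducials "
            f"{beat.qrs_onset}/{beat.qrs_offset}/{beat.t_onset})")
    return lo, hi


def optimize_window(beat: VcgBeat, axis: str,
                    alpha: float = DEFAULT_ALPHA,
                    deriv: np.ndarray | None = None) -> SlopeWindow:
    """Morphology-adapted slope window inside the axis's region.

    The window is anchored at the sample of maximal absolute derivative
    (ties go to the earlier sample) and grown in both directions while the
    absolute derivative stays >= alpha * regional max and inside the region.
    A region of constant absolute derivative therefore yields the whole
    region.
    """
    lo, hi = _region(beat, axis)
    if deriv is None:
        deriv = central_difference(beat.axis(axis), beat.fs)
    a = np.abs(deriv[lo:hi])
    peak = float(a.max())
    if peak == 0.0:
        logger.warning("flat derivative on axis %s; window = whole region",
                       axis)
        return SlopeWindow(axis, lo, hi)
    anchor = lo + int(np.argmax(a))
    thr = alpha * peak
    start = anchor
    while start - 1 >= lo and np.abs(deriv[start - 1]) >= thr:
        start -= 1
    end = anchor + 1
    while end < hi and np.abs(deriv[end]) >= thr:
        end += 1
    return SlopeWindow(axis, start, end)


def vcg_slope_features(beat: VcgBeat, alpha: float = DEFAULT_ALPHA,
                       use_abs: bool = False) -> VcgFeatureSet:
    """dXmean, dYmean, dZmean in mV/s: the (signed by default) mean of the
    central-difference derivative over each axis's optimized window."""
    values, windows = {}, {}
    for axis in ("X", "Y", "Z"):
        d = central_difference(beat.axis(axis), beat.fs)
        win = optimize_window(beat, axis, alpha=alpha, deriv=d)
        seg = d[win.start:win.end]
        values[axis] = float(np.mean(np.abs(seg) if use_abs else seg))
        windows[axis] = win
    return VcgFeatureSet(dXmean=values["X"], dYmean=values["Y"],
                         dZmean=values["Z"], windows=windows)


def extract_vcg_features(rec: EcgRecording, ann: BeatAnnotation,
                         matrix: str = "kors", alpha: float = DEFAULT_ALPHA,
                         use_abs: bool = False) -> VcgFeatureSet:
    """Full VCG chain: derive X/Y/Z, band-pass 0.5-40 Hz, average beats
    aligned on R, differentiate, extract the three slope features."""
    x, y, z = derive_vcg(rec, matrix=matrix)
    xyz = tuple(bandpass(s, rec.fs) for s in (x, y, z))
    beat = average_beat(xyz, ann, rec.fs)
    return vcg_slope_features(beat, alpha=alpha, use_abs=use_abs)
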