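"""QRS detection, QRST delineation, and atrial-signal extraction.

The atrial (fibrillatory) activity of an AF ECG is obscured by the far
larger ventricular QRS-T complexes.  This module finds those complexes with
an energy-envelope detector, delineates each one with a derivative-threshold
search, and removes them by zero-replacement: every sample inside a
[QRS onset, T end] interval is set to exactly zero and each remaining
segment is mean-centered, so the spectrum of the result reflects atrial
activity alone.  Zero-replacement is deliberately simple and leaves no
residual QRS energy inside the masked intervals, unlike template
subtraction which can leave large subtraction artefacts.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .recording import AtrialSignal, BeatAnnotation, EcgRecording

logger = logging.getLogger(__name__)

__all__ = ["detect_qrs", "delineate_qrst", "cancel_qrst"]

#: QRS complexes cannot occur closer than this (ventricular refractoriness).
REFRACTORY_S = 0.200

#: Unmasked runs shorter than this cannot support a mean estimate and are
#: zeroed instead of centered.
MIN_SEGMENT_S = 0.050


def _qrs_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """Squared 10-30 Hz band-passed signal smoothed over ~120 ms."""
    sos = sps.butter(2, [10.0, min(30.0, 0.45 * fs)], "bandpass",
                     fs=fs, output="sos")
    e = sps.sosfiltfilt(sos, x) ** 2
    win = max(3, int(round(0.120 * fs)))
    return sps.convolve(e, np.ones(win) / win, mode="same")


def detect_qrs(rec: EcgRecording, lead: str = "II") -> np.ndarray:
    """Detect R peaks on one lead; returns sorted sample indices.

    Energy-envelope detector: the 10-30 Hz band-pass energy is smoothed and
    thresholded adaptively at a fraction of its upper quantile; candidate
    peaks are refractory-separated by >= 200 ms and each is refined to the
    local absolute-amplitude maximum of the band-passed signal.  A flat or
    empty recording yields an empty list rather than an error.
    """
    x = rec.lead(lead)
    if rec.duration < 2.0:
        raise ValueError("recording must be at least 2 s long")
    if not np.any(x != x[0]):
        return np.asarray([], dtype=np.int64)

    env = _qrs_envelope(x, rec.fs)
    thr = 0.20 * np.quantile(env, 0.99)
    if thr <= 0:
        return np.asarray([], dtype=np.int64)
    peaks, _ = sps.find_peaks(env, height=thr,
                              distance=int(round(REFRACTORY_S * rec.fs)))
    # refine to the extremum of the QRS-band signal near each envelope peak
    sos = sps.butter(2, [10.0, min(30.0, 0.45 * rec.fs)], "bandpass",
                     fs=rec.fs, output="sos")
    xb = np.abs(sps.sosfiltfilt(sos, x))
    half = int(round(0.050 * rec.fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(xb[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    # re-impose refractory separation after refinement
    keep = []
    for p in refined:
        if not keep or p - keep[-1] >= REFRACTORY_S * rec.fs:
            keep.append(p)
    return np.asarray(keep, dtype=np.int64)


def _search_below(absd: np.ndarray, start: int, stop: int, step: int,
                  thr: float, run: int) -> int:
    """First index from start toward stop where absd stays < thr for `run`
    consecutive samples; returns the boundary index (or stop)."""
    count = 0
    i = start
    while i != stop:
        if absd[i] < thr:
            count += 1
            if count >= run:
                return i - step * (run - 1)
        else:
            count = 0
        i += step
    return stop


def delineate_qrst(rec: EcgRecording, r_peaks: np.ndarray,
                   lead: str = "II") -> BeatAnnotation:
    """Locate QRS onset/offset and T end around each detected R peak.

    Derivative-threshold delineation: onset (offset) is where the absolute
    smoothed derivative stays below 3% of the beat's peak derivative for
    10 ms, searching backward (forward) from the R peak within a 150 ms
    window.  T end is searched after the T peak of the low-pass signal, up
    to min(next onset, R + 0.6 * local RR); if no T wave is discernible the
    fallback is qrs_offset + 0.3 * RR.  Beats whose search windows leave the
    record are dropped with a warning.
    """
    x = rec.lead(lead)
    fs = rec.fs
    n = len(x)
    r_peaks = np.asarray(sorted(r_peaks), dtype=np.int64)

    # smooth derivative for QRS borders; the T apex is read on a 6 Hz
    # low-pass — a symmetric zero-phase filter does not move a symmetric
    # peak, so the apex survives both smoothing and f-wave interference
    deriv = np.gradient(sps.savgol_filter(x, max(5, int(0.012 * fs) | 1), 3)) * fs
    absd = np.abs(deriv)
    # background slope level (f-wave + noise) sets a floor under the
    # fraction-of-peak threshold so the search terminates outside the QRS
    background = float(np.median(absd))
    sos_t = sps.butter(2, 6.0, "lowpass", fs=fs, output="sos")
    xt = sps.sosfiltfilt(sos_t, x)

    qrs_win = int(round(0.150 * fs))
    run = max(2, int(round(0.010 * fs)))
    onsets, rps, offsets, tends = [], [], [], []
    for b, r in enumerate(r_peaks):
        if r < 2 * run or r > n - 2 * run:
            logger.warning("beat %d at sample %d too close to the record "
                           "edge; dropped", b, r)
            continue
        # search windows clipped at the record edges (partial beats kept)
        w_lo = max(0, r - qrs_win)
        w_hi = min(n - 1, r + qrs_win)
        local = absd[w_lo: w_hi + 1].max()
        thr = max(0.03 * local, 2.0 * background)
        on = _search_below(absd, r, w_lo, -1, thr, run)
        off = _search_below(absd, r, w_hi, +1, thr, run)
        if on >= r:
            on = w_lo
        if off <= r:
            off = w_hi

        rr_next = (r_peaks[b + 1] - r) if b + 1 < len(r_peaks) else \
                  (r - r_peaks[b - 1]) if b > 0 else int(0.8 * fs)
        t_stop = min(n - 1, r + int(0.62 * rr_next))
        if b + 1 < len(r_peaks):
            t_stop = min(t_stop, r_peaks[b + 1] - int(0.090 * fs))
        t_end = None
        t_seek_lo = off + int(0.080 * fs)
        if t_seek_lo < t_stop - 1:
            # T apex on the low-pass signal; a symmetric zero-phase filter
            # does not move a symmetric peak, so the apex is robust to both
            # smearing and f-wave interference.  T end is then placed a
            # proportional interval past the apex (~3 sigma for a roughly
            # symmetric T wave).
            tp = t_seek_lo + int(np.argmax(np.abs(xt[t_seek_lo:t_stop])))
            amp_t = abs(xt[tp])
            if amp_t > 2.0 * np.median(np.abs(xt)):
                t_end = min(t_stop, tp + int(round(0.8 * (tp - off))))
        if t_end is None:
            t_end = min(n - 1, off + int(0.35 * rr_next))
        t_end = max(t_end, off + 1)
        onsets.append(on)
        rps.append(r)
        offsets.append(off)
        tends.append(t_end)

    # enforce non-overlap: clip each t_end at the next beat's onset
    for b in range(len(rps) - 1):
        if tends[b] >= onsets[b + 1]:
            tends[b] = max(offsets[b] + 1, onsets[b + 1] - 1)
    return BeatAnnotation(onsets, rps, offsets, tends)


def cancel_qrst(rec: EcgRecording, ann: BeatAnnotation,
                lead: str) -> AtrialSignal:
    """Zero-replace every [qrs_onset, t_end] interval (closed, 0-based) and
    mean-center each remaining maximal segment independently.

    Segments shorter than 50 ms are zeroed rather than centered (too short
    to estimate a mean).  Returns the atrial signal with its replacement
    mask; idempotent up to re-centering.
    """
    x = rec.lead(lead).copy()
    n = len(x)
    mask = np.zeros(n, dtype=bool)
    for on, te in zip(ann.qrs_onset, ann.t_end):
        mask[max(0, int(on)): min(n, int(te) + 1)] = True
    x[mask] = 0.0

    min_len = int(round(MIN_SEGMENT_S * rec.fs))
    # maximal unmasked runs
    edges = np.flatnonzero(np.diff(np.concatenate(([1], mask.view(np.int8),
                                                   [1]))))
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo >= min_len:
            x[lo:hi] -= x[lo:hi].mean()
        else:
            x[lo:hi] = 0.0
            mask[lo:hi] = True
    return AtrialSignal(samples=x, mask=mask, fs=rec.fs, source_lead=lead)
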