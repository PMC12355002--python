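"""Amplitude-spectrum analysis of atrial activity.

Four spectral parameters characterise the fibrillatory waves inside the
atrial band (3-15 Hz by default):

* DF — dominant frequency, the frequency of the highest spectral peak;
* RI — regularity index, the fraction of band energy concentrated at the
  DF peak;
* OI — organizational index, the fraction of band energy at the DF peak
  plus its harmonics (more organized AF has more of its energy in the
  harmonic series);
* Q2 — quality factor of the DF peak measured 2 dB below its maximum
  (DF divided by the -2 dB peak width): sharper peaks mean more regular
  fibrillation.

Two preprocessing routes feed these parameters: SP, the direct amplitude
spectrum of the QRST-cancelled signal, and WT, the spectrum of the
3.9-15.6 Hz portion of a maximal-overlap discrete wavelet transform
multiresolution analysis (level 7, sum of the two coarsest detail bands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .delineate import cancel_qrst
from .recording import AtrialSignal, BeatAnnotation, EcgRecording

__all__ = [
    "AmplitudeSpectrum", "SpectralParams", "SpectralFeatureSet",
    "amplitude_spectrum", "modwt_band", "dominant_frequency",
    "regularity_index", "organizational_index", "q2_factor",
    "spectral_params", "extract_spectral_features",
    "NoDominantPeakError",
]

ATRIAL_BAND = (3.0, 15.0)
DEFAULT_ZERO_PAD = 8
DEFAULT_PEAK_HALFWIDTH = 0.5     # Hz, integration half-width for RI/OI
DEFAULT_MAX_HARMONICS = 3
MODWT_WAVELET = "sym4"           # least-asymmetric, length 8


class NoDominantPeakError(ValueError):
    """The band contains no energy, so no dominant frequency exists."""


@dataclass
class AmplitudeSpectrum:
    """DFT magnitude restricted to a frequency band."""

    freqs: np.ndarray        # Hz, strictly increasing
    amps: np.ndarray         # mV per bin, >= 0
    band: tuple = ATRIAL_BAND
    resolution: float = 0.0  # Hz between bins

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.amps = np.asarray(self.amps, float)
        if self.freqs.shape != self.amps.shape:
            raise ValueError("freqs and amps must match")

    @property
    def band_energy(self) -> float:
        """Sum of squared amplitudes over the band."""
        return float(np.sum(self.amps ** 2))


@dataclass
class SpectralParams:
    DF: float
    RI: float
    OI: float
    Q2: float
    lead: str = ""
    method: str = "SP"       # "SP" | "WT"
    q2_at_band_edge: bool = False


@dataclass
class SpectralFeatureSet:
    """The five named per-recording model features (Lead_Method_Parameter)."""

    V1_WT_DF: float
    V1_WT_Q2: float
    V2_WT_RI: float
    aVR_WT_OI: float
    II_SP_DF: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("V1_WT_DF", "V1_WT_Q2", "V2_WT_RI", "aVR_WT_OI", "II_SP_DF")}


def amplitude_spectrum(sig, fs: float | None = None,
                       band: tuple = ATRIAL_BAND,
                       zero_pad_factor: int = DEFAULT_ZERO_PAD,
                       ) -> AmplitudeSpectrum:
    """Amplitude spectrum of the full series (zeros included), band-limited.

    A single full-length DFT magnitude is used — no Welch averaging, since
    10 s records are short and the parameters are defined on one spectrum.
    Zero-padding by ``zero_pad_factor`` refines the frequency grid (it does
    not add resolution, only interpolates the spectrum for peak-width and
    peak-position readout).
    """
    if isinstance(sig, AtrialSignal):
        x, fs = sig.samples, sig.fs
    else:
        x = np.asarray(sig, float)
        if fs is None:
            raise ValueError("fs required for a bare array")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"band {band} outside (0, fs/2)")
    nfft = int(len(x) * max(1, int(zero_pad_factor)))
    amps = np.abs(np.fft.rfft(x, nfft)) * 2.0 / len(x)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sel = (freqs >= lo) & (freqs <= hi)
    return AmplitudeSpectrum(freqs[sel], amps[sel], band=(lo, hi),
                             resolution=fs / nfft)


def modwt_band(sig: np.ndarray, fs: float = 1000.0, level: int = 7,
               wavelet: str = MODWT_WAVELET) -> np.ndarray:
    """Band-limited signal: sum of the two coarsest MODWT detail bands.

    A maximal-overlap (shift-invariant) wavelet multiresolution analysis at
    ``level`` splits the signal into additive octave bands; detail levels 7
    and 6 jointly cover ~3.9-15.6 Hz at fs = 1000 Hz, i.e. the atrial band.
    The input is symmetrically extended to a multiple of 2**level (the
    transform's length requirement) and the result trimmed back, so the
    output has the input's length.
    """
    if level < 2:
        raise ValueError("level must be >= 2")
    x = np.asarray(sig, float)
    block = 2 ** level
    if len(x) < block:
        raise ValueError(f"need at least {block} samples at level {level}")
    if fs != 1000.0:
        import warnings
        warnings.warn(
            f"MODWT band edges assume fs=1000 Hz; at fs={fs} the returned "
            f"band covers {fs / 2 ** (level + 1):.2f}-"
            f"{fs / 2 ** (level - 1):.2f} Hz", stacklevel=2)
    pad = (-len(x)) % block
    left = pad // 2
    right = pad - left
    xp = np.pad(x, (left, right), mode="symmetric") if pad else x
    mra = pywt.mra(xp, wavelet, level=level, transform="swt")
    # mra = [smooth_L, detail_L, detail_{L-1}, ..., detail_1]
    out = mra[1] + mra[2]
    return out[left:left + len(x)] if pad else out


def modwt_mra(sig: np.ndarray, fs: float = 1000.0, level: int = 7,
              wavelet: str = MODWT_WAVELET) -> list:
    """Full additive MRA [smooth, detail_level, ..., detail_1], input length."""
    x = np.asarray(sig, float)
    block = 2 ** level
    pad = (-len(x)) % block
    left = pad // 2
    xp = np.pad(x, (left, pad - left), mode="symmetric") if pad else x
    mra = pywt.mra(xp, wavelet, level=level, transform="swt")
    return [c[left:left + len(x)] for c in mra] if pad else mra


def dominant_frequency(spec: AmplitudeSpectrum) -> float:
    """Frequency of the maximum-amplitude bin; ties go to the lower
    frequency (np.argmax returns the first maximum)."""
    if spec.band_energy == 0.0:
        raise NoDominantPeakError("all-zero spectrum has no dominant peak")
    return float(spec.freqs[int(np.argmax(spec.amps))])


def _peak_energy(spec: AmplitudeSpectrum, centre: float, w: float) -> float:
    sel = np.abs(spec.freqs - centre) <= w
    return float(np.sum(spec.amps[sel] ** 2))


def regularity_index(spec: AmplitudeSpectrum, df: float,
                     peak_halfwidth: float = DEFAULT_PEAK_HALFWIDTH) -> float:
    """Energy within +/- peak_halfwidth of DF over total band energy."""
    tot = spec.band_energy
    if tot == 0.0:
        raise NoDominantPeakError("zero band energy: RI undefined")
    return _peak_energy(spec, df, peak_halfwidth) / tot


def organizational_index(spec: AmplitudeSpectrum, df: float,
                         peak_halfwidth: float = DEFAULT_PEAK_HALFWIDTH,
                         max_harmonics: int = DEFAULT_MAX_HARMONICS) -> float:
    """Energy at DF and its harmonics k*DF (k <= max_harmonics, inside the
    band) over total band energy.  OI >= RI by construction."""
    tot = spec.band_energy
    if tot == 0.0:
        raise NoDominantPeakError("zero band energy: OI undefined")
    sel = np.zeros(len(spec.freqs), dtype=bool)
    for k in range(1, max_harmonics + 1):
        f = k * df
        if f > spec.band[1] + peak_halfwidth:
            break
        sel |= np.abs(spec.freqs - f) <= peak_halfwidth
    return float(np.sum(spec.amps[sel] ** 2)) / tot


def q2_factor(spec: AmplitudeSpectrum, df: float,
              power_db: bool = False) -> tuple[float, bool]:
    """Quality factor of the DF peak at -2 dB: DF / (peak width where the
    amplitude first drops 2 dB below the maximum).

    Crossings are located by linear interpolation between bins.  If the
    -2 dB level is never crossed on one side before the band edge, the
    width is measured to the edge and the returned flag is True.  With
    ``power_db`` the threshold is 2 dB in power (10^(-2/20) vs 10^(-2/10)).
    """
    i0 = int(np.argmin(np.abs(spec.freqs - df)))
    peak = spec.amps[i0]
    if peak <= 0:
        raise NoDominantPeakError("zero peak amplitude: Q2 undefined")
    thr = peak * 10.0 ** (-2.0 / (10.0 if power_db else 20.0))
    at_edge = False

    def cross(direction: int) -> float:
        i = i0
        while 0 <= i + direction < len(spec.amps):
            j = i + direction
            if spec.amps[j] < thr:
                # linear interpolation between bins i and j
                frac = (spec.amps[i] - thr) / (spec.amps[i] - spec.amps[j])
                return spec.freqs[i] + frac * (spec.freqs[j] - spec.freqs[i])
            i = j
        nonlocal at_edge
        at_edge = True
        return spec.freqs[i]

    f_hi = cross(+1)
    f_lo = cross(-1)
    width = max(f_hi - f_lo, spec.resolution if spec.resolution > 0
                else np.diff(spec.freqs).min())
    return df / width, at_edge


def spectral_params(spec: AmplitudeSpectrum, lead: str = "",
                    method: str = "SP",
                    peak_halfwidth: float = DEFAULT_PEAK_HALFWIDTH,
                    max_harmonics: int = DEFAULT_MAX_HARMONICS,
                    ) -> SpectralParams:
    """All four parameters of one spectrum."""
    df = dominant_frequency(spec)
    q2, at_edge = q2_factor(spec, df)
    return SpectralParams(
        DF=df,
        RI=regularity_index(spec, df, peak_halfwidth),
        OI=organizational_index(spec, df, peak_halfwidth, max_harmonics),
        Q2=q2, lead=lead, method=method, q2_at_band_edge=at_edge,
    )


def extract_spectral_features(rec: EcgRecording, ann: BeatAnnotation,
                              band: tuple = ATRIAL_BAND,
                              peak_halfwidth: float = DEFAULT_PEAK_HALFWIDTH,
                              cancel_before_wt: bool = False,
                              ) -> SpectralFeatureSet:
    """The five named features from leads II, aVR, V1 and V2.

    SP features come from the spectrum of the QRST-cancelled signal.  WT
    features come from the MODWT band of the whole lead by default; with
    ``cancel_before_wt`` the wavelet band is taken of the cancelled signal
    instead, which removes the ventricular energy that would otherwise
    remain inside the atrial band.
    """
    for lead in ("II", "aVR", "V1", "V2"):
        if lead not in rec.lead_names:
            from .recording import MissingLeadError
            raise MissingLeadError(f"lead {lead!r} required for the spectral "
                                   f"feature set")

    def wt_params(lead: str) -> SpectralParams:
        if cancel_before_wt:
            src = cancel_qrst(rec, ann, lead).samples
        else:
            src = rec.lead(lead)
        band_sig = modwt_band(src, fs=rec.fs)
        spec = amplitude_spectrum(band_sig, fs=rec.fs, band=band)
        return spectral_params(spec, lead=lead, method="WT",
                               peak_halfwidth=peak_halfwidth)

    try:
        v1 = wt_params("V1")
        v2 = wt_params("V2")
        avr = wt_params("aVR")
        sp_ii = spectral_params(
            amplitude_spectrum(cancel_qrst(rec, ann, "II"), band=band),
            lead="II", method="SP", peak_halfwidth=peak_halfwidth)
    except NoDominantPeakError as err:
        raise NoDominantPeakError(
            f"spectral feature extraction failed: {err}") from err

    return SpectralFeatureSet(
        V1_WT_DF=v1.DF, V1_WT_Q2=v1.Q2, V2_WT_RI=v2.RI,
        aVR_WT_OI=avr.OI, II_SP_DF=sp_ii.DF,
    )
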