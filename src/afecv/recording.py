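"""Core containers for multi-lead ECG recordings and per-beat fiducials.

All signals are stored in millivolts, all fiducials as 0-based sample
indices.  The canonical 12-lead order is Einthoven/Goldberger limb leads
followed by the precordial leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical 12-lead order used throughout the package.
STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The 8 linearly independent leads that determine the other 4.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


class MissingLeadError(KeyError):
    """A requested lead is not present in the recording."""


@dataclass
class EcgRecording:
    """Multi-lead sampled ECG.

    Parameters
    ----------
    signals : ndarray, shape (n_leads, n_samples)
        Lead voltages in mV.
    fs : float
        Sampling frequency in Hz.
    lead_names : sequence of str
        One unique label per row of ``signals``.
    """

    signals: np.ndarray
    fs: float
    lead_names: tuple = STANDARD_LEADS

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.lead_names = tuple(self.lead_names)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.lead_names) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.signals.shape[0]} signal rows"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (a view), raising MissingLeadError."""
        try:
            return self.signals[self.lead_names.index(name)]
        except ValueError:
            raise MissingLeadError(
                f"lead {name!r} not in recording (have {list(self.lead_names)})"
            ) from None

    def has_leads(self, names) -> bool:
        return all(n in self.lead_names for n in names)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide frame, one column per lead, one row per sample."""
        return pd.DataFrame(self.signals.T, columns=list(self.lead_names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float) -> "EcgRecording":
        return cls(df.to_numpy(dtype=float).T, fs=fs,
                   lead_names=tuple(df.columns))


@dataclass
class BeatAnnotation:
    """Per-beat fiducials: QRS onset, R peak, QRS offset, T-wave end.

    Each field is an int array of equal length; within a beat the order
    qrs_onset < r_peak < qrs_offset < t_end holds, and beats are strictly
    increasing.
    """

    qrs_onset: np.ndarray
    r_peak: np.ndarray
    qrs_offset: np.ndarray
    t_end: np.ndarray

    def __post_init__(self):
        for name in ("qrs_onset", "r_peak", "qrs_offset", "t_end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        n = len(self.r_peak)
        if not all(len(getattr(self, f)) == n
                   for f in ("qrs_onset", "qrs_offset", "t_end")):
            raise ValueError("fiducial arrays must have equal length")
        if n:
            within = (self.qrs_onset < self.r_peak) & \
                     (self.r_peak < self.qrs_offset) & \
                     (self.qrs_offset < self.t_end)
            if not within.all():
                bad = int(np.flatnonzero(~within)[0])
                raise ValueError(f"fiducials out of order in beat {bad}")
            if n > 1 and not (np.diff(self.r_peak) > 0).all():
                raise ValueError("beats must be strictly increasing")

    def __len__(self) -> int:
        return len(self.r_peak)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beat": np.arange(len(self)),
            "qrs_on": self.qrs_onset,
            "r_peak": self.r_peak,
            "qrs_off": self.qrs_offset,
            "t_end": self.t_end,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BeatAnnotation":
        return cls(df["qrs_on"].to_numpy(), df["r_peak"].to_numpy(),
                   df["qrs_off"].to_numpy(), df["t_end"].to_numpy())


@dataclass
class AtrialSignal:
    """Single-lead atrial signal after QRST zero-replacement.

    ``mask`` marks samples that were replaced by zeros (the ventricular
    intervals); each maximal unmasked run has been mean-centered.
    """

    samples: np.ndarray
    mask: np.ndarray
    fs: float
    source_lead: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.samples.shape != self.mask.shape:
            raise ValueError("samples and mask must have the same shape")

    def __len__(self) -> int:
        return len(self.samples)
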