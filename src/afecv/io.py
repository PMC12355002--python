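"""Readers and writers for the pipeline's plain-text formats.

Signals travel as wide CSV (one column per lead, header row of lead names,
one row per sample, mV); the sampling rate is not part of the CSV and must
be supplied on read.  Annotations, feature tables and cohorts are ordinary
CSVs with fixed column names.
"""

from __future__ import annotations

import pandas as pd

from .recording import STANDARD_LEADS, BeatAnnotation, EcgRecording

__all__ = [
    "read_ecg", "write_ecg", "read_annotation", "write_annotation",
    "read_cohort", "write_cohort",
]

_ANN_COLUMNS = ["beat", "qrs_on", "r_peak", "qrs_off", "t_end"]


def read_ecg(path, fs: float | None = None, dialect: str = "csv"
             ) -> EcgRecording:
    """Read a multi-lead recording.

    Only the wide-CSV dialect is supported; ``fs`` is required because the
    CSV carries no header metadata.  Lead labels must come from the
    standard 12-lead set.
    """
    if dialect != "csv":
        raise ValueError(f"unsupported dialect {dialect!r}; only 'csv'")
    if fs is None:
        raise ValueError("fs is required when reading a CSV recording")
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in STANDARD_LEADS]
    if unknown:
        raise ValueError(
            f"unknown lead label(s) {unknown}; valid labels are "
            f"{list(STANDARD_LEADS)}")
    return EcgRecording.from_dataframe(df, fs=fs)


def write_ecg(rec: EcgRecording, path) -> None:
    rec.to_dataframe().to_csv(path, index=False, float_format="%.10f")


def write_annotation(ann: BeatAnnotation, path) -> None:
    ann.to_dataframe().to_csv(path, index=False)


def read_annotation(path) -> BeatAnnotation:
    df = pd.read_csv(path)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing columns {missing}")
    return BeatAnnotation.from_dataframe(df)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "outcome" not in df.columns:
        raise ValueError("cohort CSV must contain an 'outcome' column")
    return df
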