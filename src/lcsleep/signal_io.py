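"""Load-cell recording I/O and the bundled pilot-study result tables.

A recording is a CSV with a timestamp column ``t_s`` followed by four
sensor columns ``lc1..lc4`` (one load cell under each shoulder and hip).
Recording metadata travels in ``#``-prefixed comment lines before the
header, e.g. ``# sample_rate_hz=250``; when the sample-rate line is absent
it is inferred from the timestamp column.

The pilot tables bundle the per-study-night screening results of a
14-subject validation cohort (one attended PSG night, up to two home HSAT
nights, up to two load-cell-only home nights per subject) plus a usability
survey; :mod:`lcsleep.evaluation` recomputes all diagnostic-accuracy
statistics from them.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError, FixtureError, FormatError
from .types import CensoredAHI, Category, Setting, Severity

N_CHANNELS = 4
CHANNEL_COLUMNS = ["lc1", "lc2", "lc3", "lc4"]
TIME_COLUMN = "t_s"


@dataclass
class LCRecording:
    """A raw 4-channel under-mattress pressure recording.

    Parameters
    ----------
    subject_id : str
        Study subject identifier.
    night : int
        1-based night index within the study.
    setting : Setting
        Acquisition context (clinic PSG / home HSAT / home LC-only).
    sample_rate_hz : float
        Sampling rate; the acquisition hardware runs at 250 Hz.
    channels : ndarray, shape (4, n)
        Pressure samples per load cell, arbitrary sensor units.
    start_time : pandas.Timestamp, optional
        Absolute start time; the pipeline only uses relative time.
    """

    subject_id: str
    night: int
    setting: Setting
    sample_rate_hz: float
    channels: np.ndarray
    start_time: pd.Timestamp | None = None
    valid_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != N_CHANNELS:
            raise DataError(
                f"expected {N_CHANNELS} equal-length channels, got array of "
                f"shape {self.channels.shape}"
            )
        if self.channels.shape[1] < 1:
            raise DataError("channels must contain at least one sample")
        if not self.sample_rate_hz > 0:
            raise DataError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if int(self.night) < 1:
            raise DataError(f"night index must be >= 1, got {self.night}")
        self.night = int(self.night)
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.n_samples,):
                raise DataError("valid_mask length must equal channel length")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


def read_lc_csv(path: str | Path) -> LCRecording:
    """Read a 4-channel load-cell recording from CSV.

    Raises
    ------
    FormatError
        Missing/extra columns or unparseable header.
    DataError
        Non-monotone timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in [TIME_COLUMN, *CHANNEL_COLUMNS] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DataError(f"{path}: timestamps are not strictly increasing")
    if "sample_rate_hz" in meta:
        fs = float(meta["sample_rate_hz"])
    elif len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        raise FormatError(f"{path}: cannot determine sample rate")
    return LCRecording(
        subject_id=meta.get("subject_id", path.stem),
        night=int(meta.get("night", 1)),
        setting=Setting.parse(meta.get("setting", "home_lc_only")),
        sample_rate_hz=fs,
        channels=df[CHANNEL_COLUMNS].to_numpy(dtype=float).T,
    )


def write_lc_csv(rec: LCRecording, path: str | Path) -> Path:
    """Write a recording as CSV; ``read_lc_csv`` round-trips it losslessly
    (floats are serialized with ``repr`` precision)."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate_hz
    df = pd.DataFrame({TIME_COLUMN: t})
    for name, chan in zip(CHANNEL_COLUMNS, rec.channels):
        df[name] = chan
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# night={rec.night}\n")
        fh.write(f"# setting={rec.setting.value}\n")
        fh.write(f"# sample_rate_hz={rec.sample_rate_hz!r}\n")
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# Pilot-study result tables


@dataclass(frozen=True)
class StudyRecord:
    """One scored study night: gold-standard and predicted outcome."""

    subject_id: str
    night: int
    setting: Setting
    duration_h: float | None
    actual_category: Category | None
    predicted_category: Category | None
    actual_ahi: float | None
    predicted_ahi: CensoredAHI | None
    actual_severity: Severity | None
    predicted_severity: Severity | None

    @property
    def has_result(self) -> bool:
        """False for studies that yielded no interpretable signal (one
        clinic night in the pilot cohort had 0.00 h of usable data)."""
        return self.actual_category is not None or self.predicted_category is not None


class PilotTables(NamedTuple):
    clinic: list[StudyRecord]       # attended PSG nights (14 rows, 13 scored)
    hsat: list[StudyRecord]         # home nights wearing HSAT sensors (22 rows)
    lc_only: list[StudyRecord]      # home nights, load cells only (24 rows)
    survey: pd.DataFrame            # usability ratings (percent per score 1-5)


_FIXTURES = {
    "clinic_psg.csv": "561e3586a4d84be15e06ba27a542ab5f9fc591029218a6aa069d80ec8e766daf",
    "home_hsat.csv": "8df6f5e6372a829a6801c3189a6a5e175d7f647295b9db662098f63061695e0e",
    "home_lc_only.csv": "f55ab13a21a749a66ab1b740ff59a0cb404a0bbb2083909e0072bf98ea6b0099",
    "survey.csv": "c35a01b982f14180ec3000b9ecd2bead386824ab8c3b8c909fbfe195c092aa74",
}

_SEVERITY_TOKENS = {
    "normal": Severity.NORMAL,
    "mild": Severity.MILD,
    "moderate": Severity.MODERATE_SEVERE,
    "severe": Severity.MODERATE_SEVERE,
    "moderate/severe": Severity.MODERATE_SEVERE,
}


def _fixture_bytes(name: str) -> bytes:
    ref = resources.files("lcsleep.data").joinpath(name)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise FixtureError(f"bundled table {name} is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURES[name]:
        raise FixtureError(f"bundled table {name} is corrupted (checksum mismatch)")
    return raw


def _parse_severity(token: str | float | None) -> Severity | None:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    text = str(token).strip().lower()
    if not text:
        return None
    try:
        return _SEVERITY_TOKENS[text]
    except KeyError as exc:
        raise FixtureError(f"unrecognized severity label {token!r}") from exc


def _parse_records(name: str) -> list[StudyRecord]:
    import io

    df = pd.read_csv(io.BytesIO(_fixture_bytes(name)), dtype=str)
    records = []
    for row in df.itertuples(index=False):
        def opt(text):
            return None if text is None or (isinstance(text, float)) or not str(text).strip() else str(text).strip()

        actual_cat = opt(row.actual_category)
        predicted_cat = opt(row.predicted_category)
        actual_ahi = opt(row.actual_ahi)
        predicted_ahi = opt(row.predicted_ahi)
        records.append(
            StudyRecord(
                subject_id=str(row.subject_id),
                night=int(row.night),
                setting=Setting.parse(row.setting),
                duration_h=float(row.duration_h) if opt(row.duration_h) else None,
                actual_category=Category(actual_cat.lower()) if actual_cat else None,
                predicted_category=Category(predicted_cat.lower()) if predicted_cat else None,
                actual_ahi=float(actual_ahi) if actual_ahi else None,
                predicted_ahi=CensoredAHI.parse(predicted_ahi) if predicted_ahi else None,
                actual_severity=_parse_severity(opt(row.actual_severity)),
                predicted_severity=_parse_severity(opt(row.predicted_severity)),
            )
        )
    return records


def load_pilot_tables() -> PilotTables:
    """Load the bundled pilot-cohort result tables.

    Returns the clinic-PSG table (14 rows, one with no interpretable data),
    the home HSAT table (22 study nights), the load-cell-only home table
    (24 study nights over 12 subjects) and the usability survey. Each file
    is checksum-verified so a silently edited fixture fails loudly.
    """
    import io

    clinic = _parse_records("clinic_psg.csv")
    hsat = _parse_records("home_hsat.csv")
    lc_only = _parse_records("home_lc_only.csv")
    survey = pd.read_csv(io.BytesIO(_fixture_bytes("survey.csv")))
    return PilotTables(clinic, hsat, lc_only, survey)
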