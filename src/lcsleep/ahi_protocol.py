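"""Per-night AHI estimation and multi-night aggregation.

Nights recorded concurrently with a gold-standard test are scored from
the whole valid recording in one pass. Unattended load-cell-only nights
have no clinician to flag bad spans, so they are scored with a windowed
protocol instead: overlapping 3-h segments are each run through the
two-stage model, a rolling median filter rejects outlying window
estimates (noise-contaminated segments), and the night's AHI is the mean
of the surviving estimates. A subject's final AHI over multiple nights is
the maximum night estimate -- OSA has high night-to-night variability and
screening errs toward the more severe night.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .osa_model import TrainedPipeline, predict_study, severity_of
from .preprocess import preprocess_recording
from .signal_io import LCRecording
from .spectral import MIN_DURATION_S, features_from_signal
from .types import CensoredAHI, Category, Setting, Severity

DEFAULT_WINDOW_H = 3.0
DEFAULT_STEP_H = 1.0
DEFAULT_MEDIAN_WINDOW = 5
DEFAULT_OUTLIER_THRESHOLD = 10.0  # events/h deviation from rolling median
#: Numeric stand-in for a censored window estimate (midpoint of [0, 5)).
CENSORED_WINDOW_VALUE = 2.5


@dataclass
class AHISeries:
    """Time-ordered per-window AHI estimates for one night."""

    window_start_s: np.ndarray
    window_end_s: np.ndarray
    ahi: np.ndarray               # numeric; censored windows hold 2.5
    category: list[Category]      # per-window stage-one gate
    window_h: float
    step_h: float

    def __len__(self) -> int:
        return len(self.ahi)


@dataclass
class NightEstimate:
    subject_id: str
    night: int
    setting: Setting
    ahi: CensoredAHI
    n_windows_used: int = 1
    n_windows_rejected: int = 0

    @property
    def severity(self) -> Severity:
        return severity_of(self.ahi)


@dataclass
class SubjectDiagnosis:
    subject_id: str
    nights: list[NightEstimate]
    final_ahi: CensoredAHI = field(init=False)
    final_severity: Severity = field(init=False)

    def __post_init__(self) -> None:
        numeric = [n.ahi.value for n in self.nights if not n.ahi.is_censored]
        self.final_ahi = CensoredAHI.of(max(numeric)) if numeric else CensoredAHI.censored()
        self.final_severity = severity_of(self.final_ahi)


def whole_night_ahi(rec: LCRecording, pipeline: TrainedPipeline) -> NightEstimate:
    """Score an entire (valid portion of a) night in one pass."""
    n_valid = rec.n_samples if rec.valid_mask is None else int(rec.valid_mask.sum())
    if n_valid / rec.sample_rate_hz < MIN_DURATION_S:
        raise InsufficientDataError(
            f"valid signal of {n_valid / rec.sample_rate_hz:.0f} s is too short "
            f"to score (need >= {MIN_DURATION_S:.0f} s)"
        )
    pred = predict_study(features_from_signal(preprocess_recording(rec)), pipeline)
    return NightEstimate(rec.subject_id, rec.night, rec.setting, pred.ahi)


def windowed_ahi(
    rec: LCRecording,
    pipeline: TrainedPipeline,
    window_h: float = DEFAULT_WINDOW_H,
    step_h: float = DEFAULT_STEP_H,
) -> AHISeries:
    """Score overlapping fixed-length segments of one night.

    Windows start every ``step_h`` hours; a trailing partial window is
    dropped. Censored (normal-gated) windows enter the series at the
    numeric stand-in 2.5 events/h so the median filter can operate.
    """
    if window_h <= 0 or step_h <= 0:
        raise ValidationError("window_h and step_h must be positive")
    n_win = int(round(window_h * 3600 * rec.sample_rate_hz))
    n_step = int(round(step_h * 3600 * rec.sample_rate_hz))
    if rec.n_samples < n_win:
        raise InsufficientDataError(
            f"recording of {rec.duration_h:.2f} h is shorter than one "
            f"{window_h:.1f}-h window"
        )
    starts, ends, values, cats = [], [], [], []
    pos = 0
    while pos + n_win <= rec.n_samples:
        sub = LCRecording(
            subject_id=rec.subject_id, night=rec.night, setting=rec.setting,
            sample_rate_hz=rec.sample_rate_hz,
            channels=rec.channels[:, pos:pos + n_win],
        )
        pred = predict_study(features_from_signal(preprocess_recording(sub)), pipeline)
        starts.append(pos / rec.sample_rate_hz)
        ends.append((pos + n_win) / rec.sample_rate_hz)
        values.append(pred.ahi.numeric(censored_as=CENSORED_WINDOW_VALUE))
        cats.append(pred.category)
        pos += n_step
    return AHISeries(np.array(starts), np.array(ends), np.array(values),
                     cats, window_h, step_h)


def reject_outliers(
    series: AHISeries,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
    threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> AHISeries:
    """Drop window estimates far from the rolling median.

    An estimate deviating more than ``threshold`` events/h from the
    centered rolling median (edge-truncated) is treated as a
    noise-contaminated segment and removed. If every estimate would be
    rejected, the one closest to the global median is kept.
    """
    if len(series) == 0:
        raise ValidationError("empty AHI series")
    med = (
        pd.Series(series.ahi)
        .rolling(median_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    keep = np.abs(series.ahi - med) <= threshold
    if not keep.any():
        keep[np.argmin(np.abs(series.ahi - np.median(series.ahi)))] = True
    return AHISeries(
        series.window_start_s[keep], series.window_end_s[keep],
        series.ahi[keep], [c for c, k in zip(series.category, keep) if k],
        series.window_h, series.step_h,
    )


def night_from_series(
    filtered: AHISeries,
    subject_id: str = "",
    night: int = 1,
    setting: Setting = Setting.HOME_LC_ONLY,
    n_windows_total: int | None = None,
) -> NightEstimate:
    """Average the surviving window estimates into one night AHI.

    The night is censored ("<5") when the majority of surviving windows
    were gated normal by stage one.
    """
    if len(filtered) == 0:
        raise ValidationError("no surviving window estimates")
    normal_votes = sum(c is Category.NORMAL for c in filtered.category)
    if normal_votes > len(filtered) / 2:
        ahi = CensoredAHI.censored()
    else:
        ahi = CensoredAHI.of(float(np.mean(filtered.ahi)))
    total = len(filtered) if n_windows_total is None else n_windows_total
    return NightEstimate(subject_id, night, setting, ahi,
                         n_windows_used=len(filtered),
                         n_windows_rejected=total - len(filtered))


def windowed_night_ahi(
    rec: LCRecording,
    pipeline: TrainedPipeline,
    window_h: float = DEFAULT_WINDOW_H,
    step_h: float = DEFAULT_STEP_H,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
    threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> NightEstimate:
    """Full windowed protocol: windows -> outlier rejection -> mean."""
    series = windowed_ahi(rec, pipeline, window_h=window_h, step_h=step_h)
    filtered = reject_outliers(series, median_window=median_window, threshold=threshold)
    return night_from_series(filtered, rec.subject_id, rec.night, rec.setting,
                             n_windows_total=len(series))


def aggregate_subject(nights: list[NightEstimate]) -> SubjectDiagnosis:
    """Max rule over nights; censored only if every night is censored."""
    if not nights:
        raise ValidationError("need at least one night estimate")
    return SubjectDiagnosis(nights[0].subject_id, list(nights))


def estimates_to_frame(nights: list[NightEstimate]) -> pd.DataFrame:
    """Serialize night estimates as a tidy table (one row per night)."""
    return pd.DataFrame(
        {
            "subject_id": [n.subject_id for n in nights],
            "night": [n.night for n in nights],
            "setting": [n.setting.value for n in nights],
            "ahi": [str(n.ahi) for n in nights],
            "severity": [n.severity.value for n in nights],
            "windows_used": [n.n_windows_used for n in nights],
            "windows_rejected": [n.n_windows_rejected for n in nights],
        }
    )
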