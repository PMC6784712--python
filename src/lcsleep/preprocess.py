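"""Raw 4-channel recording -> single filtered, standardized composite signal.

The pipeline is: sum the four time-aligned load-cell channels, band-pass
filter (default 0.05-5 Hz) to strip baseline drift and non-physiologic
high-frequency noise, then scale to zero mean and unit (population)
standard deviation. Spans marked invalid by a clinician are excised before
filtering rather than zero-filled: downstream features are distributional
over frequency, so concatenation is preferable to imputation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, DegenerateSignalError, ValidationError
from .signal_io import LCRecording
from .types import Setting

#: Default band edges in Hz. The upper edge removes noise harmonics above
#: 5 Hz; the lower edge removes drift while preserving the slowest feature
#: band (0.06-0.08 Hz).
DEFAULT_LOW_HZ = 0.05
DEFAULT_HIGH_HZ = 5.0
FILTER_ORDER = 4


@dataclass
class CompositeSignal:
    """Filtered, standardized composite pressure waveform."""

    samples: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""
    night: int = 1
    setting: Setting = Setting.HOME_LC_ONLY

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


def combine_channels(rec: LCRecording) -> np.ndarray:
    """Sum the four load-cell channels sample-by-sample."""
    return rec.channels.sum(axis=0)


def bandpass(
    x: np.ndarray,
    sample_rate_hz: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    A 4th-order Butterworth is applied forward and backward
    (``sosfiltfilt``), preserving length and phase; phase distortion would
    corrupt the sub-band moment features computed downstream.
    """
    x = np.asarray(x, dtype=float)
    nyq = sample_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValidationError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low_hz}, {high_hz})"
        )
    sos = sps.butter(FILTER_ORDER, [low_hz, high_hz], btype="bandpass",
                     fs=sample_rate_hz, output="sos")
    # sosfiltfilt pads with edge reflections; require enough samples for it
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if len(x) <= padlen:
        raise DataError(f"signal too short to filter ({len(x)} samples)")
    return sps.sosfiltfilt(sos, x)


def standardize(x: np.ndarray) -> np.ndarray:
    """Scale to zero mean, unit population standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population (n) convention, so magnitudes are reproducible
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError(
            "constant signal cannot be standardized (flat or disconnected sensor?)"
        )
    return (x - x.mean()) / sd


def preprocess_recording(
    rec: LCRecording,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> CompositeSignal:
    """Full preprocessing chain: excise invalid spans, sum channels,
    band-pass, standardize."""
    channels = rec.channels
    if rec.valid_mask is not None:
        if not rec.valid_mask.any():
            raise DataError("recording has no valid samples")
        channels = channels[:, rec.valid_mask]
    raw = channels.sum(axis=0)
    if np.ptp(raw) == 0:
        raise DegenerateSignalError("composite signal is constant")
    filtered = bandpass(raw, rec.sample_rate_hz, low_hz, high_hz)
    return CompositeSignal(
        samples=standardize(filtered),
        sample_rate_hz=rec.sample_rate_hz,
        subject_id=rec.subject_id,
        night=rec.night,
        setting=rec.setting,
    )
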