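"""Spectral sub-band moment features.

A single full-length FFT of the preprocessed composite signal is taken
(no Welch averaging, no taper by default: the 0.02 Hz sub-bands require
long windows anyway and a rectangular window keeps Parseval exact). The
magnitude of the Fourier coefficients is then summarized within
consecutive non-overlapping 0.02 Hz sub-bands by four statistical moments
(mean, variance, skewness, kurtosis). Six of those sub-band moments,
selected by one-way ANOVA F-score against the three severity classes,
form the feature vector driving the two-stage classifier:

    X1 kurtosis 0.06-0.08 Hz   (stage-1 detection tree)
    X2 skewness 0.36-0.38 Hz   (stage-2 AHI regression)
    X3 skewness 0.96-0.98 Hz   (stage-2 AHI regression)
    X4 kurtosis 1.18-1.20 Hz   (stage-1 detection tree)
    X5 kurtosis 1.40-1.42 Hz   (stage-2 AHI regression)
    X6 skewness 1.68-1.70 Hz   (stage-1 detection tree)

The bands straddle the respiratory oscillation and its harmonics plus the
ballistocardiographic (cardiac) component; apnea/hypopnea episodes
amplitude-modulate breathing, reshaping the magnitude distribution within
these bands. Skewness uses the adjusted Fisher-Pearson convention and
kurtosis the excess (Fisher) convention; both are scale-invariant, so the
features are insensitive to sensor gain.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, ValidationError
from .preprocess import CompositeSignal

BAND_WIDTH_HZ = 0.02
MAX_BAND_HZ = 5.0
MIN_BINS_PER_BAND = 3
#: Minimum signal duration so each 0.02 Hz band holds >= 3 FFT bins.
MIN_DURATION_S = 150.0

#: (band_low_hz, statistic) for X1..X6, in order.
FEATURE_BANDS: tuple[tuple[float, str], ...] = (
    (0.06, "kurtosis"),
    (0.36, "skewness"),
    (0.96, "skewness"),
    (1.18, "kurtosis"),
    (1.40, "kurtosis"),
    (1.68, "skewness"),
)

#: Indices (0-based) of the features used by each classification stage.
STAGE1_FEATURES = (0, 3, 5)  # X1, X4, X6 -> detection tree
STAGE2_FEATURES = (1, 2, 4)  # X2, X3, X5 -> AHI regression


@dataclass
class MagnitudeSpectrum:
    """One-sided FFT magnitude spectrum of a composite signal."""

    frequencies_hz: np.ndarray
    magnitudes: np.ndarray
    resolution_hz: float


@dataclass
class SubBandMoments:
    """Moment table over consecutive 0.02 Hz sub-bands tiling [0, 5) Hz.

    Row ``k`` summarizes the magnitudes with frequency in
    ``[k*0.02, (k+1)*0.02)`` Hz. Bands with fewer than 3 bins hold NaN.
    """

    band_low_hz: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    skewness: np.ndarray
    kurtosis: np.ndarray

    def band_index(self, low_hz: float) -> int:
        idx = int(np.argmin(np.abs(self.band_low_hz - low_hz)))
        if abs(self.band_low_hz[idx] - low_hz) > 1e-9:
            raise DataError(f"no sub-band starting at {low_hz} Hz")
        return idx

    def statistic(self, low_hz: float, name: str) -> float:
        return float(getattr(self, name)[self.band_index(low_hz)])


def magnitude_spectrum(signal: CompositeSignal, window: str | None = None) -> MagnitudeSpectrum:
    """One-sided magnitude spectrum of the whole signal.

    Parameters
    ----------
    signal : CompositeSignal
        Preprocessed composite waveform, at least 150 s long.
    window : {None, "hann"}
        Optional taper; default rectangular.
    """
    x = np.asarray(signal.samples, dtype=float)
    n = len(x)
    if signal.duration_s < MIN_DURATION_S:
        raise DataError(
            f"signal of {signal.duration_s:.1f} s is too short for 0.02 Hz "
            f"sub-band analysis (need >= {MIN_DURATION_S:.0f} s)"
        )
    if window == "hann":
        x = x * np.hanning(n)
    elif window is not None:
        raise ValidationError(f"unknown window {window!r}")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / signal.sample_rate_hz)
    return MagnitudeSpectrum(freqs, mags, signal.sample_rate_hz / n)


def subband_moments(spec: MagnitudeSpectrum, width_hz: float = BAND_WIDTH_HZ) -> SubBandMoments:
    """Moments of FFT-coefficient magnitudes within each sub-band."""
    if spec.resolution_hz > width_hz / MIN_BINS_PER_BAND:
        raise DataError(
            f"spectral resolution {spec.resolution_hz:.4g} Hz undersamples "
            f"{width_hz} Hz bands"
        )
    n_bands = int(round(MAX_BAND_HZ / width_hz))
    lows = np.arange(n_bands) * width_hz
    out = {k: np.full(n_bands, np.nan) for k in ("mean", "variance", "skewness", "kurtosis")}
    # half-open bands [low, low+width); assign each bin once
    band_of = np.floor(spec.frequencies_hz / width_hz + 1e-12).astype(int)
    for k in range(n_bands):
        m = spec.magnitudes[band_of == k]
        if len(m) < MIN_BINS_PER_BAND:
            warnings.warn(f"sub-band {lows[k]:.2f} Hz has {len(m)} bins; moments undefined")
            continue
        out["mean"][k] = m.mean()
        out["variance"][k] = m.var()
        if m.var() == 0:
            # degenerate (constant) magnitude distribution
            warnings.warn(f"sub-band {lows[k]:.2f} Hz has zero variance")
            out["skewness"][k] = 0.0
            out["kurtosis"][k] = 0.0
        else:
            out["skewness"][k] = stats.skew(m, bias=False)
            out["kurtosis"][k] = stats.kurtosis(m, fisher=True, bias=False)
    return SubBandMoments(lows, out["mean"], out["variance"], out["skewness"], out["kurtosis"])


def extract_features(moments: SubBandMoments) -> np.ndarray:
    """The six selected sub-band moments X1..X6 as a vector."""
    values = np.array(
        [moments.statistic(low, stat) for low, stat in FEATURE_BANDS]
    )
    if not np.all(np.isfinite(values)):
        bad = [FEATURE_BANDS[i][0] for i in np.flatnonzero(~np.isfinite(values))]
        raise DataError(f"feature band(s) starting at {bad} Hz have undefined moments")
    return values


def features_from_signal(signal: CompositeSignal, window: str | None = None) -> np.ndarray:
    """Convenience: spectrum -> sub-band moments -> X1..X6."""
    return extract_features(subband_moments(magnitude_spectrum(signal, window=window)))


def anova_select(
    features_table: np.ndarray,
    labels: np.ndarray,
    k: int = 6,
    band_low_hz: np.ndarray | None = None,
    statistic_names: np.ndarray | None = None,
):
    """Rank candidate sub-band moments by one-way ANOVA F-score.

    ``features_table`` is (n_studies, n_candidates); ``labels`` the severity
    class per study. Candidates are ranked by the F statistic of a one-way
    ANOVA across classes; the top ``k`` are returned as a list of
    ``(candidate_index, F)`` pairs, optionally annotated with band/statistic
    names.
    """
    X = np.asarray(features_table, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("feature selection needs >= 2 classes")
    groups = [X[labels == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every class needs >= 2 studies")
    fscores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        with np.errstate(invalid="ignore"):
            fscores[j] = stats.f_oneway(*[g[:, j] for g in groups]).statistic
    fscores = np.nan_to_num(fscores, nan=-np.inf)
    order = np.argsort(-fscores, kind="stable")[:k]
    ranked = []
    for j in order:
        entry = {"index": int(j), "f_score": float(fscores[j])}
        if band_low_hz is not None:
            entry["band_low_hz"] = float(band_low_hz[j])
        if statistic_names is not None:
            entry["statistic"] = str(statistic_names[j])
        ranked.append(entry)
    return ranked


def candidate_moment_table(moments_list: list[SubBandMoments]):
    """Stack every (band x {skewness, kurtosis}) candidate for selection.

    Returns ``(table, band_low_hz, statistic_names)`` with candidates
    restricted to bands inside the filter passband [0, 5) Hz and defined
    (non-NaN) in every study.
    """
    blocks, lows, names = [], [], []
    ref = moments_list[0]
    for stat in ("skewness", "kurtosis"):
        col = np.stack([getattr(m, stat) for m in moments_list], axis=0)
        blocks.append(col)
        lows.append(ref.band_low_hz)
        names.append(np.full(len(ref.band_low_hz), stat, dtype=object))
    table = np.concatenate(blocks, axis=1)
    lows = np.concatenate(lows)
    names = np.concatenate(names)
    ok = np.all(np.isfinite(table), axis=0)
    return table[:, ok], lows[ok], names[ok]
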