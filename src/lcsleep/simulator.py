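"""Synthetic 4-channel load-cell recordings with known event rates.

Each channel carries a weighted copy of a composite body signal built from
narrowband physiological oscillators:

* respiration: a non-negative raised-cosine breath waveform at a steady
  0.2975 Hz (17.9 breaths/min), harmonic-rich up to ~4th order;
* a ballistocardiographic (BCG) pulse at 1.1125 Hz (66.8 bpm) whose
  amplitude is modulated by the instantaneous breath waveform
  (stroke-volume variation with intrathoracic pressure);
* a low-frequency hemodynamic (Mayer-wave-like) cycle at 0.07 Hz that
  modulates both the BCG and the respiratory amplitude;
* a random-walk baseline drift, white sensor noise per channel, and
  occasional large movement bursts shared across channels.

Apnea/hypopnea events follow a Poisson process at the target AHI
(overlapping placements rejected). Each event suppresses respiratory
amplitude by its depth (>= 0.9 apnea, 0.3-0.9 hypopnea) for 10-60 s while
a slow labored-effort oscillation (paradoxical chest movement, 0.70-0.88x
the breath rate, with a crescendo "struggle" cycle at 0.06-0.08 Hz)
persists, and ends with a few seconds of recovery hyperpnea.

The oscillator frequencies are deliberately stable so that a quiet night
concentrates narrowband power at known places inside the fixed analysis
sub-bands: the LF cycle at 0.07 Hz (0.06-0.08 band), the LF sidebands of
the breath fundamental and 3rd harmonic at 0.3675 and 0.9625 Hz
(0.36-0.38 and 0.96-0.98 bands), the 4th breath harmonic at 1.19 Hz
(1.18-1.20 band) and the first cardiac-respiratory sideband at 1.41 Hz
(1.40-1.42 band). Event activity amplitude-modulates these carriers,
draining the lines and flooding the bands with diffuse sidebands, so the
within-band magnitude distributions flatten monotonically as the event
rate rises -- the contrast the sub-band skewness/kurtosis features are
designed to detect. Effort-oscillation harmonics additionally sweep
0.96-0.98 and 1.68-1.70 Hz. Real sleep breathing wanders more than this
idealization; see the package methods notes for what that implies about
passing tests.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import preprocess_recording
from .signal_io import LCRecording
from .spectral import features_from_signal
from .types import Setting

#: Default cohort severity mix (normal : mild : moderate/severe), mirroring
#: the 14-subject pilot cohort composition 6:5:3.
DEFAULT_SEVERITY_MIX = (6 / 14, 5 / 14, 3 / 14)
#: Uniform true-AHI ranges per severity class (events/h).
SEVERITY_AHI_RANGES = ((0.0, 4.0), (6.0, 15.0), (16.0, 45.0))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic recording generator (defaults are the
    realistic overnight conditions the package is tested under)."""

    duration_h: float = 6.0
    sample_rate_hz: float = 250.0
    respiratory_rate_hz: float = 0.2975
    cardiac_rate_hz: float = 1.1125
    respiratory_amplitude: float = 1.0
    cardiac_amplitude: float = 0.2
    target_ahi: float = 0.0
    event_duration_s: tuple[float, float] = (10.0, 60.0)
    apnea_fraction: float = 0.5       # remaining events are hypopneas
    apnea_depth: tuple[float, float] = (0.9, 1.0)
    hypopnea_depth: tuple[float, float] = (0.3, 0.9)
    effort_amplitude: float = 1.2     # labored-effort oscillation during events
    effort_rate_factor: tuple[float, float] = (0.7, 0.88)  # x baseline rate
    effort_sharpness: int = 16        # gasp-like effort spikes, rich harmonics
    struggle_rate_hz: tuple[float, float] = (0.06, 0.08)  # crescendo effort cycle
    struggle_depth: float = 0.9       # modulation depth of the effort crescendo
    recovery_overshoot: float = 0.9   # post-event hyperpnea amplitude gain
    recovery_duration_s: float = 5.0
    cardiac_resp_modulation: float = 1.0  # BCG amplitude swing per breath
    lf_wave_hz: float = 0.07          # Mayer-wave-like LF hemodynamic cycle
    lf_wave_depth: float = 0.4        # BCG amplitude swing of the LF cycle
    resp_lf_depth: float = 0.2        # respiratory amplitude swing of the LF cycle
    breath_sharpness: int = 5         # moderate harmonic content
    rate_jitter: float = 0.0          # fractional slow wander of breath rate
    cardiac_jitter: float = 0.0       # fractional slow wander of heart rate
    drift_sigma: float = 0.005        # random-walk step SD per sqrt(second)
    movement_rate_per_h: float = 0.5
    movement_amplitude: float = 2.0
    noise_sigma: float = 0.02
    channel_weights: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if self.duration_h <= 0 or self.sample_rate_hz <= 0:
            raise ValidationError("duration and sample rate must be positive")
        if self.target_ahi < 0:
            raise ValidationError("target_ahi must be >= 0")
        if self.respiratory_amplitude <= 0 or self.cardiac_amplitude <= 0:
            raise ValidationError("amplitudes must be positive")
        lo, hi = self.event_duration_s
        if not 0 < lo <= hi:
            raise ValidationError("event_duration_s range must be positive")
        if any(w <= 0 for w in self.channel_weights) or len(self.channel_weights) != 4:
            raise ValidationError("channel_weights must be 4 positive reals")
        for rng_ in (self.apnea_depth, self.hypopnea_depth):
            if not (0 < rng_[0] <= rng_[1] <= 1):
                raise ValidationError("event depths must lie in (0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class Event:
    start_s: float
    end_s: float
    kind: str          # "apnea" | "hypopnea"
    depth: float       # fractional respiratory amplitude suppression


@dataclass
class GroundTruth:
    """What the generator actually planted in a recording."""

    events: list[Event]
    movements: list[tuple[float, float]]
    duration_h: float

    @property
    def true_ahi(self) -> float:
        return len(self.events) / self.duration_h


def _place_events(cfg: SimulationConfig, rng: np.random.Generator) -> list[Event]:
    duration_s = cfg.duration_h * 3600.0
    n_events = rng.poisson(cfg.target_ahi * cfg.duration_h)
    lo, hi = cfg.event_duration_s
    if n_events * (lo + hi) / 2 > 0.85 * duration_s:
        raise ValidationError(
            f"target_ahi={cfg.target_ahi} cannot place {n_events} disjoint "
            f"events in {cfg.duration_h} h"
        )
    placed: list[Event] = []
    attempts = 0
    while len(placed) < n_events:
        attempts += 1
        if attempts > 200 * max(n_events, 1):
            raise ValidationError("event placement failed; AHI too high for disjoint events")
        dur = rng.uniform(lo, hi)
        start = rng.uniform(0, duration_s - dur)
        if any(start < e.end_s + 5.0 and e.start_s - 5.0 < start + dur for e in placed):
            continue
        if rng.random() < cfg.apnea_fraction:
            kind, depth = "apnea", rng.uniform(*cfg.apnea_depth)
        else:
            kind, depth = "hypopnea", rng.uniform(*cfg.hypopnea_depth)
        placed.append(Event(start, start + dur, kind, depth))
    return sorted(placed, key=lambda e: e.start_s)


def _slow_wander(n: int, fs: float, rng: np.random.Generator, step_s: float = 30.0) -> np.ndarray:
    """Smooth random curve in [-1, 1], piecewise-linear over ~30 s knots."""
    n_knots = max(int(n / fs / step_s) + 2, 2)
    knots = np.clip(rng.normal(0, 0.5, n_knots).cumsum() * 0.3, -1, 1)
    knots = np.clip(knots - knots.mean(), -1, 1)
    t = np.linspace(0, n_knots - 1, n)
    return np.interp(t, np.arange(n_knots), knots)


def _pulse_train(rate_hz: float, jitter: float, sharpness: int, n: int, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Non-negative periodic pulse with slowly wandering rate."""
    rate = rate_hz * (1.0 + jitter * _slow_wander(n, fs, rng))
    phase = 2 * np.pi * np.cumsum(rate) / fs
    return ((1.0 - np.cos(phase)) / 2.0) ** sharpness


def _event_envelope(events: list[Event], n: int, fs: float, ramp_s: float = 2.0) -> np.ndarray:
    env = np.ones(n)
    t = np.arange(n) / fs
    for e in events:
        inside = (t >= e.start_s) & (t < e.end_s)
        env[inside] = np.minimum(env[inside], 1.0 - e.depth)
        # cosine ramps so the modulation does not splatter broadband energy
        for edge, sign in ((e.start_s, 1), (e.end_s, -1)):
            span = (t >= edge - ramp_s) & (t < edge) if sign > 0 else \
                   (t >= edge) & (t < edge + ramp_s)
            frac = (t[span] - (edge - ramp_s if sign > 0 else edge)) / ramp_s
            ramp = 1.0 - e.depth * (0.5 - 0.5 * np.cos(np.pi * (frac if sign > 0 else 1 - frac)))
            env[span] = np.minimum(env[span], ramp)
    return env


def _recovery_envelope(events: list[Event], n: int, fs: float,
                       overshoot: float, duration_s: float) -> np.ndarray:
    """Post-event hyperpnea: a tapered amplitude overshoot right after each
    event, scaled by the event's depth (deeper obstruction, bigger recovery
    breaths)."""
    gain = np.ones(n)
    for e in events:
        i0 = int(e.end_s * fs)
        i1 = min(i0 + int(duration_s * fs), n)
        if i1 - i0 < 2:
            continue
        gain[i0:i1] += overshoot * e.depth * np.hanning(i1 - i0)
    return gain


def _effort_component(cfg: SimulationConfig, events: list[Event], n: int, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Labored respiratory effort during events: a slowed harmonic-rich
    oscillation, tapered at the event edges, with a per-event rate."""
    effort = np.zeros(n)
    for e in events:
        i0, i1 = int(e.start_s * fs), min(int(e.end_s * fs), n)
        if i1 - i0 < 2:
            continue
        rate = cfg.respiratory_rate_hz * rng.uniform(*cfg.effort_rate_factor)
        tt = np.arange(i1 - i0) / fs
        phase = 2 * np.pi * rate * tt + rng.uniform(0, 2 * np.pi)
        pulse = ((1.0 - np.cos(phase)) / 2.0) ** cfg.effort_sharpness
        # crescendo-decrescendo struggle cycle within the obstruction
        f_s = rng.uniform(*cfg.struggle_rate_hz)
        struggle = 1.0 - cfg.struggle_depth * (
            0.5 + 0.5 * np.cos(2 * np.pi * f_s * tt + rng.uniform(0, 2 * np.pi)))
        effort[i0:i1] = (cfg.effort_amplitude * e.depth * pulse * struggle
                         * np.hanning(i1 - i0))
    return effort


def simulate_recording(cfg: SimulationConfig) -> tuple[LCRecording, GroundTruth]:
    """Generate one synthetic night and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n = int(round(cfg.duration_h * 3600 * fs))

    events = _place_events(cfg, rng)
    env = _event_envelope(events, n, fs)
    env = env * _recovery_envelope(events, n, fs, cfg.recovery_overshoot,
                                   cfg.recovery_duration_s)
    lf_cos = np.cos(2 * np.pi * cfg.lf_wave_hz * np.arange(n) / fs
                    + rng.uniform(0, 2 * np.pi))
    resp = (cfg.respiratory_amplitude * env
            * (1.0 + cfg.resp_lf_depth * lf_cos)
            * _pulse_train(cfg.respiratory_rate_hz, cfg.rate_jitter,
                           cfg.breath_sharpness, n, fs, rng))
    resp += cfg.respiratory_amplitude * _effort_component(cfg, events, n, fs, rng)
    # BCG amplitude rides on intrathoracic pressure: modulate the cardiac
    # pulse by the instantaneous breath waveform. Steady breathing puts
    # clean sidebands at cardiac +- k*breath rate; events smear them.
    breath_mod = resp / cfg.respiratory_amplitude
    lf_wave = 1.0 + cfg.lf_wave_depth * lf_cos
    cardiac = (
        cfg.cardiac_amplitude
        * _pulse_train(cfg.cardiac_rate_hz, cfg.cardiac_jitter, 8, n, fs, rng)
        * (1.0 + cfg.cardiac_resp_modulation * breath_mod)
        * lf_wave
    )
    drift = np.cumsum(rng.normal(0.0, cfg.drift_sigma / np.sqrt(fs), n))
    body = resp + cardiac + drift

    movements: list[tuple[float, float]] = []
    movement = np.zeros(n)
    for _ in range(rng.poisson(cfg.movement_rate_per_h * cfg.duration_h)):
        dur = rng.uniform(2.0, 10.0)
        start = rng.uniform(0.0, cfg.duration_h * 3600 - dur)
        i0, i1 = int(start * fs), int((start + dur) * fs)
        burst = rng.normal(0.0, cfg.movement_amplitude, i1 - i0)
        win = np.hanning(i1 - i0)
        movement[i0:i1] += burst * win
        movements.append((start, start + dur))

    weights = np.asarray(cfg.channel_weights, dtype=float)
    channels = (
        weights[:, None] * body[None, :]
        + movement[None, :] * rng.uniform(0.5, 1.5, 4)[:, None]
        + rng.normal(0.0, cfg.noise_sigma, (4, n))
    )
    rec = LCRecording(
        subject_id=f"sim-{cfg.seed}", night=1, setting=Setting.HOME_LC_ONLY,
        sample_rate_hz=fs, channels=channels,
    )
    return rec, GroundTruth(events, movements, cfg.duration_h)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortStudy:
    subject_id: str
    night: int
    true_ahi: float            # realized events / duration
    target_ahi: float          # night-level target handed to the generator
    features: np.ndarray       # X1..X6
    recording: LCRecording | None = None
    truth: GroundTruth | None = None


@dataclass
class Cohort:
    studies: list[CohortStudy]

    def feature_table(self) -> pd.DataFrame:
        """Tidy per-study table ready for leave-one-patient-out fitting."""
        rows = []
        for s in self.studies:
            row = {"subject_id": s.subject_id, "night": s.night,
                   "true_ahi": s.true_ahi, "abnormal": s.true_ahi >= 5.0}
            row.update({f"X{i+1}": v for i, v in enumerate(s.features)})
            rows.append(row)
        return pd.DataFrame(rows)


def draw_subject_ahis(
    n_subjects: int,
    rng: np.random.Generator,
    severity_mix: tuple[float, float, float] = DEFAULT_SEVERITY_MIX,
) -> np.ndarray:
    """Subject-level true AHIs with class counts allocated by largest
    remainder so small cohorts keep the intended severity mix."""
    quotas = np.array(severity_mix) * n_subjects
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: n_subjects - counts.sum()]:
        counts[i] += 1
    ahis = np.concatenate([
        rng.uniform(lo, hi, c) for (lo, hi), c in zip(SEVERITY_AHI_RANGES, counts)
    ])
    return rng.permutation(ahis)


def simulate_cohort(
    n_subjects: int,
    nights_per_subject: int = 2,
    seed: int = 0,
    config: SimulationConfig | None = None,
    severity_mix: tuple[float, float, float] = DEFAULT_SEVERITY_MIX,
    keep_recordings: bool = False,
) -> Cohort:
    """Simulate a labelled cohort and extract per-night features.

    Each subject has a latent severity drawn from ``severity_mix``; the
    per-night generator target jitters +-20% around the subject's AHI,
    emulating night-to-night variability. Recordings are discarded after
    feature extraction unless ``keep_recordings``.
    """
    if n_subjects < 3:
        raise ValidationError("cohort needs >= 3 subjects")
    template = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    subject_ahis = draw_subject_ahis(n_subjects, rng, severity_mix)
    studies: list[CohortStudy] = []
    for i, subj_ahi in enumerate(subject_ahis):
        for night in range(1, nights_per_subject + 1):
            cfg = SimulationConfig(**{
                **asdict(template),
                "target_ahi": float(subj_ahi * rng.uniform(0.8, 1.2)),
                "seed": int(rng.integers(0, 2**31 - 1)),
            })
            rec, truth = simulate_recording(cfg)
            rec.subject_id = f"S{i+1:03d}"
            rec.night = night
            feats = features_from_signal(preprocess_recording(rec))
            studies.append(CohortStudy(
                subject_id=rec.subject_id, night=night,
                true_ahi=truth.true_ahi, target_ahi=cfg.target_ahi,
                features=feats,
                recording=rec if keep_recordings else None,
                truth=truth if keep_recordings else None,
            ))
    return Cohort(studies)
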