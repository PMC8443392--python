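"""Seeded generator of dual-accelerometer recordings with ground truth.

The generator emulates the amplitude taxonomy of abdominal accelerometer
data so that the whole detection system can be trained and evaluated with
no external data:

* fetal-movement bursts: Gaussian-windowed damped oscillation packets with
  a 2-10 Hz carrier and one or two crests (equal probability), peak
  amplitude uniform in (0.015, 0.06) g, wholly contained in one 2.56 s
  analysis window;
* maternal artifacts: large slow (1-3 Hz) transients with peak amplitude in
  (0.1, 0.3) g, injected on all six axes simultaneously to emulate
  whole-body movement;
* respiration: a ~0.3 Hz sinusoid, peak amplitude at most 0.015 g
  (default 0.01 g), coupled most strongly to one axis per sensor;
* background vibration: narrowband 8-20 Hz oscillation with amplitude in
  (0.06, 0.1) g (training material only; it does not contaminate
  recordings);
* wide-band sensor noise (sigma = 0.003 g) and a per-channel DC offset.

Event timing is Poisson with the configured per-minute rates; each event
occupies a single analysis window (bursts are centred in their window with
a small jitter). Every injected FM event is annotated; artifacts are
annotated internally with the label ``"artifact"`` so evaluation can ignore
them. All randomness flows from ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary_learning import TrainingSet, normalize_signal
from .errors import ParameterError
from .signal_model import (
    DEFAULT_SAMPLE_RATE,
    DEFAULT_WINDOW_SECONDS,
    EventInterval,
    KalmanParams,
    Recording,
    preprocess_window,
    window_length,
)

#: Maximum placement redraws before an overlapping event is skipped.
MAX_COLLISION_REDRAWS = 100


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the amplitude bands above."""

    duration_s: float = 3600.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    fm_rate_per_min: float = 0.15
    fm_amp_range: tuple[float, float] = (0.015, 0.06)
    artifact_rate_per_min: float = 0.2
    artifact_amp_range: tuple[float, float] = (0.1, 0.3)
    breathing_amp: float = 0.01
    background_amp_range: tuple[float, float] = (0.06, 0.1)
    noise_sigma: float = 0.003
    dc_offset_range: tuple[float, float] = (-0.2, 0.2)
    seed: int = 0
    window_seconds: float = DEFAULT_WINDOW_SECONDS

    def __post_init__(self) -> None:
        if self.duration_s < self.window_seconds:
            raise ParameterError("duration_s must cover at least one window")
        lo, hi = self.fm_amp_range
        if not (0 < lo < hi):
            raise ParameterError("fm_amp_range must be an increasing positive pair")
        if self.breathing_amp > 0.015:
            raise ParameterError("breathing amplitude must stay below the FM band (0.015 g)")

    @property
    def samples_per_window(self) -> int:
        return window_length(self.sample_rate, self.window_seconds)


def _packet(t: np.ndarray, center: float, sigma: float, freq: float, phase: float,
            tau: float, crests: int, second_scale: float, sep_sigma: float) -> np.ndarray:
    """Gaussian-windowed damped oscillation with one or two envelope crests.

    A double-crested packet places its two humps symmetrically about
    ``center`` so the support stays well inside the analysis window.
    """
    if crests == 2:
        half = 0.5 * sep_sigma * sigma
        env = (np.exp(-0.5 * ((t - center + half) / sigma) ** 2)
               + second_scale * np.exp(-0.5 * ((t - center - half) / sigma) ** 2))
    else:
        env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    carrier = np.sin(2.0 * np.pi * freq * (t - center) + phase)
    damping = np.exp(-np.abs(t - center) / tau)
    return env * carrier * damping


def draw_burst_params(rng: np.random.Generator, cfg: SynthConfig) -> dict:
    """Draw the random shape parameters of one FM packet.

    Exposed separately from the rendering so the distribution of shape
    choices (e.g. the equal-probability single/double crest split) can be
    examined directly.
    """
    return {
        "crests": 2 if rng.random() < 0.5 else 1,
        "center": cfg.window_seconds / 2.0 + rng.uniform(-0.2, 0.2),
        "sigma": rng.uniform(0.08, 0.16),
        "freq": rng.uniform(2.0, 10.0),
        "phase": rng.uniform(0.0, 2.0 * np.pi),
        "tau": rng.uniform(0.3, 0.6),
        "second_scale": rng.uniform(0.5, 0.9),
        "sep_sigma": rng.uniform(2.2, 3.0),
        "peak": rng.uniform(*cfg.fm_amp_range),
    }


def _scale_to_preprocessed_peak(wave: np.ndarray, peak: float, cfg: SynthConfig) -> np.ndarray:
    """Scale a waveform so its *preprocessed* peak equals ``peak``.

    Event amplitudes are defined in the domain the gate thresholds: the
    baseline-removed, Kalman-filtered window. This makes the generator's
    amplitude bands hold by construction after preprocessing.
    """
    filtered_peak = float(np.max(np.abs(preprocess_window(wave, _training_kalman(cfg)))))
    return wave / filtered_peak * peak


def make_fm_burst(rng: np.random.Generator, cfg: SynthConfig) -> tuple[np.ndarray, float]:
    """One fetal-movement packet spanning a single analysis window.

    Returns the waveform (``samples_per_window`` long) and its peak
    amplitude, drawn uniformly from ``cfg.fm_amp_range`` and guaranteed to
    lie strictly inside the FM gate band (measured, like the gate, on the
    preprocessed waveform).
    """
    n = cfg.samples_per_window
    t = np.arange(n) / cfg.sample_rate
    q = draw_burst_params(rng, cfg)
    wave = _packet(t, q["center"], q["sigma"], q["freq"], q["phase"], q["tau"],
                   q["crests"], second_scale=q["second_scale"], sep_sigma=q["sep_sigma"])
    return _scale_to_preprocessed_peak(wave, q["peak"], cfg), q["peak"]


def make_artifact_burst(rng: np.random.Generator, cfg: SynthConfig) -> tuple[np.ndarray, float]:
    """One maternal body-movement transient (slow, large) in a single window."""
    n = cfg.samples_per_window
    t = np.arange(n) / cfg.sample_rate
    center = cfg.window_seconds / 2.0 + rng.uniform(-0.1, 0.1)
    wave = _packet(
        t, center,
        sigma=rng.uniform(0.2, 0.35),
        freq=rng.uniform(1.0, 3.0),
        phase=rng.uniform(0.0, 2.0 * np.pi),
        tau=rng.uniform(0.5, 1.0),
        crests=1, second_scale=0.0, sep_sigma=0.0,
    )
    peak = rng.uniform(*cfg.artifact_amp_range)
    return _scale_to_preprocessed_peak(wave, peak, cfg), peak


def _breathing_coupling(rng: np.random.Generator) -> np.ndarray:
    """Per-channel respiration coupling: one dominant axis per sensor."""
    factors = np.empty(6)
    for sensor in range(2):
        dominant = rng.integers(3)
        for axis in range(3):
            ch = sensor * 3 + axis
            if axis == dominant:
                factors[ch] = rng.uniform(0.7, 1.0)
            else:
                factors[ch] = rng.uniform(0.1, 0.5)
    return factors


def _draw_event_windows(rng: np.random.Generator, count: int, n_windows: int,
                        occupied: set[int]) -> list[int]:
    """Place events in distinct windows, redrawing collisions then skipping."""
    placed = []
    for _ in range(count):
        for _attempt in range(MAX_COLLISION_REDRAWS):
            w = int(rng.integers(n_windows))
            if w not in occupied:
                occupied.add(w)
                placed.append(w)
                break
    return placed


def make_recording(cfg: SynthConfig) -> Recording:
    """Generate a six-channel recording with FM and artifact events.

    FM events are annotated with label ``"FM_perceived"`` (the interval is
    the hosting window's span); artifact windows carry the internal label
    ``"artifact"`` so they can be inspected but are not scored as FM.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.duration_s * fs))
    L = cfg.samples_per_window
    n_windows = n // L
    duration_min = cfg.duration_s / 60.0

    channels = rng.normal(0.0, cfg.noise_sigma, size=(6, n))
    channels += rng.uniform(*cfg.dc_offset_range, size=6)[:, None]

    t = np.arange(n) / fs
    f_breath = rng.uniform(0.25, 0.35)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    coupling = _breathing_coupling(rng)
    channels += (cfg.breathing_amp * coupling)[:, None] * np.sin(
        2.0 * np.pi * f_breath * t + phase
    )

    annotations: list[EventInterval] = []
    occupied: set[int] = set()

    n_fm = int(rng.poisson(cfg.fm_rate_per_min * duration_min))
    for w in _draw_event_windows(rng, n_fm, n_windows, occupied):
        burst, _peak = make_fm_burst(rng, cfg)
        sl = slice(w * L, (w + 1) * L)
        primary = int(rng.integers(6))
        channels[primary, sl] += burst
        for axis in range(6):
            if axis != primary and rng.random() < 0.4:
                channels[axis, sl] += rng.uniform(0.3, 0.9) * burst
        annotations.append(EventInterval(w * L / fs, (w + 1) * L / fs, "FM_perceived"))

    n_art = int(rng.poisson(cfg.artifact_rate_per_min * duration_min))
    for w in _draw_event_windows(rng, n_art, n_windows, occupied):
        wave, _peak = make_artifact_burst(rng, cfg)
        sl = slice(w * L, (w + 1) * L)
        strong_axis = int(rng.integers(6))
        for axis in range(6):
            # whole-body movement: every axis responds strongly, so no axis
            # is attenuated into the FM candidate band
            factor = 1.0 if axis == strong_axis else rng.uniform(0.8, 1.0)
            channels[axis, sl] += factor * wave
        annotations.append(EventInterval(w * L / fs, (w + 1) * L / fs, "artifact"))

    annotations.sort(key=lambda ev: ev.start_s)
    return Recording(channels=channels, sample_rate=fs, annotations=annotations)


def _training_kalman(cfg: SynthConfig) -> KalmanParams:
    """Preprocessing parameters for standalone training windows.

    R is the known variance of the differenced sensor noise (2 sigma^2),
    the quantity the pipeline estimates from a quiet first window.
    """
    r = max(2.0 * cfg.noise_sigma ** 2, 1e-12)
    return KalmanParams(R=r)


def make_training_sets(cfg: SynthConfig, n_per_class: int,
                       seed: int | None = None) -> tuple[TrainingSet, TrainingSet]:
    """Build preprocessed, normalized FM and non-FM training matrices.

    The FM set holds burst-plus-noise windows whose pre-normalization
    preprocessed peak verifiably lies in the FM band (the same quantity the
    gate thresholds). The non-FM set mixes narrowband background vibration
    (amplitude in the 0.06-0.1 g band), respiration arcs, and pure sensor
    noise, in 40/40/20 proportions. Both classes pass through the same
    preprocessing chain as pipeline windows before normalization; the
    pre-normalization peaks are kept on each returned set.
    """
    if n_per_class < cfg.samples_per_window:
        raise ParameterError(
            "n_per_class must be at least the window length for "
            "complete-dictionary training"
        )
    rng = np.random.default_rng([seed if seed is not None else cfg.seed, 1])
    n = cfg.samples_per_window
    t = np.arange(n) / cfg.sample_rate
    kp = _training_kalman(cfg)
    a1, a2 = 0.015, 0.06

    fm_cols = np.empty((n, n_per_class))
    fm_peaks = np.empty(n_per_class)
    for i in range(n_per_class):
        for _attempt in range(MAX_COLLISION_REDRAWS):
            burst, _peak = make_fm_burst(rng, cfg)
            w = burst + rng.normal(0.0, cfg.noise_sigma, n)
            pre = preprocess_window(w, kp)
            peak = float(np.max(np.abs(pre)))
            if a1 < peak < a2:
                break
        fm_cols[:, i] = normalize_signal(pre)
        fm_peaks[i] = peak
    fm = TrainingSet(Y=fm_cols, class_label="FM",
                     components=["fm"] * n_per_class, peaks=fm_peaks)

    nonfm_cols = np.empty((n, n_per_class))
    nonfm_peaks = np.empty(n_per_class)
    components: list[str] = []
    for i in range(n_per_class):
        u = rng.random()
        w = rng.normal(0.0, cfg.noise_sigma, n)
        if u < 0.4:
            kind = "background"
            freq = rng.uniform(8.0, 20.0)
            amp = rng.uniform(*cfg.background_amp_range)
            am = 1.0 + 0.3 * np.sin(2.0 * np.pi * rng.uniform(0.5, 2.0) * t
                                    + rng.uniform(0.0, 2.0 * np.pi))
            w += amp * am / np.max(np.abs(am)) * np.sin(
                2.0 * np.pi * freq * t + rng.uniform(0.0, 2.0 * np.pi)
            )
        elif u < 0.8:
            kind = "breathing"
            freq = rng.uniform(0.25, 0.35)
            amp = rng.uniform(0.3, 1.0) * cfg.breathing_amp
            w += amp * np.sin(2.0 * np.pi * freq * t + rng.uniform(0.0, 2.0 * np.pi))
        else:
            kind = "noise"
        components.append(kind)
        pre = preprocess_window(w, kp)
        nonfm_cols[:, i] = normalize_signal(pre)
        nonfm_peaks[i] = float(np.max(np.abs(pre)))
    nonfm = TrainingSet(Y=nonfm_cols, class_label="NON_FM",
                        components=components, peaks=nonfm_peaks)

    return fm, nonfm
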