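"""Domain types and preprocessing for dual 3-axis abdominal accelerometer signals.

A recording holds six ordered acceleration channels (sensor 1 x,y,z then
sensor 2 x,y,z) in units of g, sampled at a fixed rate (100 Hz by default).
Analysis proceeds on non-overlapping 2.56 s windows (256 samples at the
default rate), the unit of all downstream classification.

Preprocessing of each window has three steps:

1. DC-offset correction by first differencing, dS[k] = S[k] - S[k-1]. The
   gravity projection on each axis is a large, per-channel constant that
   differencing removes exactly.
2. Scalar Kalman filtering of the differenced sequence under a random-walk
   state model (A = H = 1, no input term), which suppresses wide-band sensor
   noise while passing the 2-10 Hz band where fetal-movement transients live.
3. Cumulative-sum reintegration anchored at zero. Because convolution
   commutes with differencing, the chain is equivalent to low-pass filtering
   the raw window and removing its DC anchor: output amplitudes stay on the
   physical g scale that the downstream amplitude gate expects, and the
   reintegration introduces no random-walk drift.

Window peak amplitudes of the preprocessed output therefore remain directly
comparable to the gate thresholds (0.015 / 0.06 / 0.1 g).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    ParseError,
)

#: Default sampling rate of the acquisition hardware, samples/second.
DEFAULT_SAMPLE_RATE = 100.0

#: Default analysis window length, seconds (non-overlapping tiling).
DEFAULT_WINDOW_SECONDS = 2.56

#: Samples per window at the defaults: round(2.56 * 100) = 256.
WINDOW_SAMPLES = 256

#: Column layout of recording files.
RECORDING_COLUMNS = ("time_s", "s1x", "s1y", "s1z", "s2x", "s2y", "s2z")

#: Column layout of annotation files.
ANNOTATION_COLUMNS = ("start_s", "end_s", "label")

#: Upload amplification factor applied by the acquisition firmware.
RAW_UPLOAD_GAIN = 10_000.0

#: Accelerometer sensitivity, integer counts per g.
RAW_COUNTS_PER_G = 4096.0


@dataclass(frozen=True)
class EventInterval:
    """A ground-truth event interval in seconds, half-open [start_s, end_s)."""

    start_s: float
    end_s: float
    label: str = "FM_perceived"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"event interval requires start_s < end_s, got "
                f"[{self.start_s}, {self.end_s})"
            )

    def overlaps(self, other: "EventInterval") -> bool:
        """True if the two half-open intervals share any nonzero overlap."""
        return self.start_s < other.end_s and other.start_s < self.end_s


@dataclass
class Recording:
    """A six-channel acceleration time series in g with optional annotations.

    Channels are ordered sensor1 x,y,z then sensor2 x,y,z and must share one
    length.
    """

    channels: np.ndarray  # shape (6, n_samples), units of g
    sample_rate: float = DEFAULT_SAMPLE_RATE
    annotations: list[EventInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 6:
            raise ValueError(
                f"expected channel array of shape (6, n_samples), got "
                f"{self.channels.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        dur = self.duration_s
        for ev in self.annotations:
            if not (0.0 <= ev.start_s < ev.end_s <= dur + 1e-9):
                raise ValueError(
                    f"annotation [{ev.start_s}, {ev.end_s}) outside recording "
                    f"duration {dur:.2f} s"
                )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class Window:
    """One fixed-length segment of one axis; the unit of classification."""

    samples: np.ndarray  # length 256 at defaults, units of g
    axis_index: int
    window_index: int
    start_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("window samples must be one-dimensional")
        if not 0 <= self.axis_index <= 5:
            raise ValueError("axis_index must be in 0..5")


@dataclass
class KalmanParams:
    """Scalar Kalman filter parameters for the random-walk signal model.

    State transition x_k = A x_{k-1} + w_k with Var(w_k) = Q; measurement
    y_k = H x_k + V_k with Var(V_k) = R. The input term B_k u_k is fixed to
    zero. ``x0``/``P0`` default to the first sample of the filtered window
    and to R respectively when left as None.
    """

    A: float = 1.0
    H: float = 1.0
    Q: float = 1e-4
    R: float = 1e-5
    x0: float | None = None
    P0: float | None = None

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ParameterError(f"measurement-noise variance R must be > 0, got {self.R}")
        if self.Q < 0:
            raise ParameterError(f"process-noise variance Q must be >= 0, got {self.Q}")
        if self.P0 is not None and self.P0 < 0:
            raise ParameterError(f"initial variance P0 must be >= 0, got {self.P0}")


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _read_delimited(path, expected_columns: tuple[str, ...]) -> pd.DataFrame:
    """Read a comma- or tab-delimited text file with a header row."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, skipinitialspace=True)
    except pd.errors.ParserError as exc:  # e.g. ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    if len(df.columns) != len(expected_columns):
        raise FormatError(
            f"{path}: expected {len(expected_columns)} columns "
            f"{expected_columns}, found {len(df.columns)} ({tuple(df.columns)})"
        )
    return df


def _numeric_or_raise(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    """Coerce columns to float, naming the first bad line on failure."""
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(
                f"{path}: malformed value {df[col].iloc[line - 2]!r} in column "
                f"{col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced.astype(float)
    return df


def load_annotations(path) -> list[EventInterval]:
    """Load an annotation sidecar file (columns start_s, end_s, label)."""
    df = _read_delimited(path, ANNOTATION_COLUMNS)
    df = _numeric_or_raise(df, ("start_s", "end_s"), path)
    return [
        EventInterval(float(r.start_s), float(r.end_s), str(r.label).strip())
        for r in df.itertuples()
    ]


def load_recording(path, dialect: str = "g_units", annotation_path=None) -> Recording:
    """Load a recording file: time column plus six acceleration channels.

    Parameters
    ----------
    path
        Delimited text file with header ``time_s, s1x, s1y, s1z, s2x, s2y, s2z``.
    dialect
        ``"g_units"`` if values are already in g; ``"raw_counts"`` if they are
        firmware integers, in which case each value is divided by the upload
        amplification (10,000) and the sensor sensitivity (4096 counts/g).
    annotation_path
        Optional sidecar file of perceived-movement intervals.
    """
    if dialect not in ("g_units", "raw_counts"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    df = _read_delimited(path, RECORDING_COLUMNS)
    df = _numeric_or_raise(df, RECORDING_COLUMNS, path)
    channels = df[list(RECORDING_COLUMNS[1:])].to_numpy(dtype=float).T
    if dialect == "raw_counts":
        channels = channels / RAW_UPLOAD_GAIN / RAW_COUNTS_PER_G
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        rate = 1.0 / float(np.median(dt)) if np.median(dt) > 0 else DEFAULT_SAMPLE_RATE
    else:
        rate = DEFAULT_SAMPLE_RATE
    annotations = load_annotations(annotation_path) if annotation_path else []
    return Recording(channels=channels, sample_rate=rate, annotations=annotations)


def save_recording(rec: Recording, path, annotation_path=None) -> None:
    """Write a recording (and optionally its annotations) as delimited text."""
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame({"time_s": t})
    for name, row in zip(RECORDING_COLUMNS[1:], rec.channels):
        df[name] = row
    df.to_csv(path, index=False, float_format="%.6f")
    if annotation_path is not None:
        adf = pd.DataFrame(
            {
                "start_s": [ev.start_s for ev in rec.annotations],
                "end_s": [ev.end_s for ev in rec.annotations],
                "label": [ev.label for ev in rec.annotations],
            }
        )
        adf.to_csv(annotation_path, index=False)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def window_length(sample_rate: float = DEFAULT_SAMPLE_RATE,
                  window_seconds: float = DEFAULT_WINDOW_SECONDS) -> int:
    """Samples per analysis window: round(window_seconds * sample_rate)."""
    return int(round(window_seconds * sample_rate))


def segment_windows(rec: Recording,
                    window_seconds: float = DEFAULT_WINDOW_SECONDS) -> list[list[Window]]:
    """Tile each axis into non-overlapping windows; drop the partial tail.

    Returns a list of six lists (one per axis); window k of an axis covers
    samples [L*k, L*(k+1)) where L = round(window_seconds * sample_rate).
    """
    L = window_length(rec.sample_rate, window_seconds)
    n_win = rec.n_samples // L
    if n_win == 0:
        raise DegenerateInputError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"window ({L} samples)"
        )
    out: list[list[Window]] = []
    for axis in range(6):
        axis_windows = [
            Window(
                samples=rec.channels[axis, L * k: L * (k + 1)].copy(),
                axis_index=axis,
                window_index=k,
                start_s=L * k / rec.sample_rate,
            )
            for k in range(n_win)
        ]
        out.append(axis_windows)
    return out


def window_array(rec: Recording,
                 window_seconds: float = DEFAULT_WINDOW_SECONDS) -> np.ndarray:
    """Vectorized windowing: array of shape (6, n_windows, L)."""
    L = window_length(rec.sample_rate, window_seconds)
    n_win = rec.n_samples // L
    if n_win == 0:
        raise DegenerateInputError("recording shorter than one window")
    return rec.channels[:, : n_win * L].reshape(6, n_win, L)


# ---------------------------------------------------------------------------
# DC correction and Kalman filtering
# ---------------------------------------------------------------------------

def remove_dc(samples: np.ndarray) -> np.ndarray:
    """First-difference DC correction: out[k] = in[k] - in[k-1], out[0] = 0."""
    x = np.asarray(samples, dtype=float)
    out = np.empty_like(x)
    out[..., 0] = 0.0
    out[..., 1:] = np.diff(x, axis=-1)
    return out


def kalman_gains(n: int, p: KalmanParams) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the gain and error-variance sequences (data independent).

    For the scalar filter the Riccati recursion does not depend on the
    measurements, so gains can be computed once and reused across windows:
    P- = A^2 P + Q;  K = P- H / (H^2 P- + R);  P = (1 - K H) P-.
    """
    P = p.R if p.P0 is None else p.P0
    K = np.empty(n)
    Pout = np.empty(n)
    for k in range(n):
        P_pred = p.A * p.A * P + p.Q
        K[k] = P_pred * p.H / (p.H * p.H * P_pred + p.R)
        P = (1.0 - K[k] * p.H) * P_pred
        Pout[k] = P
    return K, Pout


def kalman_filter(samples: np.ndarray, p: KalmanParams) -> np.ndarray:
    """Scalar predict/update Kalman recursion over one window.

    Accepts a 1-D window or a 2-D batch (windows in rows, identical
    parameters); returns the sequence of updated state estimates.
    """
    y = np.asarray(samples, dtype=float)
    squeeze = y.ndim == 1
    Y = np.atleast_2d(y)
    n = Y.shape[1]
    K, _ = kalman_gains(n, p)
    x = np.full(Y.shape[0], p.x0, dtype=float) if p.x0 is not None else Y[:, 0].astype(float)
    out = np.empty_like(Y)
    for k in range(n):
        x_pred = p.A * x
        x = x_pred + K[k] * (Y[:, k] - p.H * x_pred)
        out[:, k] = x
    return out[0] if squeeze else out


def estimate_measurement_noise(rec: Recording,
                               window_seconds: float = DEFAULT_WINDOW_SECONDS) -> float:
    """Estimate R from the differenced first window (a quiet baseline).

    The variance is pooled across the six axes of the first window of the
    recording; the filter operates on differenced samples, so the estimate is
    taken in the increment domain.
    """
    L = window_length(rec.sample_rate, window_seconds)
    first = rec.channels[:, :L]
    d = remove_dc(first)[:, 1:]  # drop the anchored zero
    r = float(np.var(d))
    if r <= 0:
        r = 1e-12
    return r


#: Length of the centered moving-average baseline estimate, in samples
#: (1 s at the default rate). The moving average has spectral nulls at
#: integer multiples of 1 Hz, so subtracting it removes respiration and
#: baseline wander (< ~0.5 Hz) while passing the 2-10 Hz FM band nearly
#: unchanged.
DEFAULT_BASELINE_SAMPLES = 100


def moving_average(x: np.ndarray, k: int) -> np.ndarray:
    """Centered moving average along the last axis with edge-corrected spans."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    zeros = np.zeros(x.shape[:-1] + (1,))
    c = np.cumsum(np.concatenate([zeros, x], axis=-1), axis=-1)
    half = k // 2
    hi = np.minimum(np.arange(n) + (k - half), n)
    lo = np.maximum(np.arange(n) - half, 0)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def preprocess_window(samples: np.ndarray, p: KalmanParams,
                      baseline_samples: int = DEFAULT_BASELINE_SAMPLES) -> np.ndarray:
    """Full preprocessing chain: difference -> Kalman -> reintegrate -> detrend.

    The differenced, Kalman-smoothed increments are cumulatively summed back
    to the signal scale, then the window's slow baseline (centered moving
    average of ``baseline_samples``) is subtracted. The output is the
    denoised window with DC offset and respiration-band wander removed:
    peak amplitudes measure deviation from the local baseline, on the
    physical g scale the gate thresholds expect.
    """
    d = remove_dc(samples)
    f = kalman_filter(d, KalmanParams(p.A, p.H, p.Q, p.R, x0=0.0, P0=p.P0))
    out = np.cumsum(f, axis=-1)
    return out - moving_average(out, baseline_samples)


def preprocess_recording(rec: Recording,
                         p: KalmanParams | None = None,
                         window_seconds: float = DEFAULT_WINDOW_SECONDS) -> np.ndarray:
    """Preprocess every window of every axis; returns (6, n_windows, L).

    When ``p`` is None, R is estimated from the recording's first window and
    the remaining parameters take their defaults.
    """
    if p is None:
        p = KalmanParams(R=estimate_measurement_noise(rec, window_seconds))
    W = window_array(rec, window_seconds)
    six, n_win, L = W.shape
    flat = W.reshape(six * n_win, L)
    k = max(1, int(round(DEFAULT_BASELINE_SAMPLES / DEFAULT_SAMPLE_RATE * rec.sample_rate)))
    return preprocess_window(flat, p, baseline_samples=k).reshape(six, n_win, L)
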