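"""Per-axis FM / non-FM classification of gated candidate windows.

Two interchangeable detectors are provided, both comparing how well a window
is explained by the FM dictionary D1 versus the non-FM dictionary D2:

* OMP residual comparison: the window is sparse-coded against each
  dictionary independently (sparsity T0, default 3) and labelled with the
  class whose reconstruction error is smaller.

* LMS adaptive filtering: for every atom of both dictionaries an FIR filter
  with M taps is adapted by the least-mean-squares recursion

      r_hat(n) = sum_m w_m(n) r(n-m),    e(n) = d(n) - r_hat(n),
      w_m(n+1) = w_m(n) + 2 mu e(n) r(n-m),

  with the window as the desired signal d and the atom as the filter input
  r (samples before index 0 are zero). Epoch passes repeat until the
  epoch-mean squared error stops changing by more than ``tol`` or
  ``max_epochs`` is reached; the per-class error is the minimum final MSE
  over that class's atoms.

Windows are mean-removed and unit-normalized before either detector runs,
so classification is scale invariant. Ties (err_fm == err_nonfm) resolve to
NON_FM: a conservative choice that avoids false positives.

The LMS filter weights start at the identity tap [1, 0, ..., 0], i.e. from
the hypothesis that the reference atom already matches the window; a perfect
match therefore yields zero error immediately, and adaptation only moves the
weights when the atom and window genuinely differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dictionary_learning import (
    DEFAULT_T0,
    FeatureDictionary,
    normalize_signal,
    _omp_column,
)
from .errors import InstabilityError, ParameterError

#: Epoch-mean squared error above which LMS is declared divergent.
LMS_DIVERGENCE_MSE = 1e6


class Label(str, Enum):
    FM = "FM"
    NON_FM = "NON_FM"


@dataclass
class LmsParams:
    """LMS adaptive-filter settings (tap count M, step size mu, stopping)."""

    M: int = 8
    mu: float = 0.05
    max_epochs: int = 100
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ParameterError(f"filter order M must be >= 1, got {self.M}")
        if self.mu <= 0:
            raise ParameterError(f"step size mu must be > 0, got {self.mu}")


@dataclass
class AxisDecision:
    """Outcome of classifying one axis's window."""

    axis_index: int
    label: Label
    err_fm: float
    err_nonfm: float
    method: str  # "OMP" or "LMS"


def _decide(err_fm: float, err_nonfm: float) -> Label:
    """FM iff strictly smaller FM error; ties resolve to NON_FM."""
    return Label.FM if err_fm < err_nonfm else Label.NON_FM


def _check_dictionaries(y: np.ndarray, D1: FeatureDictionary, D2: FeatureDictionary) -> None:
    if D1.m != D2.m or D1.m != y.shape[-1]:
        raise ParameterError(
            f"dictionary/window length mismatch: window {y.shape[-1]}, "
            f"D1 {D1.m}, D2 {D2.m}"
        )
    labels = {D1.class_label, D2.class_label}
    if labels != {"FM", "NON_FM"}:
        raise ParameterError(
            f"expected one FM and one NON_FM dictionary, got labels {labels}"
        )


def _fm_first(D1: FeatureDictionary, D2: FeatureDictionary):
    """Return (FM dictionary, non-FM dictionary) regardless of argument order."""
    return (D1, D2) if D1.class_label == "FM" else (D2, D1)


# ---------------------------------------------------------------------------
# OMP detector
# ---------------------------------------------------------------------------

def omp_classify(y: np.ndarray, D1: FeatureDictionary, D2: FeatureDictionary,
                 T0: int = DEFAULT_T0, axis_index: int = 0) -> AxisDecision:
    """Dual-dictionary sparse classification by reconstruction-error comparison."""
    y = np.asarray(y, dtype=float)
    _check_dictionaries(y, D1, D2)
    d_fm, d_nonfm = _fm_first(D1, D2)
    yn = normalize_signal(y)
    _, _, r_fm = _omp_column(d_fm.D, yn, T0)
    _, _, r_nonfm = _omp_column(d_nonfm.D, yn, T0)
    err_fm = float(np.linalg.norm(r_fm))
    err_nonfm = float(np.linalg.norm(r_nonfm))
    return AxisDecision(axis_index, _decide(err_fm, err_nonfm), err_fm, err_nonfm, "OMP")


# ---------------------------------------------------------------------------
# LMS detector
# ---------------------------------------------------------------------------

def _lms_batch(d: np.ndarray, refs: np.ndarray, p: LmsParams) -> np.ndarray:
    """Run the LMS recursion for many reference signals against one target.

    ``refs`` has one reference per row. All filters share the target ``d``
    and parameters; each row's final epoch-mean squared error is returned.
    Filters whose MSE change falls below ``tol`` are frozen (their weights
    stop adapting), which is equivalent to stopping them individually.
    """
    d = np.asarray(d, dtype=float)
    refs = np.atleast_2d(np.asarray(refs, dtype=float))
    A, N = refs.shape
    if d.shape != (N,):
        raise ParameterError(
            f"desired signal length {d.shape} does not match reference length {N}"
        )
    M = min(p.M, N)
    # tapped-delay tensor: delays[a, n, m] = refs[a, n - m], zero for n < m
    delays = np.zeros((A, N, M))
    for m in range(M):
        delays[:, m:, m] = refs[:, : N - m]

    w = np.zeros((A, M))
    w[:, 0] = 1.0  # identity-tap initialization
    active = np.ones(A, dtype=bool)
    prev_mse = np.full(A, np.inf)
    mse = np.full(A, np.inf)
    two_mu = 2.0 * p.mu
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(p.max_epochs):
            e_sq = np.zeros(A)
            act = active.astype(float)[:, None]
            for n in range(N):
                x = delays[:, n, :]
                e = d[n] - np.einsum("am,am->a", w, x)
                w += two_mu * (e[:, None] * x) * act
                e_sq += e * e
            mse = e_sq / N
            if np.any(~np.isfinite(mse)) or np.any(mse > LMS_DIVERGENCE_MSE):
                raise InstabilityError(
                    "LMS diverged (MSE > 1e6); try a smaller step size mu"
                )
            converged = active & (np.abs(prev_mse - mse) < p.tol)
            active &= ~converged
            prev_mse = mse.copy()
            if not active.any():
                break
    return mse, w


def lms_fit(d: np.ndarray, r: np.ndarray, p: LmsParams = LmsParams(),
            return_weights: bool = False):
    """Adapt one LMS filter matching reference ``r`` to target ``d``.

    Returns the mean of e(n)^2 over the final epoch pass; with
    ``return_weights`` also the final tap-weight vector.
    """
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise ParameterError("d and r must be 1-D signals of equal length")
    mse, w = _lms_batch(d, r[None, :], p)
    if return_weights:
        return float(mse[0]), w[0]
    return float(mse[0])


def lms_classify(y: np.ndarray, D1: FeatureDictionary, D2: FeatureDictionary,
                 p: LmsParams = LmsParams(), axis_index: int = 0) -> AxisDecision:
    """Adaptive-filter classification over every atom of both dictionaries.

    The per-class error is the minimum final MSE over that class's atoms;
    the label is the class with the smaller error (ties to NON_FM).
    """
    y = np.asarray(y, dtype=float)
    _check_dictionaries(y, D1, D2)
    d_fm, d_nonfm = _fm_first(D1, D2)
    yn = normalize_signal(y)
    refs = np.concatenate([d_fm.D.T, d_nonfm.D.T], axis=0)
    mse, _w = _lms_batch(yn, refs, p)
    err_fm = float(np.min(mse[: d_fm.n]))
    err_nonfm = float(np.min(mse[d_fm.n:]))
    return AxisDecision(axis_index, _decide(err_fm, err_nonfm), err_fm, err_nonfm, "LMS")
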