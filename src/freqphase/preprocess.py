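"""Temporal preprocessing of BOLD-like time series.

The correlogram stage assumes zero-mean, unit-variance, band-limited input.
This module provides the minimal chain that takes an arbitrary series there:
confound regression, linear detrending, band-pass filtering to the
resting-state band (0.01–0.1 Hz by default) and standardization.

The fixed order of the full chain is: confound regression → detrend →
band-pass → standardize.  Variance is computed with ddof 0 throughout, so
that the zero-lag value of the cross-correlogram of two standardized series
equals their Pearson correlation coefficient exactly, not asymptotically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "TimeSeries",
    "detrend_linear",
    "regress_confounds",
    "bandpass",
    "standardize",
    "preprocess",
]

DEFAULT_BAND = (0.01, 0.1)


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    values : array-like of float
        The signal, in arbitrary units.  Must be finite; length >= 3.
    tr : float
        Sampling interval (repetition time) in seconds; must be positive.
    """

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError(f"TimeSeries values must be 1-D, got shape {vals.shape}")
        if vals.size < 3:
            raise ValueError(f"TimeSeries needs at least 3 time points, got {vals.size}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries values must be finite (no NaN/inf)")
        if not (self.tr > 0):
            raise ValueError(f"tr must be positive, got {self.tr}")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times 0, tr, ..., (n-1)*tr in seconds."""
        return np.arange(self.n) * self.tr

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(values=values, tr=self.tr)


# ---------------------------------------------------------------------------
# column-wise (vectorized) primitives used by both the scalar API and the
# volumetric pipeline; X has shape (n_timepoints, n_series)
# ---------------------------------------------------------------------------

def _detrend_cols(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ coef


def _bandpass_cols(X: np.ndarray, tr: float, f_lo: float, f_hi: float) -> np.ndarray:
    n = X.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr)
    # inclusive band edges; tiny tolerance keeps bin-aligned edges inside
    keep = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    spec = np.fft.rfft(X, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def _bandpass_cols_butter(X: np.ndarray, tr: float, f_lo: float, f_hi: float,
                          order: int = 4) -> np.ndarray:
    nyq = 0.5 / tr
    lo = max(f_lo, 1e-6) / nyq
    hi = f_hi / nyq
    sos = _signal.butter(order, [lo, hi], btype="band", output="sos")
    return _signal.sosfiltfilt(sos, X, axis=0)


def _standardize_cols(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean and scale columns to unit ddof-0 variance.

    Returns (standardized, valid) where ``valid`` flags columns with positive
    variance; invalid columns are returned as zeros.
    """
    mu = X.mean(axis=0)
    centered = X - mu
    sd = centered.std(axis=0, ddof=0)
    valid = sd > 0
    out = np.zeros_like(centered)
    out[:, valid] = centered[:, valid] / sd[valid]
    return out, valid


# ---------------------------------------------------------------------------
# public single-series operations
# ---------------------------------------------------------------------------

def detrend_linear(ts: TimeSeries) -> TimeSeries:
    """Remove the best-fitting affine trend (intercept + linear ramp).

    The returned values are the ordinary-least-squares residuals of the
    series regressed on [1, t]; their mean is zero to machine precision.
    """
    return ts.with_values(_detrend_cols(ts.values[:, None])[:, 0])


def regress_confounds(ts: TimeSeries, confounds: np.ndarray) -> TimeSeries:
    """Project out nuisance regressors (plus an implicit intercept).

    Parameters
    ----------
    confounds : ndarray, shape (n, k)
        One column per nuisance regressor (e.g. motion parameters, CSF/WM
        principal components), rows aligned with the time points.

    The residual is orthogonal to every confound column.  A rank-deficient
    confound matrix (after adding the intercept) raises ``ValueError`` naming
    the offending columns.
    """
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != ts.n:
        raise ValueError(
            f"confound rows ({C.shape[0]}) must equal series length ({ts.n})")
    design = np.column_stack([np.ones(ts.n), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that do not increase rank when added left-to-right
        bad: list[int] = []
        r = 0
        acc = np.empty((ts.n, 0))
        for j in range(design.shape[1]):
            trial = np.column_stack([acc, design[:, j]])
            tr_rank = np.linalg.matrix_rank(trial)
            if tr_rank == r:
                if j > 0:  # column 0 is the intercept we added
                    bad.append(j - 1)
            else:
                acc = trial
                r = tr_rank
        raise ValueError(
            f"confound matrix is rank deficient; redundant column indices: {bad}")
    coef, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ coef)


def bandpass(ts: TimeSeries, f_lo: float = DEFAULT_BAND[0],
             f_hi: float = DEFAULT_BAND[1], kind: str = "ideal") -> TimeSeries:
    """Band-pass filter by an ideal DFT mask (default) or zero-phase Butterworth.

    The ideal filter zeroes every discrete-Fourier bin with frequency
    strictly below ``f_lo`` or above ``f_hi`` (band edges inclusive) and
    leaves in-band bins untouched, so bin-aligned sinusoids pass unaltered.
    """
    nyq = 0.5 / ts.tr
    if not (0 <= f_lo < f_hi):
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi > nyq + 1e-12:
        raise ValueError(f"f_hi={f_hi} Hz exceeds Nyquist {nyq} Hz at tr={ts.tr}")
    if kind == "ideal":
        out = _bandpass_cols(ts.values[:, None], ts.tr, f_lo, f_hi)[:, 0]
    elif kind == "butterworth":
        out = _bandpass_cols_butter(ts.values[:, None], ts.tr, f_lo, f_hi)[:, 0]
    else:
        raise ValueError(f"unknown band-pass kind {kind!r}")
    return ts.with_values(out)


def standardize(ts: TimeSeries) -> TimeSeries:
    """Rescale to mean 0 and ddof-0 variance 1.

    Raises ``ValueError`` on zero-variance input: a constant series carries
    no fluctuation and its correlogram is undefined.
    """
    out, valid = _standardize_cols(ts.values[:, None])
    if not valid[0]:
        raise ValueError("zero-variance series cannot be standardized; "
                         "its correlation with anything is undefined")
    return ts.with_values(out[:, 0])


def preprocess(ts: TimeSeries, confounds: np.ndarray | None = None,
               f_lo: float = DEFAULT_BAND[0], f_hi: float = DEFAULT_BAND[1],
               detrend: bool = True, filter_kind: str = "ideal") -> TimeSeries:
    """Full chain: confound regression → detrend → band-pass → standardize."""
    if confounds is not None:
        ts = regress_confounds(ts, confounds)
    if detrend:
        ts = detrend_linear(ts)
    ts = bandpass(ts, f_lo, f_hi, kind=filter_kind)
    return standardize(ts)
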