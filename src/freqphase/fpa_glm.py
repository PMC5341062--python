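"""Windowed cosine/sine general linear model of the correlogram.

The heart of the frequency-phase analysis: a correlogram CC(l) on the
symmetric lag grid is regressed, without intercept, on 2K tapered
regressors

    c_k(l) = cos(2*pi*f_k*l) * B(l)      (symmetric,  weight beta_k)
    s_k(l) = sin(2*pi*f_k*l) * B(l)      (antisymmetric, weight gamma_k)

with l in seconds and B the window (Bartlett by default, endpoint-zero).
The default four frequencies 0.02, 0.04, 0.06, 0.08 Hz tile the
resting-state band, giving the canonical 8-regressor design on the
41-point ±40 s grid.

Because cosine columns are even in lag and sine columns odd, an even
correlogram yields gamma == 0 and an odd one beta == 0 exactly: the fit
separates in-phase from 90°-out-of-phase structure by construction.

Goodness of fit is summarized by the uncentered coefficient of
determination R² = 1 − SS_res/Σ CC² and the corresponding F statistic
(R²/p) / ((1−R²)/(n_lags−p)) with p = 2K regressors and no intercept,
so that under white-noise input F follows F(p, n_lags − p) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .crosscorr import CrossCorrelogram, LagGrid

__all__ = [
    "DEFAULT_FREQS",
    "BasisSet",
    "FPAWeights",
    "make_window",
    "build_basis",
    "fit_fpa",
    "basis_gains",
]

DEFAULT_FREQS = (0.02, 0.04, 0.06, 0.08)
WINDOW_KINDS = ("bartlett", "hann", "rectangular")
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class BasisSet:
    """Design matrix of windowed cosines then sines on a lag grid."""

    freqs: np.ndarray
    window_kind: str
    design: np.ndarray          # (n_lags, 2*K): [cos_1..cos_K, sin_1..sin_K]
    grid: LagGrid
    window: np.ndarray          # B(l) per lag

    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    @property
    def n_regressors(self) -> int:
        return 2 * self.n_freqs


@dataclass(frozen=True)
class FPAWeights:
    """Fitted weights of one connection: K symmetric + K antisymmetric scalars.

    ``betas[k]`` weights cos(2π f_k l)·B(l) (in-phase content at f_k),
    ``gammas[k]`` weights sin(2π f_k l)·B(l) (90°-out-of-phase content).
    Both are in correlation units.  ``f_stat``/``r_squared`` summarize the
    no-intercept fit with ``dof`` = (p, n_lags − p).
    """

    betas: np.ndarray
    gammas: np.ndarray
    f_stat: float
    r_squared: float
    dof: Tuple[int, int]

    @property
    def stacked(self) -> np.ndarray:
        """All weights in design order [beta_1..K, gamma_1..K]."""
        return np.concatenate([self.betas, self.gammas])

    def predict(self, basis: BasisSet) -> np.ndarray:
        """Fitted correlogram on the basis grid."""
        return basis.design @ self.stacked


def make_window(kind: str, grid: LagGrid) -> np.ndarray:
    """Even taper over the lag grid, value 1 at lag zero.

    bartlett: 1 − |l|/L_max (0 at the grid ends); hann: 0.5·(1 + cos(π l/L_max));
    rectangular: all ones.  L_max is the grid's largest lag in seconds.
    """
    if kind not in WINDOW_KINDS:
        raise ValueError(f"unknown window kind {kind!r}; choose from {WINDOW_KINDS}")
    l = grid.lags_seconds
    l_max = grid.max_lag_seconds
    if kind == "rectangular" or l_max == 0:
        return np.ones(grid.n_lags)
    if kind == "bartlett":
        return 1.0 - np.abs(l) / l_max
    return 0.5 * (1.0 + np.cos(np.pi * l / l_max))


def build_basis(freqs: Sequence[float] = DEFAULT_FREQS, grid: LagGrid | None = None,
                window_kind: str = "bartlett") -> BasisSet:
    """Assemble the windowed Fourier design matrix and verify its rank."""
    if grid is None:
        raise ValueError("a LagGrid is required")
    f = np.asarray(freqs, dtype=float)
    if f.size < 1:
        raise ValueError("at least one frequency is required")
    nyq = 0.5 / grid.tr
    if np.any(f >= nyq) or np.any(f <= 0):
        raise ValueError(f"frequencies must lie in (0, {nyq}) Hz for tr={grid.tr}")
    B = make_window(window_kind, grid)
    l = grid.lags_seconds
    phases = 2.0 * np.pi * np.outer(l, f)          # (n_lags, K)
    design = np.concatenate([np.cos(phases), np.sin(phases)], axis=1) * B[:, None]
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ValueError(
            f"design matrix is rank deficient or ill-conditioned (cond={cond:.3g}); "
            "check for duplicate frequencies or a lag range too short to "
            "distinguish them")
    return BasisSet(freqs=f, window_kind=window_kind, design=design,
                    grid=grid, window=B)


def _fit_matrix(basis: BasisSet) -> np.ndarray:
    """Pseudo-inverse of the design, for batched OLS."""
    return np.linalg.pinv(basis.design)


def _summaries(CC: np.ndarray, fitted: np.ndarray, p: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Uncentered R² and F for columns of CC; degenerate columns get R²=0, F=0."""
    ss_tot = np.sum(CC ** 2, axis=0)
    ss_res = np.sum((CC - fitted) ** 2, axis=0)
    n = CC.shape[0]
    dof2 = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        f = np.where(r2 < 1.0, (r2 / p) / ((1.0 - r2) / dof2), np.inf)
        f = np.where(np.asarray(ss_tot) > 0, f, 0.0)
    return r2, f


def fit_fpa(cc: CrossCorrelogram, basis: BasisSet) -> FPAWeights:
    """Ordinary least squares of the correlogram on the windowed basis.

    No intercept is included: correlograms of band-passed zero-mean signals
    carry no DC term, and the model is fully described by the 2K weights.
    """
    if cc.grid is not basis.grid and not np.array_equal(
            cc.grid.lags_samples, basis.grid.lags_samples):
        raise ValueError("correlogram and basis are on different lag grids")
    p = basis.n_regressors
    n = basis.grid.n_lags
    if n <= p:
        raise ValueError(f"need more lags ({n}) than regressors ({p})")
    w = _fit_matrix(basis) @ cc.values
    fitted = basis.design @ w
    r2, f = _summaries(cc.values[:, None], fitted[:, None], p)
    K = basis.n_freqs
    return FPAWeights(betas=w[:K], gammas=w[K:], f_stat=float(f[0]),
                      r_squared=float(r2[0]), dof=(p, n - p))


def basis_gains(basis: BasisSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency gain of the fit for unit-amplitude connections.

    Because the regressors are tapered but a pure sinusoidal correlogram is
    not, the no-intercept OLS assigns a unit connection a weight larger
    than 1 by a deterministic factor (about 1.6 on the standard grid).
    These factors — the fit of cos/sin(2*pi*f_k*l) alone, read at their own
    coefficient — let callers convert raw weights to calibrated amplitudes.
    """
    P = _fit_matrix(basis)
    l = basis.grid.lags_seconds
    K = basis.n_freqs
    gain_cos = np.empty(K)
    gain_sin = np.empty(K)
    for k, f in enumerate(basis.freqs):
        gain_cos[k] = (P @ np.cos(2.0 * np.pi * f * l))[k]
        gain_sin[k] = (P @ np.sin(2.0 * np.pi * f * l))[K + k]
    return gain_cos, gain_sin


def fit_fpa_many(CC: np.ndarray, basis: BasisSet
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched fit over correlogram columns.

    Parameters
    ----------
    CC : ndarray, shape (n_lags, m)

    Returns
    -------
    betas : (m, K), gammas : (m, K), f_stat : (m,), r_squared : (m,)
    """
    p = basis.n_regressors
    n = basis.grid.n_lags
    if CC.shape[0] != n:
        raise ValueError(f"CC rows ({CC.shape[0]}) must equal grid size ({n})")
    if n <= p:
        raise ValueError(f"need more lags ({n}) than regressors ({p})")
    W = _fit_matrix(basis) @ CC                    # (2K, m)
    fitted = basis.design @ W
    r2, f = _summaries(CC, fitted, p)
    K = basis.n_freqs
    return W[:K].T, W[K:].T, f, r2
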