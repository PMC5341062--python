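"""Phase-differences, time-delays and connection typing from fitted weights.

At each basis frequency the pair (beta_k, gamma_k) is a Cartesian
representation of the connection's complex amplitude:

    amplitude_k = sqrt(beta_k^2 + gamma_k^2)
    phase_k     = atan2(gamma_k, beta_k)            in (-180, 180] degrees
    delay_k     = (phase_k / 360) / f_k             in seconds

With the correlogram sign convention (positive lag = target lags seed),
a POSITIVE phase means the TARGET series lags the SEED.  Swapping the
pair order negates all phases and delays and leaves amplitudes unchanged.

Connections are typed per frequency from per-weight significance flags:
symmetric (in-phase; only beta significant), antisymmetric (90°
out-of-phase; only gamma), asymmetric (any other phase; both), or none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fpa_glm import FPAWeights

__all__ = [
    "PhaseSpectrum",
    "ConnectionClass",
    "phase_spectrum",
    "delay_from_phase",
    "approx_pearson",
    "classify_connection",
]

AMPLITUDE_EPS = 1e-12
LABELS = ("symmetric", "antisymmetric", "asymmetric", "none")


@dataclass(frozen=True)
class PhaseSpectrum:
    """Per-frequency amplitude (correlation units), phase (deg) and delay (s).

    ``defined`` flags frequencies whose amplitude exceeds the degeneracy
    threshold; where it is False, phase and delay are NaN, not zero.
    """

    freqs: np.ndarray
    amplitude: np.ndarray
    phase_deg: np.ndarray
    delay_seconds: np.ndarray
    defined: np.ndarray


@dataclass(frozen=True)
class ConnectionClass:
    """Per-frequency connection-type labels with the flags that produced them."""

    labels: tuple
    sig_beta: np.ndarray
    sig_gamma: np.ndarray


def phase_spectrum(w: FPAWeights, freqs: Sequence[float]) -> PhaseSpectrum:
    """Convert fitted weights into per-frequency amplitude/phase/delay."""
    f = np.asarray(freqs, dtype=float)
    if f.size != w.betas.size:
        raise ValueError(
            f"{f.size} frequencies but {w.betas.size} symmetric weights")
    amp = np.hypot(w.betas, w.gammas)
    defined = amp >= AMPLITUDE_EPS
    phase = np.degrees(np.arctan2(w.gammas, w.betas))
    # atan2 returns (-180, 180]; map exact -180 to +180 for the half-open range
    phase = np.where(np.isclose(phase, -180.0), 180.0, phase)
    phase = np.where(defined, phase, np.nan)
    with np.errstate(invalid="ignore"):
        delay = (phase / 360.0) / f
    return PhaseSpectrum(freqs=f, amplitude=amp, phase_deg=phase,
                         delay_seconds=delay, defined=defined)


def delay_from_phase(phase_deg: float, freq: float) -> float:
    """Time delay in seconds of a phase offset at one frequency.

    delay = (phase/360)/f:  90° at 0.02 Hz is 12.5 s (a quarter of a 50 s
    cycle), 180° at 0.02 Hz is 25 s, 34° at 0.02 Hz is 4.7 s.
    """
    if not (freq > 0):
        raise ValueError(f"frequency must be positive, got {freq}")
    return (phase_deg / 360.0) / freq


def approx_pearson(w: FPAWeights) -> float:
    """Pearson correlation approximated by the in-phase content at lag zero.

    Every window equals 1 at lag 0 and every sine vanishes there, so the
    fitted correlogram at lag 0 is just the sum of the symmetric weights.
    """
    return float(np.sum(w.betas))


def classify_connection(sig_beta: Sequence[bool],
                        sig_gamma: Sequence[bool]) -> ConnectionClass:
    """Type each frequency from per-weight significance flags."""
    sb = np.asarray(sig_beta, dtype=bool)
    sg = np.asarray(sig_gamma, dtype=bool)
    if sb.shape != sg.shape:
        raise ValueError("sig_beta and sig_gamma must have equal length")
    labels = []
    for b, g in zip(sb, sg):
        if b and g:
            labels.append("asymmetric")
        elif b:
            labels.append("symmetric")
        elif g:
            labels.append("antisymmetric")
        else:
            labels.append("none")
    return ConnectionClass(labels=tuple(labels), sig_beta=sb, sig_gamma=sg)
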