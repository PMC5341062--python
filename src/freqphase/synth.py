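"""Synthetic signals and datasets with known frequency/phase structure.

A band-limited zero-mean signal is modelled as a finite Fourier sum

    x(t) = sum_k a_k cos(2 pi f_k t) + b_k sin(2 pi f_k t)

with frequencies restricted to DFT bins of the record (integer multiples
of 1/(n*tr)).  Under unit-variance normalization, sum_k (a_k^2+b_k^2)/2 = 1,
the circular correlogram of two such signals has the closed form

    CC(l) = sum_k (1/2) [ (a_i a_j + b_i b_j) cos(2 pi f_k l)
                        + (a_i b_j - b_i a_j) sin(2 pi f_k l) ]

which serves as the exact analytic oracle for the whole pipeline: the
in-phase coefficient products drive the even (symmetric) part of the
correlogram and the quadrature products drive the odd (antisymmetric)
part.  The 1/2 factor is fixed by CC(0) = 1 for identical normalized
signals.

Only bin-aligned generator frequencies are accepted so that circular-mode
correlograms match the closed form to machine precision rather than
asymptotically.

``synth_dataset`` arranges such pairs in a small 3-D geometry (a seed
block plus planted target blocks with controlled phase offsets, embedded
in noise) across multiple simulated subjects — the test bed for the
seed-map pipeline.  Noise is white Gaussian band-passed to the analysis
band, so voxel series resemble temporally preprocessed resting-state data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .crosscorr import CrossCorrelogram, LagGrid
from .preprocess import DEFAULT_BAND, TimeSeries, _bandpass_cols

__all__ = [
    "FourierCoefficients",
    "Component",
    "SyntheticSpec",
    "PlantedBlock",
    "DatasetSpec",
    "SyntheticDataset",
    "synthesize",
    "analytic_cc",
    "synth_pair",
    "synth_dataset",
]

_BIN_TOL = 1e-9


def _check_bin_aligned(freqs: np.ndarray, n: int, tr: float) -> None:
    cycles = freqs * n * tr
    if np.any(np.abs(cycles - np.round(cycles)) > _BIN_TOL):
        raise ValueError(
            f"frequencies {freqs} are not DFT-bin aligned for a record of "
            f"{n} x {tr} s = {n * tr} s; bin spacing is {1.0 / (n * tr):.6g} Hz")


@dataclass(frozen=True)
class FourierCoefficients:
    """Cosine/sine coefficients at DFT-bin-aligned frequencies."""

    freqs: np.ndarray
    a: np.ndarray
    b: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if not (f.shape == a.shape == b.shape):
            raise ValueError("freqs, a, b must have equal shapes")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        for name, arr in (("freqs", f), ("a", a), ("b", b)):
            object.__setattr__(self, name, arr)

    @property
    def implied_variance(self) -> float:
        return float(np.sum(self.a ** 2 + self.b ** 2) / 2.0)

    @staticmethod
    def from_amp_phase(freqs: Sequence[float], amplitudes: Sequence[float],
                       phases_deg: Sequence[float], normalize: bool = True
                       ) -> "FourierCoefficients":
        """Build coefficients for sum_k A_k cos(2 pi f_k t - phi_k).

        A positive phase delays the waveform in time.  With ``normalize``
        the amplitudes are rescaled so the implied variance is 1.
        """
        f = np.asarray(freqs, dtype=float)
        A = np.asarray(amplitudes, dtype=float)
        phi = np.radians(np.asarray(phases_deg, dtype=float))
        if normalize:
            power = np.sum(A ** 2) / 2.0
            if power <= 0:
                raise ValueError("cannot normalize all-zero amplitudes")
            A = A / np.sqrt(power)
        return FourierCoefficients(freqs=f, a=A * np.cos(phi), b=A * np.sin(phi),
                                   normalized=normalize)


def synthesize(coef: FourierCoefficients, n: int, tr: float) -> TimeSeries:
    """Evaluate the Fourier sum at t = 0, tr, ..., (n-1)*tr."""
    _check_bin_aligned(coef.freqs, n, tr)
    t = np.arange(n) * tr
    phases = 2.0 * np.pi * np.outer(t, coef.freqs)
    vals = np.cos(phases) @ coef.a + np.sin(phases) @ coef.b
    if coef.normalized:
        var = vals.var(ddof=0)
        if abs(var - 1.0) > 1e-8:
            raise ValueError(
                f"normalized coefficients produced variance {var:.6g}; "
                "check for duplicate or aliased frequencies")
    return TimeSeries(values=vals, tr=tr)


def analytic_cc(coef_i: FourierCoefficients, coef_j: FourierCoefficients,
                grid: LagGrid) -> CrossCorrelogram:
    """Closed-form circular correlogram of two normalized Fourier signals."""
    if not np.allclose(coef_i.freqs, coef_j.freqs):
        raise ValueError("coefficient sets must share the same frequencies")
    if not (coef_i.normalized and coef_j.normalized):
        raise ValueError("analytic correlogram requires normalized coefficients")
    l = grid.lags_seconds
    w = 2.0 * np.pi * np.outer(l, coef_i.freqs)
    even = coef_i.a * coef_j.a + coef_i.b * coef_j.b
    odd = coef_i.a * coef_j.b - coef_i.b * coef_j.a
    vals = 0.5 * (np.cos(w) @ even + np.sin(w) @ odd)
    return CrossCorrelogram(values=vals, grid=grid, source_pair=("i", "j"),
                            estimator="circular")


@dataclass(frozen=True)
class Component:
    """One shared sinusoidal component of a synthetic pair.

    ``phase_i_deg``/``phase_j_deg`` are the waveform delays of each member;
    the connection's phase-difference is phase_j - phase_i (positive:
    second member lags the first).
    """

    freq: float
    amplitude: float = 1.0
    phase_i_deg: float = 0.0
    phase_j_deg: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of one coupled pair."""

    n: int = 300
    tr: float = 2.0
    components: tuple = (Component(freq=0.02),)
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 time points")
        freqs = np.array([c.freq for c in self.components])
        _check_bin_aligned(freqs, self.n, self.tr)

    def coefficients(self) -> tuple[FourierCoefficients, FourierCoefficients]:
        freqs = [c.freq for c in self.components]
        amps = [c.amplitude for c in self.components]
        ci = FourierCoefficients.from_amp_phase(
            freqs, amps, [c.phase_i_deg for c in self.components])
        cj = FourierCoefficients.from_amp_phase(
            freqs, amps, [c.phase_j_deg for c in self.components])
        return ci, cj


def synth_pair(spec: SyntheticSpec) -> tuple[TimeSeries, TimeSeries]:
    """Two series sharing components at controlled phase offsets, plus noise."""
    ci, cj = spec.coefficients()
    x = synthesize(ci, spec.n, spec.tr)
    y = synthesize(cj, spec.n, spec.tr)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        x = x.with_values(x.values + rng.normal(0, spec.noise_sd, spec.n))
        y = y.with_values(y.values + rng.normal(0, spec.noise_sd, spec.n))
    return x, y


# ---------------------------------------------------------------------------
# volumetric datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedBlock:
    """A rectangular target block coupled to the seed at a fixed phase offset.

    ``dphase_deg`` is how far the block's signal LAGS the seed's, in degrees
    of the component cycle: 0 plants a symmetric (in-phase) connection,
    90 an antisymmetric one.
    """

    name: str
    corner: tuple
    size: tuple
    freq: float = 0.02
    amplitude: float = 1.0
    dphase_deg: float = 0.0

    def slices(self) -> tuple:
        return tuple(slice(c, c + s) for c, s in zip(self.corner, self.size))


@dataclass(frozen=True)
class DatasetSpec:
    """Geometry and signal plan for a multi-subject synthetic volume set."""

    shape: tuple = (24, 24, 12)
    n: int = 300
    tr: float = 2.0
    seed_corner: tuple = (2, 2, 3)
    seed_size: tuple = (4, 4, 4)
    blocks: tuple = ()
    noise_sd: float = 1.0
    n_subjects: int = 20
    band: tuple = DEFAULT_BAND
    voxel_size_mm: float = 3.0

    def seed_block(self) -> PlantedBlock:
        return PlantedBlock(name="seed", corner=self.seed_corner,
                            size=self.seed_size)


@dataclass(frozen=True)
class SyntheticDataset:
    """Subject volumes plus ground-truth block masks for scoring."""

    subjects: tuple                  # n_subjects arrays of shape (*shape, n)
    truth_masks: dict                # block name -> boolean 3-D mask
    spec: DatasetSpec
    affine: np.ndarray


def _check_blocks(spec: DatasetSpec) -> list[PlantedBlock]:
    blocks = [spec.seed_block(), *spec.blocks]
    occupancy = np.zeros(spec.shape, dtype=int)
    for blk in blocks:
        for c, s, dim in zip(blk.corner, blk.size, spec.shape):
            if c < 0 or c + s > dim:
                raise ValueError(f"block {blk.name!r} does not fit in {spec.shape}")
        occupancy[blk.slices()] += 1
    if occupancy.max() > 1:
        raise ValueError("planted blocks overlap")
    return blocks


def synth_dataset(spec: DatasetSpec, rng_seed: int = 0) -> SyntheticDataset:
    """Generate per-subject 4-D volumes realizing the planted connections.

    Each subject draws an independent random phase per component frequency
    for the seed waveform; target blocks reproduce it shifted by their
    planted phase offset.  Every voxel receives independent white Gaussian
    noise band-passed to the analysis band.
    """
    blocks = _check_blocks(spec)
    freqs = sorted({blk.freq for blk in blocks if blk.name != "seed"}) or [0.02]
    _check_bin_aligned(np.asarray(freqs), spec.n, spec.tr)
    rng = np.random.default_rng(rng_seed)
    t = np.arange(spec.n) * spec.tr
    n_vox = int(np.prod(spec.shape))
    subjects = []
    for _ in range(spec.n_subjects):
        seed_phase = {f: rng.uniform(0, 360) for f in freqs}
        vol = rng.normal(0.0, spec.noise_sd, size=(spec.n, n_vox))
        vol = _bandpass_cols(vol, spec.tr, *spec.band)
        vol = vol.reshape(spec.n, *spec.shape)

        def waveform(freq: float, amplitude: float, lag_deg: float) -> np.ndarray:
            phi = np.radians(seed_phase[freq] + lag_deg)
            return np.sqrt(2.0) * amplitude * np.cos(2 * np.pi * freq * t - phi)

        for blk in blocks:
            if blk.name == "seed":
                sig = sum(waveform(f, 1.0 / np.sqrt(len(freqs)), 0.0) for f in freqs)
            else:
                sig = waveform(blk.freq, blk.amplitude, blk.dphase_deg)
            vol[(slice(None), *blk.slices())] += sig[:, None, None, None]
        subjects.append(np.moveaxis(vol, 0, -1))     # (*shape, n)
    truth = {}
    for blk in blocks:
        mask = np.zeros(spec.shape, dtype=bool)
        mask[blk.slices()] = True
        truth[blk.name] = mask
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    return SyntheticDataset(subjects=tuple(subjects), truth_masks=truth,
                            spec=spec, affine=affine)
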