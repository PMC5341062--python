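"""Group-level statistics on weight maps: one-sample t and cluster correction.

Each fitted weight (beta_1..K, gamma_1..K) is tested across subjects with
a voxelwise one-sample t-test (two-sided).  Significance combines a
voxel-level p threshold with a cluster-extent threshold: suprathreshold
voxels are grouped into connected components (positive- and negative-t
voxels never merge) and components smaller than the extent threshold are
discarded.  The extent threshold may be fixed (e.g. the conventional 100
voxels) or calibrated by Monte-Carlo simulation of smooth Gaussian null
fields, AlphaSim style.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GroupSPM",
    "one_sample_t",
    "one_sample_t_map",
    "threshold_spm",
    "mc_cluster_threshold",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class GroupSPM:
    """Voxelwise group t/p maps for one weight, with surviving-cluster labels."""

    t_map: np.ndarray
    p_map: np.ndarray
    df: int
    weight_name: str
    cluster_labels: np.ndarray
    thresholds: Tuple[float, int, int]       # (voxel_p, cluster_k, connectivity)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max())


def one_sample_t(stack: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample t-test of the mean against zero.

    Returns (t, p) with t = mean/(sd/sqrt(n)), sd using ddof 1, and p the
    two-sided tail probability at df = n-1.  A zero-sd stack yields
    (nan, nan) — undefined, not infinite.
    """
    x = np.asarray(stack, dtype=float)
    if x.size < 2:
        raise ValueError(f"one-sample t needs n >= 2, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return (float("nan"), float("nan"))
    t = x.mean() / (sd / np.sqrt(x.size))
    p = 2.0 * stats.t.sf(abs(t), df=x.size - 1)
    return (float(t), float(p))


def one_sample_t_map(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-sample t over axis 0 (subjects).

    Zero-sd or NaN-containing locations get NaN t and p.
    """
    x = np.asarray(stack, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError(f"one-sample t needs n >= 2 subjects, got {n}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    p = np.full_like(t, np.nan)
    ok = np.isfinite(t)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return t, p


def _structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order)


def _label_surviving(binary: np.ndarray, structure: np.ndarray,
                     cluster_k: int) -> list[np.ndarray]:
    labels, n = ndimage.label(binary, structure=structure)
    keep = []
    if n:
        sizes = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if sizes[lab] >= cluster_k:
                keep.append(labels == lab)
    return keep


def threshold_spm(t_map: np.ndarray, df: int, voxel_p: float, cluster_k: int,
                  connectivity: int = 26, mask: np.ndarray | None = None,
                  weight_name: str = "weight",
                  affine: np.ndarray | None = None
                  ) -> tuple[GroupSPM, pd.DataFrame]:
    """Voxel-then-extent thresholding of a group t map.

    Suprathreshold voxels (two-sided p < ``voxel_p`` inside ``mask``) are
    grouped into connected components at the given connectivity, positive
    and negative t separately, and components with fewer than ``cluster_k``
    voxels are dropped.  Surviving clusters are labelled 1..m in decreasing
    size order; the companion table lists size, peak |t| and peak location
    (indices, and mm when ``affine`` is given).
    """
    t_map = np.asarray(t_map, dtype=float)
    if mask is None:
        mask = np.ones(t_map.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t_map.shape:
        raise ValueError(f"mask shape {mask.shape} != t map shape {t_map.shape}")
    if not mask.any():
        raise ValueError("analysis mask is empty")
    p_map = np.full(t_map.shape, np.nan)
    ok = mask & np.isfinite(t_map)
    p_map[ok] = 2.0 * stats.t.sf(np.abs(t_map[ok]), df=df)
    supra = ok & (p_map < voxel_p)
    structure = _structure(connectivity)
    comps = (_label_surviving(supra & (t_map > 0), structure, cluster_k)
             + _label_surviving(supra & (t_map < 0), structure, cluster_k))
    comps.sort(key=lambda m: (-int(m.sum()), tuple(np.argwhere(m)[0])))
    labels = np.zeros(t_map.shape, dtype=int)
    rows = []
    for i, comp in enumerate(comps, start=1):
        labels[comp] = i
        tvals = np.where(comp, np.abs(t_map), -np.inf)
        peak = np.unravel_index(np.argmax(tvals), t_map.shape)
        row = {"label": i, "size_voxels": int(comp.sum()),
               "peak_t": float(t_map[peak]),
               "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2]}
        if affine is not None:
            mm = affine @ np.array([*peak, 1.0])
            row.update({"peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2]})
        rows.append(row)
    table = pd.DataFrame(rows, columns=["label", "size_voxels", "peak_t",
                                        "peak_i", "peak_j", "peak_k"]
                         + (["peak_x_mm", "peak_y_mm", "peak_z_mm"]
                            if affine is not None else []))
    spm = GroupSPM(t_map=t_map, p_map=p_map, df=df, weight_name=weight_name,
                   cluster_labels=labels,
                   thresholds=(voxel_p, cluster_k, connectivity))
    return spm, table


def mc_cluster_threshold(mask: np.ndarray,
                         smoothness_fwhm_mm: float | Sequence[float] = 8.0,
                         voxel_size_mm: float | Sequence[float] = 2.0,
                         voxel_p: float = 1e-4, corrected_p: float = 0.01,
                         n_iter: int = 1000, rng_seed: int = 0,
                         connectivity: int = 26) -> int:
    """Monte-Carlo cluster-extent threshold for smooth Gaussian null fields.

    Simulates ``n_iter`` white-noise volumes, smooths each with a Gaussian
    of the given FWHM, re-standardizes within the mask, thresholds
    two-sided at ``voxel_p`` and records the largest cluster size.  Returns
    the ceiling of the (1 - corrected_p) quantile of the maximum-size null
    distribution: clusters at least this large occur with probability
    about ``corrected_p`` under the null.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a non-empty 3-D boolean volume")
    fwhm = np.broadcast_to(np.asarray(smoothness_fwhm_mm, dtype=float), (3,))
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if np.any(fwhm < 0) or np.any(vox <= 0):
        raise ValueError("FWHM must be >= 0 and voxel size positive")
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100 for a usable quantile")
    if not (0 < corrected_p < 1):
        raise ValueError(f"corrected_p must be in (0,1), got {corrected_p}")
    sigma_vox = fwhm / vox / _FWHM_TO_SIGMA
    z_crit = stats.norm.isf(voxel_p / 2.0)
    structure = _structure(connectivity)
    rng = np.random.default_rng(rng_seed)
    max_sizes = np.zeros(n_iter)
    for it in range(n_iter):
        vol = rng.standard_normal(mask.shape)
        if np.any(sigma_vox > 0):
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
        inside = vol[mask]
        vol = (vol - inside.mean()) / inside.std(ddof=0)
        supra_hi = mask & (vol > z_crit)
        supra_lo = mask & (vol < -z_crit)
        biggest = 0
        for supra in (supra_hi, supra_lo):
            labels, n = ndimage.label(supra, structure=structure)
            if n:
                biggest = max(biggest, int(np.bincount(labels.ravel())[1:].max()))
        max_sizes[it] = biggest
    return int(np.ceil(np.quantile(max_sizes, 1.0 - corrected_p)))
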