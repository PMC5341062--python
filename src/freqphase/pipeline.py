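"""Seed-based pipelines: seed-to-voxel weight maps and ROI-to-ROI tables.

The seed-to-voxel flow mirrors the method end to end: extract the seed's
mean series, temporally preprocess every voxel, cross-correlate seed
against voxel, fit the windowed cosine/sine GLM per voxel, stack the
subject weight maps, run a voxelwise one-sample t per weight and apply
cluster-extent correction.  Group-mean amplitude/phase/delay maps per
frequency and a connection-class label map are derived from the group
mean weights, and a machine-readable manifest of every parameter is
written alongside the volumes.

The ROI-to-ROI flow is the same mathematics on region-by-time matrices,
with Benjamini–Hochberg FDR across ordered region pairs in place of the
spatial cluster correction (off by default in significance labelling;
both raw and adjusted p-values are reported).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

try:  # nibabel is only needed for volumetric I/O
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

from . import __version__ as _pkg_version
from .preprocess import (DEFAULT_BAND, TimeSeries, _bandpass_cols,
                         _detrend_cols, preprocess)
from .crosscorr import cross_correlogram, cross_correlogram_many, make_lag_grid
from .fpa_glm import (DEFAULT_FREQS, BasisSet, build_basis, fit_fpa,
                      fit_fpa_many)
from .group_stats import GroupSPM, one_sample_t_map, threshold_spm

__all__ = [
    "SeedConfig",
    "SubjectWeightMaps",
    "extract_seed_series",
    "subject_connection_maps",
    "group_from_subject_maps",
    "run_group_analysis",
    "roi_to_roi",
    "score_recovery",
]

MISSING = np.nan  # sentinel for zero-variance voxels


@dataclass(frozen=True)
class SeedConfig:
    """All knobs of a seed analysis; every field has the conventional default.

    ``inputs`` are per-subject 4-D volumes (paths or nibabel images or
    arrays), ``seed_mask`` a binary 3-D volume (or a label image together
    with ``seed_label``), ``analysis_mask`` an optional inclusion mask
    (e.g. gray matter).  The lag grid spans ±``max_lag_seconds`` in steps
    of ``tr``; the basis holds one cosine and one sine per frequency.
    """

    inputs: tuple = ()
    tr: float = 2.0
    seed_mask: object = None
    seed_label: int | None = None
    analysis_mask: object = None
    freqs: tuple = DEFAULT_FREQS
    window_kind: str = "bartlett"
    max_lag_seconds: float = 40.0
    estimator: str = "linear"
    band: tuple = DEFAULT_BAND
    filter_kind: str = "ideal"
    detrend: bool = True
    voxel_p: float = 1e-4
    cluster_k: int = 100
    connectivity: int = 26
    output_dir: str | None = None
    rng_seed: int = 0

    def lag_grid(self) -> LagGrid:
        return make_lag_grid(self.tr, self.max_lag_seconds)

    def basis(self) -> BasisSet:
        return build_basis(self.freqs, self.lag_grid(), self.window_kind)

    def weight_names(self) -> list[str]:
        K = len(self.freqs)
        return [f"beta{k+1}" for k in range(K)] + [f"gamma{k+1}" for k in range(K)]


@dataclass(frozen=True)
class SubjectWeightMaps:
    """Per-subject fitted weight volumes: K betas, K gammas and the fit F."""

    betas: np.ndarray            # (*shape, K)
    gammas: np.ndarray           # (*shape, K)
    f_map: np.ndarray            # (*shape,)
    affine: np.ndarray
    subject_id: str
    mask: np.ndarray             # voxels actually fitted

    @property
    def shape(self) -> tuple:
        return self.f_map.shape


# ---------------------------------------------------------------------------
# input plumbing
# ---------------------------------------------------------------------------

def _as_volume(obj, name: str = "volume") -> tuple[np.ndarray, np.ndarray]:
    """Accept a path, nibabel image or ndarray; return (data, affine)."""
    if isinstance(obj, (str, Path)):
        if nib is None:  # pragma: no cover
            raise ImportError("nibabel is required to read NIfTI inputs")
        img = nib.load(str(obj))
        return np.asarray(img.get_fdata()), img.affine
    if nib is not None and isinstance(obj, nib.spatialimages.SpatialImage):
        return np.asarray(obj.get_fdata()), obj.affine
    arr = np.asarray(obj, dtype=float)
    return arr, np.eye(4)


def _as_mask(obj, label: int | None = None) -> np.ndarray:
    data, _ = _as_volume(obj, "mask")
    if label is not None:
        return np.round(data).astype(int) == label
    return data > 0.5


def _preprocess_columns(X: np.ndarray, cfg: SeedConfig
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Detrend, band-pass and standardize columns of (n, m); flag valid ones.

    Validity uses a floor relative to the raw column scale so that constant
    or trend-only voxels (whose residual is pure round-off) are flagged
    missing rather than standardized into numerical noise.
    """
    ref = X.std(axis=0, ddof=0)
    if cfg.detrend:
        X = _detrend_cols(X)
    X = _bandpass_cols(X, cfg.tr, *cfg.band)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    valid = sd > np.maximum(1e-12, 1e-8 * ref)
    out = np.zeros_like(X)
    out[:, valid] = X[:, valid] / sd[valid]
    return out, valid


# ---------------------------------------------------------------------------
# subject level
# ---------------------------------------------------------------------------

def extract_seed_series(img4d, seed_mask, cfg: SeedConfig) -> TimeSeries:
    """Mean in-mask series, passed through the full preprocessing chain."""
    data, _ = _as_volume(img4d)
    mask = _as_mask(seed_mask, cfg.seed_label)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"seed mask shape {mask.shape} does not match volume grid "
            f"{data.shape[:3]}")
    if not mask.any():
        raise ValueError("seed mask is empty")
    raw = data[mask].mean(axis=0)
    ts = TimeSeries(values=raw, tr=cfg.tr)
    return preprocess(ts, f_lo=cfg.band[0], f_hi=cfg.band[1],
                      detrend=cfg.detrend, filter_kind=cfg.filter_kind)


def subject_connection_maps(seed: TimeSeries, img4d, cfg: SeedConfig,
                            subject_id: str = "subject") -> SubjectWeightMaps:
    """Fit the windowed GLM of seed-vs-voxel correlograms at every voxel.

    Out-of-mask and zero-variance voxels carry NaN in all weight volumes
    (a missing-value sentinel, excluded from group statistics).
    """
    data, affine = _as_volume(img4d)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    shape, n = data.shape[:3], data.shape[3]
    if seed.n != n:
        raise ValueError(f"seed length {seed.n} != volume time points {n}")
    if cfg.analysis_mask is not None:
        amask = _as_mask(cfg.analysis_mask)
        if amask.shape != shape:
            raise ValueError("analysis mask does not match the volume grid")
    else:
        amask = np.ones(shape, dtype=bool)
    basis = cfg.basis()
    grid = basis.grid
    if grid.lags_samples[-1] >= n:
        raise ValueError(
            f"max lag {cfg.max_lag_seconds}s is not below the record length "
            f"{n * cfg.tr}s")
    X = data[amask].T.astype(float)              # (n, m)
    X, valid = _preprocess_columns(X, cfg)
    n_invalid = int((~valid).sum())
    CC = cross_correlogram_many(seed.values, X[:, valid], grid, cfg.estimator)
    betas, gammas, f_stat, _ = fit_fpa_many(CC, basis)
    K = basis.n_freqs
    out_b = np.full((*shape, K), MISSING)
    out_g = np.full((*shape, K), MISSING)
    out_f = np.full(shape, MISSING)
    idx = np.flatnonzero(amask.ravel())[valid]
    coords = np.unravel_index(idx, shape)
    out_b[coords] = betas
    out_g[coords] = gammas
    out_f[coords] = f_stat
    fitted_mask = np.zeros(shape, dtype=bool)
    fitted_mask[coords] = True
    if n_invalid:
        import logging
        logging.getLogger(__name__).info(
            "%s: %d zero-variance voxels set to missing", subject_id, n_invalid)
    return SubjectWeightMaps(betas=out_b, gammas=out_g, f_map=out_f,
                             affine=affine, subject_id=str(subject_id),
                             mask=fitted_mask)


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupResult:
    """Everything the group stage produces, in memory."""

    spms: Mapping[str, GroupSPM]
    cluster_tables: Mapping[str, pd.DataFrame]
    mean_betas: np.ndarray
    mean_gammas: np.ndarray
    amplitude: np.ndarray        # (*shape, K)
    phase_deg: np.ndarray
    delay_seconds: np.ndarray
    class_map: np.ndarray        # (*shape, K) int codes, see CLASS_CODES
    mask: np.ndarray
    affine: np.ndarray
    manifest: dict


CLASS_CODES = {"none": 0, "symmetric": 1, "antisymmetric": 2, "asymmetric": 3}


def group_from_subject_maps(maps: Sequence[SubjectWeightMaps],
                            cfg: SeedConfig) -> GroupResult:
    """One-sample t per weight, cluster correction, and derived phase maps."""
    if len(maps) < 2:
        raise ValueError(f"group stage needs >= 2 subjects, got {len(maps)}")
    shape = maps[0].shape
    bad = [m.subject_id for m in maps if m.shape != shape]
    if bad:
        raise ValueError(f"subject grids mismatch for: {bad}")
    affine = maps[0].affine
    K = maps[0].betas.shape[-1]
    names = cfg.weight_names()
    group_mask = np.logical_and.reduce([m.mask for m in maps])
    if not group_mask.any():
        raise ValueError("no voxel is valid across all subjects")
    stack_b = np.stack([m.betas for m in maps])      # (S, *shape, K)
    stack_g = np.stack([m.gammas for m in maps])
    spms: dict[str, GroupSPM] = {}
    tables: dict[str, pd.DataFrame] = {}
    df = len(maps) - 1
    for k in range(K):
        for name, stack in ((names[k], stack_b[..., k]),
                            (names[K + k], stack_g[..., k])):
            t, _ = one_sample_t_map(stack)
            spm, table = threshold_spm(
                t, df=df, voxel_p=cfg.voxel_p, cluster_k=cfg.cluster_k,
                connectivity=cfg.connectivity, mask=group_mask,
                weight_name=name, affine=affine)
            spms[name] = spm
            tables[name] = table
    mean_b = np.where(group_mask[..., None], stack_b.mean(axis=0), np.nan)
    mean_g = np.where(group_mask[..., None], stack_g.mean(axis=0), np.nan)
    amplitude = np.hypot(mean_b, mean_g)
    phase = np.degrees(np.arctan2(mean_g, mean_b))
    phase = np.where(amplitude >= 1e-12, phase, np.nan)
    freqs = np.asarray(cfg.freqs)
    delay = (phase / 360.0) / freqs
    class_map = np.zeros((*shape, K), dtype=int)
    for k in range(K):
        sig_b = spms[names[k]].cluster_labels > 0
        sig_g = spms[names[K + k]].cluster_labels > 0
        class_map[..., k] = (np.where(sig_b & sig_g, CLASS_CODES["asymmetric"], 0)
                             + np.where(sig_b & ~sig_g, CLASS_CODES["symmetric"], 0)
                             + np.where(~sig_b & sig_g,
                                        CLASS_CODES["antisymmetric"], 0))
    manifest = {
        "package": "freqphase",
        "version": _pkg_version,
        "n_subjects": len(maps),
        "subject_ids": [m.subject_id for m in maps],
        "config": _manifest_config(cfg),
        "class_codes": CLASS_CODES,
        "sign_convention": "positive phase: target lags seed",
    }
    return GroupResult(spms=spms, cluster_tables=tables, mean_betas=mean_b,
                       mean_gammas=mean_g, amplitude=amplitude, phase_deg=phase,
                       delay_seconds=delay, class_map=class_map,
                       mask=group_mask, affine=affine, manifest=manifest)


def _manifest_config(cfg: SeedConfig) -> dict:
    d = asdict(cfg)
    for key in ("inputs", "seed_mask", "analysis_mask"):
        v = d.get(key)
        if key == "inputs":
            d[key] = [str(x) if isinstance(x, (str, Path)) else "<in-memory>"
                      for x in (v or ())]
        else:
            d[key] = str(v) if isinstance(v, (str, Path)) else (
                None if v is None else "<in-memory>")
    return d


def run_group_analysis(cfg: SeedConfig, seed_name: str = "seed"):
    """Full seed-to-voxel run over all subjects; writes outputs if configured.

    Returns (GroupResult, list[SubjectWeightMaps]).
    """
    if len(cfg.inputs) < 2:
        raise ValueError(
            f"group analysis needs >= 2 subject volumes, got {len(cfg.inputs)}")
    if cfg.seed_mask is None:
        raise ValueError("a seed mask is required")
    maps = []
    for s, img in enumerate(cfg.inputs):
        seed_ts = extract_seed_series(img, cfg.seed_mask, cfg)
        maps.append(subject_connection_maps(seed_ts, img, cfg,
                                            subject_id=f"sub-{s:03d}"))
    result = group_from_subject_maps(maps, cfg)
    if cfg.output_dir is not None:
        write_outputs(result, maps, cfg, seed_name)
    return result, maps


def write_outputs(result: GroupResult, maps: Sequence[SubjectWeightMaps],
                  cfg: SeedConfig, seed_name: str = "seed") -> None:
    """Write NIfTI volumes, cluster CSVs and the run manifest."""
    if nib is None:  # pragma: no cover
        raise ImportError("nibabel is required to write NIfTI outputs")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = result.affine

    def save(arr, name):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff),
                 str(out / f"{seed_name}_{name}.nii.gz"))

    names = cfg.weight_names()
    K = len(cfg.freqs)
    for m in maps:
        for k in range(K):
            save(m.betas[..., k], f"{m.subject_id}_{names[k]}")
            save(m.gammas[..., k], f"{m.subject_id}_{names[K + k]}")
        save(m.f_map, f"{m.subject_id}_F")
    for name, spm in result.spms.items():
        save(spm.t_map, f"group_t_{name}")
        save(spm.p_map, f"group_p_{name}")
        save(spm.cluster_labels, f"group_clusters_{name}")
        result.cluster_tables[name].to_csv(
            out / f"{seed_name}_clusters_{name}.csv", index=False)
    for k, f in enumerate(cfg.freqs):
        tag = f"{f:g}Hz"
        save(result.amplitude[..., k], f"group_amplitude_{tag}")
        save(result.phase_deg[..., k], f"group_phase_{tag}")
        save(result.delay_seconds[..., k], f"group_delay_{tag}")
        save(result.class_map[..., k], f"group_class_{tag}")
    (out / f"{seed_name}_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# ROI-to-ROI matrix mode
# ---------------------------------------------------------------------------

def roi_to_roi(matrix_inputs: Sequence[pd.DataFrame], cfg: SeedConfig,
               fdr_alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordered-pair weight tables across subjects plus group t with BH-FDR.

    ``matrix_inputs`` holds one region-by-time table per subject (rows =
    time points, columns = named regions; the region set must agree across
    subjects).  Returns (per_subject, group) tables in long format.
    """
    from statsmodels.stats.multitest import multipletests

    if len(matrix_inputs) < 1:
        raise ValueError("at least one subject table is required")
    regions = list(matrix_inputs[0].columns)
    for s, df_in in enumerate(matrix_inputs):
        if list(df_in.columns) != regions:
            raise ValueError(
                f"subject {s} region names {list(df_in.columns)} differ from "
                f"subject 0 {regions}")
    basis = cfg.basis()
    grid = basis.grid
    names = cfg.weight_names()
    rows = []
    for s, df_in in enumerate(matrix_inputs):
        X = df_in.to_numpy(dtype=float)
        X, valid = _preprocess_columns(X, cfg)
        if not valid.all():
            bad = [r for r, ok in zip(regions, valid) if not ok]
            raise ValueError(f"zero-variance regions in subject {s}: {bad}")
        series = {r: TimeSeries(values=X[:, i], tr=cfg.tr)
                  for i, r in enumerate(regions)}
        for i in regions:
            for j in regions:
                if i == j:
                    continue
                cc = cross_correlogram(series[i], series[j], grid,
                                       cfg.estimator, source_pair=(i, j))
                w = fit_fpa(cc, basis)
                row = {"subject": s, "seed": i, "target": j,
                       "F": w.f_stat, "R2": w.r_squared}
                for k, name in enumerate(names):
                    row[name] = w.stacked[k]
                rows.append(row)
    per_subject = pd.DataFrame(rows)
    if len(matrix_inputs) < 2:
        return per_subject, pd.DataFrame()
    group_rows = []
    for (i, j), sub in per_subject.groupby(["seed", "target"], sort=True):
        for name in names:
            vals = sub[name].to_numpy()
            mean = vals.mean()
            sd = vals.std(ddof=1)
            n = vals.size
            if sd == 0:
                t, p = np.nan, np.nan
            else:
                from scipy import stats as _st
                t = mean / (sd / np.sqrt(n))
                p = 2.0 * _st.t.sf(abs(t), df=n - 1)
            group_rows.append({"seed": i, "target": j, "weight": name,
                               "mean": mean, "t": t, "p": p, "df": n - 1})
    group = pd.DataFrame(group_rows)
    ok = group["p"].notna()
    adj = np.full(len(group), np.nan)
    if ok.any():
        _, p_adj, _, _ = multipletests(group.loc[ok, "p"], alpha=fdr_alpha,
                                       method="fdr_bh")
        adj[ok.to_numpy()] = p_adj
    group["p_fdr"] = adj
    group["significant"] = group["p_fdr"] < fdr_alpha
    return per_subject, group


# ---------------------------------------------------------------------------
# scoring against planted truth
# ---------------------------------------------------------------------------

def score_recovery(spm: GroupSPM, truth_mask: np.ndarray) -> dict:
    """Sensitivity and false-positive clusters of one SPM vs a planted block.

    Sensitivity is the fraction of truth voxels inside surviving clusters;
    a false positive is any surviving cluster entirely outside the truth.
    """
    truth = np.asarray(truth_mask, dtype=bool)
    detected = spm.cluster_labels > 0
    sens = float((detected & truth).sum() / truth.sum()) if truth.any() else np.nan
    fp = 0
    for lab in range(1, spm.n_clusters + 1):
        comp = spm.cluster_labels == lab
        if not (comp & truth).any():
            fp += 1
    return {"sensitivity": sens, "false_positive_clusters": fp,
            "n_clusters": spm.n_clusters}
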