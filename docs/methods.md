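# Methods

This note documents the model, the numerical choices and the limits of
what the synthetic validation shows. It is the package's own account of
its science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted.

## Signal model and correlogram

A preprocessed, band-limited, zero-mean series is treated as a finite
Fourier sum, x(t) = Σ_k a_k cos(2π f_k t) + b_k sin(2π f_k t), with
frequencies inside the conventional resting-state band (0.01–0.1 Hz).
Under unit-variance normalization (Σ_k (a_k²+b_k²)/2 = 1) the lagged
cross-correlation of a pair,

    CC(l) = (1/n) Σ_t x(t) y(t+l),

satisfies CC(0) = Pearson's r *exactly* because standardization uses the
ddof-0 variance; this identity is enforced, not asymptotic. For two such
sums the circular correlogram has the closed form

    CC(l) = Σ_k ½[(a_k^i a_k^j + b_k^i b_k^j) cos(2π f_k l)
                 + (a_k^i b_k^j − b_k^i a_k^j) sin(2π f_k l)],

whose ½ factor is pinned by CC(0) = 1 for identical normalized signals.
The even term collects the in-phase (symmetric) coupling, the odd term the
quadrature (antisymmetric) coupling. This closed form is the package's
independent oracle: circular correlograms of synthesized DFT-bin-aligned
pairs match it to < 1e−8 at every lag (in practice ~1e−15).

### Estimators

Two correlogram estimators are provided. The default `linear` estimator
truncates the overlap and still divides by n (the biased estimator): its
values are attenuated by approximately (1 − |l|/n), which at the default
geometry (|l| ≤ 20 samples of n = 300) is at most ~7% and even in lag, so
it does not bias phases. The `circular` estimator wraps indices modulo n
and is exact for bin-aligned signals; it exists chiefly so oracle tests
are equalities rather than approximations. The choice is configurable;
nothing downstream depends on it structurally.

Lags are restricted to integer multiples of TR (no sub-sample
interpolation), giving the standard 41-point ±40 s grid at TR = 2 s.

## The windowed GLM

The correlogram is regressed without intercept on 2K tapered regressors,
cos(2π f_k l)·B(l) and sin(2π f_k l)·B(l), with l in seconds, K = 4
frequencies 0.02–0.08 Hz by default, and B the Bartlett window
B(l) = 1 − |l|/L_max (endpoint-zero; Hann and rectangular are options).
Choices that matter:

- **No intercept.** Correlograms of band-passed zero-mean signals have no
  DC term; the model is exactly the 2K weights. A DC offset in the input
  would inflate β estimates — callers feeding unfiltered data should be
  aware.
- **Parity is exact.** On the symmetric grid every cosine column is even
  and every sine column odd, so even input yields γ ≡ 0 and odd input
  β ≡ 0 at machine precision, for every window. This is the mechanism that
  makes the symmetric/antisymmetric typing well-defined.
- **Goodness of fit.** R² is the *uncentered* coefficient of determination
  (1 − SS_res/Σ CC²), the standard convention for intercept-free OLS, and
  F = (R²/p)/((1−R²)/(n_lags−p)) with dof (8, 33) on the default grid.
  Under white-noise input this F follows F(8, 33) exactly; the 10,000-
  replicate Monte-Carlo mean in the suite sits within 3 SE of its
  theoretical mean 33/31.
- **Conditioning.** The design is solved by pseudo-inverse; construction
  fails loudly if the condition number exceeds 1e8 (duplicate frequencies,
  or a lag range too short to separate them).

### Window gain

The regressors are tapered but a sinusoidal correlogram is not, so the fit
assigns a *unit* connection a weight larger than 1 by a deterministic,
per-frequency factor (≈1.6–1.7 with Bartlett on the default grid),
partially compensated by opposite-sign leakage into neighbouring
frequencies. `basis_gains()` computes these factors; calibrated amplitudes
(raw weight / gain) recover unit connections within 10%. Phases are almost
unaffected — the cosine and sine gains at one frequency differ by ~5% at
worst, bounding the noiseless phase error to ≈1.2° (well inside the 5°
validation band). Two consequences worth knowing:

- The lag-0 identity "r ≈ Σ β_k" holds when the basis *represents* the
  correlogram (good fit). For a noiseless non-decaying cosine correlogram
  under a Bartlett taper, Σβ overshoots r by ~20%; with the rectangular
  window the identity is tight. Real, noisy, band-limited correlograms
  decay with lag, which is precisely the regime the taper is designed for.
- A connection planted at a single frequency produces (consistent,
  small, opposite-sign) weights at neighbouring basis frequencies. In
  group maps with many subjects these leakage weights can reach
  significance *at the true location*; they are a property of the basis,
  not spatial false positives.

## Phase, delay, typing

Per frequency, φ_k = atan2(γ_k, β_k) in (−180°, 180°], amplitude
√(β_k²+γ_k²), delay (φ_k/360)/f_k seconds. Degenerate amplitudes
(< 1e−12) report NaN phase, flagged, rather than a fabricated 0°. The
four-quadrant arctangent reproduces all canonical conversions at 0.02 Hz:
90° → 12.5 s, 180° → 25 s, 34° → 4.7 s, 79° → 10.9 s. Positive phase
means the target lags the seed; swapping pair order negates phases and
delays and leaves amplitudes invariant. No cross-frequency pooled phase is
defined — amplitudes at different frequencies are not commensurable after
windowing, and any pooling rule would be arbitrary; phases are reported
per frequency only.

Typing per frequency from per-weight significance: β only → symmetric,
γ only → antisymmetric, both → asymmetric, neither → none.

## Group statistics

Each weight is tested across subjects with a two-sided one-sample t
(df = n−1; zero-sd stacks yield NaN, never ±inf). Cluster correction:
suprathreshold voxels (two-sided p < voxel_p inside the mask) are labelled
at configurable connectivity (6/18/26, default 26), positive and negative
t separately — they never merge — and components below the extent
threshold are dropped. The extent threshold is either fixed (the
conventional 100 voxels) or returned by `mc_cluster_threshold`, which
simulates Gaussian white-noise volumes smoothed to a user-supplied FWHM
(default 8 mm), re-standardized within the mask, thresholded at voxel_p,
and takes the ceiling of the (1−corrected_p) quantile of the per-iteration
maximum cluster size (AlphaSim-style). Smoothness is user-supplied rather
than estimated from residuals: residual-based FWHM estimation is a
substantial separate method and out of scope. In ROI-matrix mode the
spatial correction is replaced by Benjamini–Hochberg FDR across ordered
region pairs (reported alongside raw p; significance labelling at
α = 0.05).

## Synthetic data: what it emulates and what it does not

`synth_dataset` builds multi-subject 4-D volumes: a seed block whose
waveform has a random phase per subject, planted target blocks reproducing
it at a controlled phase offset, and independent white Gaussian noise per
voxel, band-passed to 0.01–0.1 Hz so background series resemble temporally
preprocessed data. Defaults mirror a standard resting-state acquisition:
300 time points, TR = 2 s, noise_sd = 1 against unit-variance signal
(SNR 1 per voxel), 20 subjects, 24×24×12 geometry with 6×6×6 blocks.
Generator frequencies must be DFT bins of the record so oracle tests are
exact.

Under these conditions the full pipeline (voxel p < 1e−4, extent k = 20
scaled to the small grid) recovers planted symmetric and antisymmetric
blocks in the correct weight's map with 100% voxel sensitivity, zero
clusters outside planted truth, and zero clusters in a matched null run;
SNR-1 phase recovery has a median error of ~3–4° (validation band 15°).
The end-to-end run excludes the seed block from the analysis mask — the
seed's self-connection is trivially significant and is not a detection.

What the generator does *not* emulate: hemodynamic-response convolution,
spatially correlated (smoothed) noise, physiological confounds, motion,
inter-subject anatomical variability, or amplitude heterogeneity within
blocks. Passing tests therefore demonstrate the correctness and
calibration of the estimator chain, not detection power on real fMRI,
where effective SNR and cluster geometry differ.

## Numerical and interface choices

- Preprocessing order is fixed: confound regression → linear detrend →
  band-pass → standardize. The band-pass is an ideal DFT mask (band edges
  inclusive), exactly idempotent and transparent to bin-aligned signals; a
  zero-phase Butterworth is available for users who prefer a smooth
  transition band.
- Voxels whose series are constant or trend-only are flagged missing
  (NaN sentinel) using a floor relative to the raw series scale, and are
  excluded from group statistics rather than standardized into round-off
  noise.
- All pipeline stages are deterministic given the configuration and seed;
  subject-level and group-level stages are separately re-runnable, and a
  JSON manifest (parameters, seeds, version, sign convention) accompanies
  every volumetric run.
- Problem sizes in the validation suite (24×24×12 grids, 100-replicate
  noise studies, 10,000-replicate null calibrations) were chosen as the
  smallest at which the targeted effects and calibration bands are
  unambiguous.

## Known limitations

- Phases are estimated from real-valued weights of a windowed fit, not a
  spectral estimator; off-bin coupling frequencies incur small bias
  (bounded by the window's leakage profile).
- The Monte-Carlo extent threshold assumes stationary Gaussian smoothness
  supplied by the user; it is a null-field reconstruction, not an
  estimate from the data at hand.
- Negative weights in non-neuronal tissue (CSF, white matter) are not
  detected or handled automatically; users should supply an analysis
  mask.
- No causality claims follow from phase signs; a positive delay is a
  statement about temporal offset under the stated convention, nothing
  more.
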