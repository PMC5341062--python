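import numpy as np
import pytest

import freqphase as fp
from freqphase.synth import Component, DatasetSpec, PlantedBlock, SyntheticSpec


class TestSynthesize:
    def test_unit_variance_cosine(self):
        coef = fp.FourierCoefficients(freqs=[0.02], a=[np.sqrt(2)], b=[0.0])
        ts = fp.synthesize(coef, 300, 2.0)
        assert ts.values.var(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert ts.values[0] == pytest.approx(np.sqrt(2))

    def test_sine_is_quarter_cycle_delayed_cosine(self):
        f = 0.02
        cos_ts = fp.synthesize(
            fp.FourierCoefficients(freqs=[f], a=[np.sqrt(2)], b=[0.0]), 300, 2.0)
        sin_ts = fp.synthesize(
            fp.FourierCoefficients(freqs=[f], a=[0.0], b=[np.sqrt(2)]), 300, 2.0)
        t = np.arange(300) * 2.0
        delayed = np.sqrt(2) * np.cos(2 * np.pi * f * (t - 12.5))  # quarter of 50 s
        assert np.max(np.abs(sin_ts.values - delayed)) < 1e-10
        assert sin_ts.values.var(ddof=0) == pytest.approx(1.0, abs=1e-10)
        assert cos_ts.values.var(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_dft_round_trip_recovers_coefficients(self, rng):
        n, tr = 300, 2.0
        freqs = np.array([0.02, 0.04, 0.08])
        a = rng.standard_normal(3)
        b = rng.standard_normal(3)
        coef = fp.FourierCoefficients(freqs=freqs, a=a, b=b, normalized=False)
        ts = fp.synthesize(coef, n, tr)
        spec = np.fft.rfft(ts.values)
        bins = np.round(freqs * n * tr).astype(int)
        a_hat = 2 * spec[bins].real / n
        b_hat = -2 * spec[bins].imag / n
        assert np.max(np.abs(a_hat - a)) < 1e-10
        assert np.max(np.abs(b_hat - b)) < 1e-10

    def test_off_bin_frequency_rejected(self):
        coef = fp.FourierCoefficients(freqs=[0.0213], a=[np.sqrt(2)], b=[0.0])
        with pytest.raises(ValueError, match="bin"):
            fp.synthesize(coef, 300, 2.0)


class TestAnalyticCC:
    def test_self_correlation_is_cosine(self, grid41):
        coef = fp.FourierCoefficients(freqs=[0.02], a=[np.sqrt(2)], b=[0.0])
        cc = fp.analytic_cc(coef, coef, grid41)
        assert np.allclose(cc.values, np.cos(2 * np.pi * 0.02 * grid41.lags_seconds))
        assert cc.values[grid41.zero_index] == pytest.approx(1.0)

    def test_cosine_vs_sine_is_pure_sine(self, grid41):
        ci = fp.FourierCoefficients(freqs=[0.02], a=[np.sqrt(2)], b=[0.0])
        cj = fp.FourierCoefficients(freqs=[0.02], a=[0.0], b=[np.sqrt(2)])
        cc = fp.analytic_cc(ci, cj, grid41)
        assert np.allclose(cc.values, np.sin(2 * np.pi * 0.02 * grid41.lags_seconds))
        assert cc.values[grid41.zero_index] == pytest.approx(0.0)

    def test_disjoint_frequency_content_uncorrelated(self, grid41):
        freqs = [0.02, 0.04]
        ci = fp.FourierCoefficients(freqs=freqs, a=[np.sqrt(2), 0.0], b=[0.0, 0.0])
        cj = fp.FourierCoefficients(freqs=freqs, a=[0.0, np.sqrt(2)], b=[0.0, 0.0])
        cc = fp.analytic_cc(ci, cj, grid41)
        assert np.max(np.abs(cc.values)) < 1e-12

    def test_mismatched_frequency_sets_rejected(self, grid41):
        ci = fp.FourierCoefficients(freqs=[0.02], a=[np.sqrt(2)], b=[0.0])
        cj = fp.FourierCoefficients(freqs=[0.04], a=[np.sqrt(2)], b=[0.0])
        with pytest.raises(ValueError, match="frequencies"):
            fp.analytic_cc(ci, cj, grid41)

    def test_equals_circular_correlogram_of_synthesized_pairs(self, grid41, rng):
        freqs = list(fp.DEFAULT_FREQS)
        for _ in range(5):
            amps = rng.uniform(0.2, 1.0, 4)
            ph_i = rng.uniform(0, 360, 4)
            ph_j = rng.uniform(0, 360, 4)
            ci = fp.FourierCoefficients.from_amp_phase(freqs, amps, ph_i)
            cj = fp.FourierCoefficients.from_amp_phase(freqs, amps, ph_j)
            x = fp.synthesize(ci, 300, 2.0)
            y = fp.synthesize(cj, 300, 2.0)
            cc = fp.cross_correlogram(fp.standardize(x), fp.standardize(y),
                                      grid41, "circular")
            oracle = fp.analytic_cc(ci, cj, grid41)
            assert np.max(np.abs(cc.values - oracle.values)) < 1e-8


class TestSynthPair:
    def test_in_phase_pair_is_perfectly_correlated(self, grid41):
        x, y = fp.synth_pair(SyntheticSpec(components=(Component(freq=0.02),)))
        r = np.corrcoef(x.values, y.values)[0, 1]
        assert abs(r - 1.0) < 1e-10

    def test_antiphase_pair_is_anticorrelated(self):
        spec = SyntheticSpec(components=(Component(freq=0.02, phase_j_deg=180.0),))
        x, y = fp.synth_pair(spec)
        assert abs(np.corrcoef(x.values, y.values)[0, 1] + 1.0) < 1e-10

    def test_quadrature_pair_full_pipeline_recovery(self, grid41, basis41):
        spec = SyntheticSpec(components=(Component(freq=0.02, phase_j_deg=90.0),))
        x, y = fp.synth_pair(spec)
        cc = fp.cross_correlogram(fp.standardize(x), fp.standardize(y),
                                  grid41, "circular")
        w = fp.fit_fpa(cc, basis41)
        ps = fp.phase_spectrum(w, basis41.freqs)
        assert abs(ps.phase_deg[0] - 90.0) < 5.0
        assert abs(fp.pearson_from_cc(cc)) < 0.05

    def test_noise_reproducible_from_seed(self):
        spec = SyntheticSpec(components=(Component(freq=0.02),), noise_sd=1.0,
                             rng_seed=7)
        x1, y1 = fp.synth_pair(spec)
        x2, y2 = fp.synth_pair(spec)
        assert np.array_equal(x1.values, x2.values)
        assert np.array_equal(y1.values, y2.values)


class TestParameterRecovery:
    def test_noiseless_phase_and_amplitude_all_freqs_all_phases(self, grid41,
                                                                basis41):
        gain_cos, gain_sin = fp.basis_gains(basis41)
        for k, f in enumerate(basis41.freqs):
            for dphase in range(0, 360, 30):
                spec = SyntheticSpec(
                    components=(Component(freq=f, phase_j_deg=float(dphase)),))
                x, y = fp.synth_pair(spec)
                cc = fp.cross_correlogram(fp.standardize(x), fp.standardize(y),
                                          grid41, "circular")
                w = fp.fit_fpa(cc, basis41)
                est = np.degrees(np.arctan2(w.gammas[k], w.betas[k]))
                err = (est - dphase + 180) % 360 - 180
                assert abs(err) < 5.0, (f, dphase, err)
                amp = np.hypot(w.betas[k] / gain_cos[k], w.gammas[k] / gain_sin[k])
                assert abs(amp - 1.0) < 0.1, (f, dphase, amp)


class TestSynthDataset:
    def small_spec(self, **kw):
        defaults = dict(shape=(10, 10, 6), n=120, tr=2.0, n_subjects=2,
                        seed_corner=(0, 0, 0), seed_size=(3, 3, 3),
                        blocks=(PlantedBlock(name="sym", corner=(6, 6, 2),
                                             size=(3, 3, 3), freq=0.025),),
                        noise_sd=1.0)
        defaults.update(kw)
        return DatasetSpec(**defaults)

    def test_shapes_and_truth_masks(self):
        ds = fp.synth_dataset(self.small_spec(), rng_seed=3)
        assert len(ds.subjects) == 2
        assert ds.subjects[0].shape == (10, 10, 6, 120)
        assert ds.truth_masks["seed"].sum() == 27
        assert ds.truth_masks["sym"].sum() == 27
        assert not (ds.truth_masks["seed"] & ds.truth_masks["sym"]).any()

    def test_deterministic_under_fixed_seed(self):
        spec = self.small_spec()
        ds1 = fp.synth_dataset(spec, rng_seed=5)
        ds2 = fp.synth_dataset(spec, rng_seed=5)
        assert np.array_equal(ds1.subjects[0], ds2.subjects[0])
        ds3 = fp.synth_dataset(spec, rng_seed=6)
        assert not np.array_equal(ds1.subjects[0], ds3.subjects[0])

    def test_overlapping_blocks_rejected(self):
        spec = self.small_spec(blocks=(
            PlantedBlock(name="bad", corner=(1, 1, 1), size=(3, 3, 3),
                         freq=0.025),))
        with pytest.raises(ValueError, match="overlap"):
            fp.synth_dataset(spec, rng_seed=0)

    def test_block_outside_geometry_rejected(self):
        spec = self.small_spec(blocks=(
            PlantedBlock(name="big", corner=(8, 8, 4), size=(5, 5, 5),
                         freq=0.025),))
        with pytest.raises(ValueError, match="fit"):
            fp.synth_dataset(spec, rng_seed=0)

    def test_planted_signal_visible_in_block_spectrum(self):
        ds = fp.synth_dataset(self.small_spec(noise_sd=0.2), rng_seed=9)
        vol = ds.subjects[0]
        series = vol[ds.truth_masks["sym"]].mean(axis=0)
        spec = np.abs(np.fft.rfft(series - series.mean()))
        freqs = np.fft.rfftfreq(120, 2.0)
        assert freqs[np.argmax(spec)] == pytest.approx(0.025)
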