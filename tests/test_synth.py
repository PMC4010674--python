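"""Synthetic datasets, Wishart sampling, spectral estimation, data features."""

import numpy as np
import pytest

import fielddcm as fd
from fielddcm.containers import EpochSeries
from fielddcm.synth import (
    DEFAULT_TRUE_SENSITIVITIES,
    default_ground_truth,
    SIMULATION_REFERENCE_DEVIATIONS,
)

from conftest import reduced_priors


class TestGenerateDataset:
    def test_shape_and_invariants(self, model7, design, small_grid):
        ds = fd.generate_dataset(None, model7, design, n_epochs=16, seed=1,
                                 grid=small_grid)
        assert ds.data.values.shape == (9, 24, 4, 4)
        v = ds.data.values
        assert np.allclose(v, np.conj(np.swapaxes(v, -1, -2)))
        assert np.linalg.eigvalsh(v).min() > -1e-12

    def test_seed_reproducibility(self, model7, design, small_grid):
        a = fd.generate_dataset(None, model7, design, n_epochs=8, seed=3,
                                grid=small_grid)
        b = fd.generate_dataset(None, model7, design, n_epochs=8, seed=3,
                                grid=small_grid)
        c = fd.generate_dataset(None, model7, design, n_epochs=8, seed=4,
                                grid=small_grid)
        assert np.array_equal(a.data.values, b.data.values)
        assert not np.array_equal(a.data.values, c.data.values)

    def test_large_epoch_convergence(self, model7, design):
        # law of large numbers: the sampled CSD approaches the analytic one
        grid = fd.SpectralGrid.default(freqs=np.linspace(30, 60, 4), n_modes=8)
        ds = fd.generate_dataset(None, model7, design, n_epochs=10_000, seed=5,
                                 grid=grid)
        rel = (np.linalg.norm(ds.data.values - ds.expected.values)
               / np.linalg.norm(ds.expected.values))
        assert rel < 3.0 / np.sqrt(10_000) * 4  # a few standard errors

    def test_requires_two_epochs(self, model7, design, small_grid):
        with pytest.raises(ValueError):
            fd.generate_dataset(None, model7, design, n_epochs=1, grid=small_grid)


class TestEstimateCSD:
    def test_white_noise_flat(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 200_000))
        est = fd.estimate_csd(x, fs_hz=1000.0, epoch_s=0.5, overlap=0.5)
        p = est.values[0, :, 0, 0].real
        # white noise of unit variance at 1 kHz: one-sided density 0.002
        assert np.median(p) == pytest.approx(0.002, rel=0.05)
        assert p.std() / p.mean() < 0.2

    def test_sinusoid_peak_at_nearest_bin(self):
        fs, f0 = 1000.0, 41.0
        t = np.arange(int(fs * 60)) / fs
        x = np.sin(2 * np.pi * f0 * t)[None, :]
        est = fd.estimate_csd(x, fs_hz=fs, epoch_s=0.5)
        i = np.argmax(est.values[0, :, 0, 0].real)
        assert abs(est.grid.freqs[i] - f0) <= 1.0  # 2 Hz resolution

    def test_identical_channels_unit_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30_000)
        est = fd.estimate_csd(np.stack([x, x]), fs_hz=1000.0)
        v = est.values[0]
        coh = np.abs(v[:, 0, 1]) ** 2 / (v[:, 0, 0].real * v[:, 1, 1].real)
        assert np.allclose(coh, 1.0)

    def test_delayed_copy_has_positive_phase(self):
        # y2(t) = y1(t - tau) with the model convention g_12 = Y1 Y2*
        # gives arg g_12 = +omega tau
        rng = np.random.default_rng(2)
        n, lag = 100_000, 5
        x = rng.standard_normal(n)
        y = np.roll(x, lag)
        est = fd.estimate_csd(np.stack([x, y]), fs_hz=1000.0)
        f = est.grid.freqs
        sel = (f > 20) & (f < 80)
        phase = np.angle(est.values[0, sel, 0, 1])
        expected = 2 * np.pi * f[sel] * lag / 1000.0
        assert np.allclose(phase, expected, atol=0.05)

    def test_epoched_input(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 500, 40))
        series = EpochSeries(data=data, fs_hz=1000.0)
        est = fd.estimate_csd(series)
        assert est.values.shape[1:] == (len(est.grid.freqs), 2, 2)

    def test_epoch_shorter_than_window_rejected(self):
        series = EpochSeries(data=np.zeros((2, 100, 4)), fs_hz=1000.0)
        with pytest.raises(ValueError):
            fd.estimate_csd(series, epoch_s=0.5)


class TestGammaPeak:
    def test_lorentzian_bump_detected(self):
        f = np.arange(2.0, 101.0, 2.0)
        p = 1.0 / (1.0 + ((f - 55.0) / 8.0) ** 2)
        assert fd.gamma_peak(f, p) == pytest.approx(55.0, abs=1.0)

    def test_monotone_spectrum_has_no_peak(self):
        f = np.arange(2.0, 101.0, 2.0)
        assert fd.gamma_peak(f, 1.0 / f) is None

    def test_empty_band_rejected(self):
        f = np.arange(2.0, 20.0, 2.0)
        with pytest.raises(ValueError):
            fd.gamma_peak(f, f * 0 + 1, band=(30, 80))

    def test_peak_nondecreasing_with_contrast(self, model7, design):
        # the generating model couples contrast to the superficial-pyramidal
        # loop (stronger coupling, reduced self-inhibition): the gamma peak
        # must not move downwards as contrast rises
        grid = fd.SpectralGrid.default(freqs=np.arange(2.0, 101.0, 1.0), n_modes=16)
        pr = reduced_priors(model7)
        truth = default_ground_truth(model7)
        assert truth["beta__alpha_44"] < 0  # gain disinhibition
        vals = fd.predict_conditions(truth, model7, design, pr, grid)
        peaks = [fd.gamma_peak(grid.freqs, vals[c, :, 0, 0].real)
                 for c in range(design.n_conditions)]
        assert all(p is not None for p in peaks)
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] > peaks[0]


class TestTransferMap:
    def test_symmetric_in_k(self, prior_mean_params, small_grid):
        syn, conn = prior_mean_params[:2]
        m = fd.transfer_map(4, small_grid, syn, conn)
        assert np.allclose(m, m[::-1])

    def test_equals_transfer_matrix_modulus(self, prior_mean_params, small_grid):
        syn, conn = prior_mean_params[:2]
        m = fd.transfer_map(2, small_grid, syn, conn)
        T = fd.transfer_matrix(small_grid.wavenumbers[:, None],
                               small_grid.omegas[None, :], syn, conn)
        assert np.allclose(m, np.abs(T[..., 1]) ** 2)

    def test_k0_peak_interior(self, prior_mean_params):
        syn, conn = prior_mean_params[:2]
        grid = fd.SpectralGrid.default(freqs=np.linspace(2, 150, 149), n_modes=4)
        m = fd.transfer_map(4, grid, syn, conn)
        col = m[np.argmin(np.abs(grid.wavenumbers))]
        i = int(np.argmax(col))
        assert 0 < i < len(col) - 1


class TestSimulator:
    def test_reference_configuration_is_stable(self, priors):
        syn, conn, _, _ = fd.simulation_reference_params(priors)
        assert fd.stability_screen(syn, conn, modes=(0, 1, 2, 4, 8, 16)) == 0

    def test_prior_means_fail_stability_screen(self, prior_mean_params):
        # the real-axis spectral predictions are finite at the prior means,
        # but the delayed dynamics are supercritical there
        syn, conn = prior_mean_params[:2]
        assert fd.stability_screen(syn, conn, modes=(0,)) > 0

    def test_divergence_reported(self, prior_mean_params):
        from fielddcm.simulate import FieldDivergenceError
        syn, conn = prior_mean_params[:2]
        with pytest.raises(FieldDivergenceError):
            fd.simulate_field(syn, conn, duration_s=1.0, dt_ms=0.25, seed=0)

    def test_zero_input_decays(self, priors):
        syn, conn, _, _ = fd.simulation_reference_params(priors)
        rec, _ = fd.simulate_field(syn, conn, duration_s=1.0, dt_ms=0.25,
                                   input_psd=1e-20, seed=0, burn_s=0.0)
        assert np.abs(rec[-100:]).max() <= np.abs(rec).max()
        assert np.abs(rec).max() < 1e-6

    def test_linearity_quadruples_power(self, priors):
        syn, conn, sensors, _ = fd.simulation_reference_params(priors)
        from fielddcm.simulate import electrode_series
        out = []
        for amp in (1.0, 4.0):
            rec, fs = fd.simulate_field(syn, conn, duration_s=4.0, dt_ms=0.25,
                                        input_psd=amp, seed=12)
            sites = electrode_series(rec, sensors, conn.patch_length)
            est = fd.estimate_csd(sites, fs_hz=fs, overlap=0.5)
            out.append(est.values[0])
        assert np.allclose(out[1], 4.0 * out[0], rtol=1e-7, atol=1e-12)

    def test_seed_determinism(self, priors):
        syn, conn, _, _ = fd.simulation_reference_params(priors)
        a, _ = fd.simulate_field(syn, conn, duration_s=0.5, dt_ms=0.25, seed=8)
        b, _ = fd.simulate_field(syn, conn, duration_s=0.5, dt_ms=0.25, seed=8)
        assert np.array_equal(a, b)

    def test_welch_csd_tracks_analytic_prediction(self, priors):
        # short-run agreement at the sampling-noise level; the full-length
        # oracle comparison lives in the acceptance suite
        syn, conn, sensors, _ = fd.simulation_reference_params(priors)
        from fielddcm.simulate import electrode_series
        rec, fs = fd.simulate_field(syn, conn, duration_s=32.0, dt_ms=0.25,
                                    input_psd=1.0, seed=13)
        sites = electrode_series(rec, sensors, conn.patch_length)
        est = fd.estimate_csd(sites, fs_hz=fs, overlap=0.5, fmax_hz=100)
        grid = fd.SpectralGrid.default(freqs=est.grid.freqs, n_modes=32)
        pred = fd.predict_csd(grid, sensors, fd.NoiseParams(alpha_u=1.0),
                              syn, conn)
        band = (grid.freqs >= 20) & (grid.freqs <= 90)
        g, h = pred.values[0][band], est.values[0][band]
        rel = np.linalg.norm(h - g) / np.linalg.norm(g)
        # expected sampling floor ~ sqrt(sum Gii Gjj / n_eff) / |G| ~ 0.17
        assert rel < 0.30
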