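"""Simulator: pool dynamics, spectrum rendering, EPSI grids, thermal reference."""

import numpy as np
import pytest

from hpgluc import synth
from hpgluc.spectra import PeakWindow, integrate_peak
from hpgluc.synth import (AcquisitionScheme, KineticModel, NoiseSpec,
                          Resonance, default_resonances, reference_phantom,
                          render_spectrum_series, render_thermal_spectrum,
                          simulate_epsi_dataset, simulate_pool_dynamics)

from conftest import pulsed_decay_closed_form, single_pool, single_pool_model


class TestPoolDynamics:
    @pytest.mark.parametrize("T1,theta", [(31.7, 10.0), (15.7, 13.0),
                                          (10.0, 3.4), (60.0, 15.3)])
    def test_single_pool_matches_closed_form(self, T1, theta):
        """Numerical propagation reproduces the analytic pulsed decay to 1e-6."""
        scheme = AcquisitionScheme(TR_s=3.0, n_timepoints=30)
        dyn = simulate_pool_dynamics(single_pool_model(), scheme,
                                     [single_pool(T1, theta)])
        expected = pulsed_decay_closed_form(1.0, theta, 3.0, T1, 30)
        rel = np.abs(dyn.amplitudes[:, 0] - expected) / expected
        assert rel.max() < 1e-6

    def test_no_conversion_means_no_product(self, cell_resonances):
        scheme = AcquisitionScheme(n_timepoints=50)
        model = KineticModel(k_pgls_per_s=0.0)
        dyn = simulate_pool_dynamics(model, scheme, cell_resonances)
        j = dyn.pool_names.index(synth.SIX_PG)
        assert np.all(dyn.amplitudes[:, j] == 0)

    def test_invivo_flip_angle_configuration(self, invivo_resonances):
        """The EPSI acquisition tips 3.4/12/15.3 degrees on delta/gamma/6PG."""
        by_name = {r.name: r.flip_angle_deg for r in invivo_resonances}
        assert by_name == {synth.DELTA_GL: 3.4, synth.GAMMA_GL: 12.0,
                           synth.SIX_PG: 15.3}

    def test_conservation_without_sinks(self):
        """With T1 -> inf, theta -> 0 and no bolus, exchange and conversion
        only redistribute magnetization: the pool total is constant."""
        res = [Resonance(synth.DELTA_GL, 173.8, 4, 1e12, 1e-7),
               Resonance(synth.GAMMA_GL, 177.0, 4, 1e12, 1e-7),
               Resonance(synth.SIX_PG, 178.6, 4, 1e12, 1e-7)]
        model = KineticModel(k_pgls_per_s=0.02, k_dg_per_s=0.01,
                             k_gd_per_s=0.02)
        scheme = AcquisitionScheme(n_timepoints=40)
        dyn = simulate_pool_dynamics(model, scheme, res)
        totals = dyn.Mz.sum(axis=1)
        assert np.abs(totals - totals[0]).max() < 1e-9

    def test_product_auc_nondecreasing_in_conversion_rate(self, cell_scheme,
                                                          cell_resonances):
        """Noiseless 6PG signal integral grows with the PGLS rate."""
        j = [r.name for r in cell_resonances].index(synth.SIX_PG)
        aucs = []
        for k in np.linspace(0.0, 0.05, 10):
            dyn = simulate_pool_dynamics(KineticModel(k_pgls_per_s=float(k)),
                                         cell_scheme, cell_resonances)
            aucs.append(np.trapezoid(dyn.amplitudes[:, j], dyn.times_s))
        assert np.all(np.diff(aucs) >= 0)

    def test_trajectories_nonnegative(self, cell_resonances):
        model = KineticModel(k_pgls_per_s=0.02, bolus_duration_s=15.0)
        scheme = AcquisitionScheme(n_timepoints=40)
        dyn = simulate_pool_dynamics(model, scheme, cell_resonances)
        assert np.all(dyn.Mz >= -1e-12)

    def test_no_magnetization_created_after_bolus(self):
        """Once the injection finishes the pool total can only decay."""
        res = [Resonance(synth.DELTA_GL, 173.8, 4, 1e12, 1e-7),
               Resonance(synth.GAMMA_GL, 177.0, 4, 1e12, 1e-7)]
        model = KineticModel(k_pgls_per_s=0.0, bolus_duration_s=15.0)
        scheme = AcquisitionScheme(TR_s=3.0, n_timepoints=30)
        dyn = simulate_pool_dynamics(model, scheme, res)
        totals = dyn.Mz.sum(axis=1)
        after = totals[dyn.times_s >= 15.0]
        assert np.all(np.diff(after) <= 1e-9)
        # and the full dose was delivered
        assert after[0] == pytest.approx(1.0, rel=1e-6)

    def test_unknown_pool_rejected(self):
        res = [Resonance("something_else", 170.0, 4, 20, 10)]
        with pytest.raises(synth.ConfigurationError):
            simulate_pool_dynamics(KineticModel(k_pgls_per_s=0.01),
                                   AcquisitionScheme(), res)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(k_pgls_per_s=-0.01)


class TestRenderSpectra:
    def test_zero_amplitudes_render_zero(self, cell_scheme, cell_resonances):
        series = render_spectrum_series(np.zeros((5, 3)), cell_scheme,
                                        cell_resonances)
        assert np.all(series.values == 0)

    def test_line_area_matches_amplitude(self, cell_scheme):
        """Integral of the rendered absorption line recovers the amplitude
        (within the Lorentzian tail truncation of a finite window)."""
        res = [single_pool(15.7, 13.0, shift_ppm=176.0)]
        series = render_spectrum_series(np.array([[2.5]]), cell_scheme, res)
        area = integrate_peak(series[0], PeakWindow("dGL", 176.0, 2.0))
        assert 0.97 * 2.5 <= area <= 2.5

    def test_seeded_noise_is_reproducible(self, cell_scheme, cell_resonances):
        amp = np.ones((4, 3))
        a = render_spectrum_series(amp, cell_scheme, cell_resonances,
                                   NoiseSpec(sigma=0.3, seed=7))
        b = render_spectrum_series(amp, cell_scheme, cell_resonances,
                                   NoiseSpec(sigma=0.3, seed=7))
        assert a.values.tobytes() == b.values.tobytes()

    def test_resonance_outside_axis_named_in_error(self, cell_scheme):
        res = [Resonance("far_line", 120.0, 4, 20, 10)]
        with pytest.raises(ValueError, match="far_line"):
            render_spectrum_series(np.ones((2, 1)), cell_scheme, res)


class TestEPSIDataset:
    def test_uniform_phantom_voxels_identical(self, epsi_scheme,
                                              invivo_resonances):
        ph = reference_phantom(k_tumor=0.005, k_background=0.005)
        ds = simulate_epsi_dataset(ph, KineticModel(bolus_duration_s=15.0),
                                   epsi_scheme, invivo_resonances)
        brain = ~ph.outside_mask
        ref = ds.values[:, 3, 3, :]
        rows, cols = np.where(brain)
        for r, c in zip(rows, cols):
            assert np.array_equal(ds.values[:, r, c, :], ref)

    def test_outside_voxels_are_signal_free(self, epsi_scheme,
                                            invivo_resonances):
        ph = reference_phantom()
        ds = simulate_epsi_dataset(ph, KineticModel(bolus_duration_s=15.0),
                                   epsi_scheme, invivo_resonances)
        assert np.all(ds.values[:, ph.outside_mask, :] == 0)

    def test_tumor_product_auc_exceeds_background_everywhere(
            self, epsi_scheme, invivo_resonances):
        """k = 0.02/s in tumor vs 0.005/s background: the noiseless 6PG
        signal integral is strictly larger in every tumor voxel."""
        ph = reference_phantom(k_tumor=0.02, k_background=0.005)
        ds = simulate_epsi_dataset(ph, KineticModel(bolus_duration_s=15.0),
                                   epsi_scheme, invivo_resonances)
        w = PeakWindow(synth.SIX_PG, 178.6, 0.5)
        mask = (ds.axis_ppm >= w.lo_ppm) & (ds.axis_ppm <= w.hi_ppm)
        auc = np.abs(ds.values[..., mask].real).sum(axis=(0, -1))
        background = (~ph.outside_mask) & (~ph.tumor_mask)
        assert auc[ph.tumor_mask].min() > auc[background].max()

    def test_grid_shape_is_native_acquisition_matrix(self, epsi_scheme,
                                                     invivo_resonances):
        ds = simulate_epsi_dataset(reference_phantom(), KineticModel(),
                                   epsi_scheme, invivo_resonances)
        assert ds.grid_shape == (8, 8)

    def test_seeded_epsi_reproducible(self, epsi_scheme, invivo_resonances):
        ph = reference_phantom()
        args = (ph, KineticModel(bolus_duration_s=15.0), epsi_scheme,
                invivo_resonances, NoiseSpec(sigma=0.01, seed=11))
        assert simulate_epsi_dataset(*args).values.tobytes() == \
            simulate_epsi_dataset(*args).values.tobytes()

    def test_phantom_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synth.Phantom(grid_shape=(8, 8), voxel_size_mm=(4.375, 4.375),
                          slice_thickness_mm=8.0,
                          k_map=np.zeros((4, 4)),
                          delivery_map=np.ones((8, 8)),
                          tumor_mask=np.zeros((8, 8), bool),
                          outside_mask=np.zeros((8, 8), bool))


class TestThermalReference:
    def test_zero_polarization_zero_spectrum(self, cell_scheme):
        res = single_pool(15.7, 90.0)
        spec = render_thermal_spectrum(1.0, cell_scheme, res, 0.0, NA=16)
        assert np.all(spec.values == 0)

    def test_amplitude_linear_in_averages(self, cell_scheme):
        res = single_pool(15.7, 90.0)
        a = render_thermal_spectrum(1.0, cell_scheme, res, 1e-5, NA=16)
        b = render_thermal_spectrum(1.0, cell_scheme, res, 1e-5, NA=32)
        assert np.allclose(b.values, 2 * a.values)
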