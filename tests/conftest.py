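import numpy as np
import pytest

from hpgluc import synth


@pytest.fixture
def cell_resonances():
    return synth.default_resonances("cell")


@pytest.fixture
def invivo_resonances():
    return synth.default_resonances("invivo")


@pytest.fixture
def cell_scheme():
    return synth.AcquisitionScheme(TR_s=3.0, n_timepoints=100,
                                   spectral_points=1024, B0_T=11.7)


@pytest.fixture
def epsi_scheme():
    return synth.AcquisitionScheme(TR_s=3.0, n_timepoints=20,
                                   spectral_points=128, B0_T=3.0,
                                   mode="epsi_grid")


def single_pool(T1_s: float, theta_deg: float, shift_ppm: float = 173.8,
                linewidth_hz: float = 4.0) -> synth.Resonance:
    return synth.Resonance(synth.DELTA_GL, shift_ppm, linewidth_hz, T1_s,
                           theta_deg)


def single_pool_model(M0: float = 1.0) -> synth.KineticModel:
    """No conversion, no exchange: the whole dose sits in the delta pool."""
    return synth.KineticModel(k_pgls_per_s=0.0, k_dg_per_s=0.0,
                              k_gd_per_s=0.0, delta_gamma_ratio0=1.0, M0=M0)


def pulsed_decay_closed_form(M0, theta_deg, TR_s, T1_s, n):
    """Sampled amplitude of an isolated pool under pulsed readout:
    M0 sin(theta) cos(theta)^i exp(-i TR / T1), i = 0..n-1."""
    th = np.deg2rad(theta_deg)
    i = np.arange(n)
    return M0 * np.sin(th) * np.cos(th) ** i * np.exp(-i * TR_s / T1_s)
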