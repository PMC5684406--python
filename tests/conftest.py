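import numpy as np
import pytest

from dimerdelay import FeedbackCoupling, solve_scalar, wavenumber_to_rate
from dimerdelay.model import _two_sided_spectral_density


@pytest.fixture(scope="session")
def fig_gamma0():
    """Bath coupling of the reference figures: 530 cm^-1 as an angular rate."""
    return wavenumber_to_rate(530.0)


@pytest.fixture(scope="session")
def fig_coupling(fig_gamma0):
    """Destructive-feedback regime: gamma0 = 530 cm^-1, tau = 50 fs, phi = pi."""
    return FeedbackCoupling(gamma0=fig_gamma0, tau=50.0, phi=np.pi)


@pytest.fixture(scope="session")
def fig_trajectories(fig_gamma0):
    """Scalar trajectories at tau = 50/100/150 fs in the phi = pi regime,
    on the 0-2000 fs window (shared across beating tests)."""
    out = {}
    for tau in (50.0, 100.0, 150.0):
        cp = FeedbackCoupling(gamma0=fig_gamma0, tau=tau, phi=np.pi)
        out[tau] = solve_scalar(cp, t_max=2000.0)
    return out


def fft_kernel_peak_weights(coupling, width=None, domega=0.005):
    """Independent FFT oracle for the spectral-density <-> kernel Fourier pair.

    Samples the two-sided formula extension of J(omega), applies a Gaussian
    regularizer exp(-omega^2 w^2 / 2) (equivalent to smearing the kernel
    deltas into Gaussians of width w), FFTs to the lag domain and integrates
    each peak over lag +- 6w.  Returns {lag: complex integrated weight}.
    """
    tau = coupling.tau
    w = tau / 40.0 if width is None else width
    om_max = 40.0 / w
    n = int(2 * om_max / domega)
    n += n % 2
    om = (np.arange(n) - n // 2) * domega
    j = _two_sided_spectral_density(om, coupling) * np.exp(-0.5 * (om * w) ** 2)
    g = domega * (-1.0) ** np.arange(n) * np.fft.fft(j)
    s = np.fft.fftfreq(n, d=domega / (2 * np.pi))
    order = np.argsort(s)
    s, g = s[order], g[order]
    out = {}
    for lag in (-tau, 0.0, tau):
        m = (s > lag - 6 * w) & (s < lag + 6 * w)
        out[lag] = np.trapezoid(g[m], s[m])
    return out
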