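import numpy as np
import pytest

from dimerdelay import (
    FeedbackCoupling,
    KernelWeights,
    SiteSystem,
    SpectralDensityCurve,
    build_kernel,
    kernel_weights,
    regularized_feedback_solution,
    solve_dimer_cross_delay,
    solve_scalar,
    solve_volterra,
)


def single_site(kernel):
    return SiteSystem(omegas=[0.0], delta=np.zeros((1, 1)), kernels={(0, 0): kernel})


class TestSiteSystem:
    def test_missing_kernel_pair_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            SiteSystem(omegas=[0.0, 0.0], delta=np.zeros((2, 2)), kernels={(0, 0): None})

    def test_non_hermitian_coupling_rejected(self):
        delta = np.array([[0.0, 1.0], [0.5, 0.0]], dtype=complex)
        kernels = {(j, l): None for j in range(2) for l in range(2)}
        with pytest.raises(ValueError, match="Hermitian"):
            SiteSystem(omegas=[0.0, 0.0], delta=delta, kernels=kernels)


class TestBuildKernel:
    def test_stationary_when_sites_resonant(self):
        cp = FeedbackCoupling(0.1, 5.0, 1.0)
        k = build_kernel(single_site(kernel_weights(cp, conjugated=True)), 0, 0, width=0.2)
        t = np.array([3.0, 8.0, 13.0])
        # depends on t - t' only: shifting both arguments changes nothing
        np.testing.assert_allclose(k.evaluate(t, t - 1.7), k.evaluate(t + 5.0, t + 3.3))

    def test_phase_factor_structure(self):
        system = SiteSystem(
            omegas=[0.3, 0.7],
            delta=np.zeros((2, 2)),
            kernels={(j, l): KernelWeights(lags=(0.0,), weights=(0.4,)) for j in range(2) for l in range(2)},
        )
        k = build_kernel(system, 0, 1, width=0.5)
        t, tp = 4.0, 1.5
        expected = np.exp(1j * (0.3 * t - 0.7 * tp)) * k.stationary_part(t - tp)
        assert k.evaluate(t, tp) == pytest.approx(expected)

    def test_zero_width_delta_has_no_pointwise_values(self):
        cp = FeedbackCoupling(0.1, 5.0, 0.0)
        k = build_kernel(single_site(kernel_weights(cp)), 0, 0, width=0.0)
        assert k.is_analytic_delta
        with pytest.raises(ValueError, match="width"):
            k.stationary_part(0.0)

    def test_flat_tapered_curve_is_memoryless_delta(self):
        """A flat density with a Gaussian frequency taper transforms into a
        single Gaussian-regularized delta 2*gamma*g_w(s)."""
        gam, w = 0.2, 0.5
        om = np.linspace(-12.0 / w, 12.0 / w, 4001)
        curve = SpectralDensityCurve(om, (gam / np.pi) * np.exp(-0.5 * (om * w) ** 2))
        k = build_kernel(single_site(curve), 0, 0)
        s = np.linspace(0.0, 5.0, 200)
        expected = 2 * gam * np.exp(-0.5 * (s / w) ** 2) / (w * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(k.stationary_part(s).real, expected, atol=1e-8)
        np.testing.assert_allclose(k.stationary_part(s).imag, 0.0, atol=1e-8)
        # half of the delta mass lies at s >= 0
        assert np.trapezoid(k.stationary_part(s).real, s) == pytest.approx(gam, rel=1e-6)

    def test_feedback_curve_recovers_kernel_peaks(self):
        """Quadrature transform of the two-sided feedback density shows three
        peaks at lags {-tau, 0, tau} with weights matching kernel_weights
        to <= 1%."""
        cp = FeedbackCoupling(0.0998, 10.0, 0.9)
        w = cp.tau / 20.0
        om = np.linspace(-10.0 / w, 10.0 / w, 400001)
        # two-sided formula extension of the feedback density, tapered so the
        # kernel deltas come out as Gaussians of width w
        jv = cp.gamma0 / np.pi * (1 + np.cos(om * cp.tau + cp.phi))
        jv = np.clip(jv, 0.0, None) * np.exp(-0.5 * (om * w) ** 2)
        curve = SpectralDensityCurve(om, jv)
        k = build_kernel(single_site(curve), 0, 0)
        kw = kernel_weights(cp)
        for lag in (-cp.tau, 0.0, cp.tau):
            s = np.linspace(lag - 6 * w, lag + 6 * w, 241)
            got = np.trapezoid(k.stationary_part(s), s)
            expected = kw.weight_at(lag)
            assert abs(got - expected) <= 0.01 * abs(expected)


class TestSolveVolterra:
    def test_zero_kernel_constant_amplitude(self):
        system = single_site(None)
        tr = solve_volterra(system, [1.0], t_max=10.0, dt=0.1)
        np.testing.assert_allclose(tr.component(), 1.0, atol=1e-12)

    def test_analytic_delta_path_matches_dde(self):
        cp = FeedbackCoupling(0.1, 10.0, 2.0)
        system = SiteSystem.single_site_feedback(cp)
        tr_v = solve_volterra(system, [1.0], t_max=50.0, dt=0.05)
        tr_d = solve_scalar(cp, t_max=50.0, dt=0.05, tol=None)
        np.testing.assert_allclose(tr_v.component(), tr_d.component(), atol=1e-10)

    def test_analytic_delta_path_dimer(self):
        cp = FeedbackCoupling(0.1, 10.0, 1.0)
        # cross-kernel delayed weight in the equation-of-motion convention
        w = cp.gamma0 * np.exp(-1j * cp.phi)
        kernels = {
            (0, 0): KernelWeights(lags=(0.0,), weights=(2 * cp.gamma0,)),
            (1, 1): KernelWeights(lags=(0.0,), weights=(2 * cp.gamma0,)),
            (0, 1): KernelWeights(lags=(cp.tau,), weights=(w,)),
            (1, 0): KernelWeights(lags=(cp.tau,), weights=(w,)),
        }
        system = SiteSystem(omegas=[0.0, 0.0], delta=np.zeros((2, 2)), kernels=kernels)
        tr_v = solve_volterra(system, [1.0, 0.0], t_max=60.0, dt=0.05)
        tr_d = solve_dimer_cross_delay(cp, [1.0, 0.0], t_max=60.0, dt=0.05, tol=None)
        np.testing.assert_allclose(tr_v.amplitudes, tr_d.amplitudes, atol=1e-10)

    def test_flat_bath_markovian_decay(self):
        """Memoryless (delta) bath: |c(t)| follows the Markovian e^{-gamma t}
        to <= 1e-4 through the regularized quadrature path."""
        gam, w = 0.2, 4e-4
        system = single_site(KernelWeights(lags=(0.0,), weights=(2 * gam,)))
        tr = solve_volterra(system, [1.0], t_max=6.0, dt=w / 10, width=w)
        err = np.max(np.abs(tr.magnitude() - np.exp(-gam * tr.times)))
        assert err <= 1e-4

    def test_underresolved_kernel_refused(self):
        cp = FeedbackCoupling(0.1, 10.0, 0.0)
        system = SiteSystem.single_site_feedback(cp)
        with pytest.raises(ValueError, match="under-resolved"):
            solve_volterra(system, [1.0], t_max=20.0, dt=0.2, width=0.5)

    def test_second_order_in_dt(self):
        gam, w = 0.2, 0.05
        system = single_site(KernelWeights(lags=(0.0,), weights=(2 * gam,)))
        t_out = np.linspace(0, 4, 81)
        sols = [
            solve_volterra(system, [1.0], t_max=4.0, dt=w / n, width=w).at(t_out)[:, 0]
            for n in (10, 20, 40)
        ]
        d1 = np.max(np.abs(sols[0] - sols[1]))
        d2 = np.max(np.abs(sols[1] - sols[2]))
        assert d1 / d2 >= 3.5  # nominal trapezoid/Heun ratio is 4

    def test_symmetric_modes_do_not_mix(self):
        """Two identical sites sharing the feedback kernel structure keep the
        symmetric/antisymmetric decomposition intact."""
        cp = FeedbackCoupling(0.1, 5.0, 1.2)
        wd = cp.gamma0 * np.exp(-1j * cp.phi)
        kernels = {
            (0, 0): KernelWeights(lags=(0.0,), weights=(2 * cp.gamma0,)),
            (1, 1): KernelWeights(lags=(0.0,), weights=(2 * cp.gamma0,)),
            (0, 1): KernelWeights(lags=(cp.tau,), weights=(wd,)),
            (1, 0): KernelWeights(lags=(cp.tau,), weights=(wd,)),
        }
        system = SiteSystem(omegas=[0.0, 0.0], delta=np.zeros((2, 2)), kernels=kernels)
        w = cp.tau / 32
        sym = solve_volterra(system, np.array([1.0, 1.0]) / np.sqrt(2), t_max=20.0,
                             dt=w / 10, width=w)
        np.testing.assert_allclose(sym.component(0), sym.component(1), atol=1e-12)
        anti = solve_volterra(system, np.array([1.0, -1.0]) / np.sqrt(2), t_max=20.0,
                              dt=w / 10, width=w)
        np.testing.assert_allclose(anti.component(0), -anti.component(1), atol=1e-12)


class TestRegularizationExtrapolation:
    def test_width_halving_at_least_halves_error(self):
        cp = FeedbackCoupling(0.1, 10.0, 2.0)
        _, _, sols = regularized_feedback_solution(cp, 3 * cp.tau, base_width=cp.tau / 64)
        t_out = np.linspace(0, 3 * cp.tau, 400)
        ref = solve_scalar(cp, t_max=3 * cp.tau, dt=cp.tau / 400, tol=1e-11).at(t_out)[:, 0]
        errs = [np.max(np.abs(s - ref)) for s in sols]
        assert errs[1] <= 0.6 * errs[0]
        assert errs[2] <= 0.6 * errs[1]

    def test_extrapolated_solution_matches_dde(self):
        """Width-extrapolated Volterra solution of the regularized feedback
        kernel agrees with the delay equation to <= 1e-4 on [0, 5 tau]."""
        cp = FeedbackCoupling(0.1, 10.0, 2.0)
        t_out, c_ext, _ = regularized_feedback_solution(
            cp, 5 * cp.tau, base_width=cp.tau / 256
        )
        ref = solve_scalar(cp, t_max=5 * cp.tau, dt=cp.tau / 400, tol=1e-11).at(t_out)[:, 0]
        assert np.max(np.abs(c_ext - ref)) <= 1e-4
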