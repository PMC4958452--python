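import numpy as np
import pytest

import stenosim as st
from stenosim.errors import ConfigurationError, OutOfLumenError
from stenosim.geometry import radius_at, radius_x_derivative
from stenosim.hemodynamics import (
    J32,
    characteristic_root,
    harmonic_velocity,
    inlet_conditions,
    solve_harmonic_pressure,
    solve_steady_pressure,
    steady_velocity,
)

OMEGA0 = 3.0 * np.pi
TP = 2.0 / 3.0


# ---------------------------------------------------------------------------
# Fourier drive
# ---------------------------------------------------------------------------


class TestFourier:
    def test_constant_signal(self):
        wf = st.fourier_decompose(np.full(64, 3.7), 14, tp=TP)
        assert wf.harmonics[0] == pytest.approx(3.7)
        assert np.allclose(wf.harmonics[1:], 0.0, atol=1e-12)

    def test_pure_cosine_lands_in_first_harmonic(self):
        t = np.linspace(0, TP, 64, endpoint=False)
        wf = st.fourier_decompose(np.cos(OMEGA0 * t), 14, tp=TP)
        assert wf.harmonics[1] == pytest.approx(1.0 + 0j, abs=1e-12)
        assert abs(wf.harmonics[2:]).max() < 1e-12

    def test_bandlimited_exact_recovery(self):
        rng = np.random.default_rng(7)
        c = rng.standard_normal(15) + 1j * rng.standard_normal(15)
        c[0] = c[0].real
        wf0 = st.InletWaveform(TP, c)
        t = np.linspace(0, TP, 128, endpoint=False)
        s = wf0.reconstruct(t)
        wf = st.fourier_decompose(s, 14, tp=TP)
        err = np.sqrt(np.mean((wf.reconstruct(t) - s) ** 2))
        assert err < 1e-10

    def test_too_few_samples_raises(self):
        with pytest.raises(ConfigurationError, match="29"):
            st.fourier_decompose(np.ones(20), 14, tp=TP)

    def test_duplicate_endpoint_dropped(self):
        t = np.linspace(0, TP, 65)  # inclusive endpoint duplicates sample 0
        wf = st.fourier_decompose(np.cos(OMEGA0 * t), 8, tp=TP)
        assert wf.harmonics[1] == pytest.approx(1.0 + 0j, abs=1e-12)


class TestSynthWaveform:
    def test_zero_peak_is_flat(self):
        _, u = st.synth_cca_waveform(TP, peak=0.0)
        assert np.all(u == 0.0)

    def test_systolic_acceleration_phase(self):
        t, u = st.synth_cca_waveform(TP, peak=0.8, n_samples=2048)
        du = np.gradient(u, t)
        assert 0.22 <= t[np.argmax(du)] / TP <= 0.26

    def test_periodic_closure_and_peak(self):
        t, u = st.synth_cca_waveform(TP, peak=0.8)
        assert u[0] == pytest.approx(u[-1])
        assert u.max() == pytest.approx(0.8)

    def test_seed_jitter_reproducible(self):
        _, u1 = st.synth_cca_waveform(TP, 0.8, seed=5)
        _, u2 = st.synth_cca_waveform(TP, 0.8, seed=5)
        _, u3 = st.synth_cca_waveform(TP, 0.8, seed=6)
        assert np.array_equal(u1, u2)
        assert not np.array_equal(u1, u3)


# ---------------------------------------------------------------------------
# Steady solution
# ---------------------------------------------------------------------------


class TestSteady:
    def test_straight_tube_linear_pressure(self, straight_geom, fluid):
        x = np.linspace(*straight_geom.axial_extent, 101)
        p0, g, h = solve_steady_pressure(straight_geom, fluid, x, 0.2)
        assert np.allclose(g, g[0])
        assert np.allclose(h, 0.0)
        # p0 linear in x
        assert np.allclose(np.diff(p0, 2), 0.0, atol=1e-10 * abs(p0[-1]))

    def test_centerline_speed_hand_value(self, straight_geom, fluid):
        # dp0/dx = -100 Pa/m in a 4 mm tube at mu = 3.5e-3 -> 0.1143 m/s
        u0, _ = steady_velocity(fluid, 4e-3, 0.0, -100.0, 0.0, 0.0)
        assert u0 == pytest.approx(0.11428571, rel=1e-6)

    def test_lubrication_balance_residual(self, geom, fluid):
        x = np.linspace(*geom.axial_extent, 2001)
        p0, g, h = solve_steady_pressure(geom, fluid, x, 0.25, t_phase=0.1)
        R = np.asarray(radius_at(geom, x, 0.1))
        Rp = np.asarray(radius_x_derivative(geom, x, 0.1))
        resid = R / 4.0 * h + g * Rp
        scale = np.abs(g * Rp).max()
        assert np.abs(resid).max() < 1e-8 * max(scale, 1.0)

    def test_symmetric_gradient_magnitude(self, geom, fluid):
        x = np.linspace(-geom.x0, geom.x0, 201)
        _, g, _ = solve_steady_pressure(geom, fluid, x, 0.25)
        np.testing.assert_allclose(g, g[::-1], rtol=1e-9)


# ---------------------------------------------------------------------------
# Womersley harmonics
# ---------------------------------------------------------------------------


class TestHarmonicODE:
    def test_womersley_number(self, fluid):
        beta1 = st.womersley_beta(fluid, OMEGA0, 1)
        assert beta1 == pytest.approx(1681.5, rel=1e-3)
        assert beta1 * 4e-3 == pytest.approx(6.726, rel=1e-3)

    def test_zero_inlet_gives_zero_solution(self, straight_geom, wall, fluid):
        x = np.linspace(*straight_geom.axial_extent, 65)
        p, g, h = solve_harmonic_pressure(
            straight_geom, wall, fluid, 1, OMEGA0, x, 0.0, 0.0
        )
        assert np.all(p == 0) and np.all(g == 0)

    def test_straight_tube_matches_characteristic_solution(
        self, straight_geom, wall, fluid
    ):
        x = np.linspace(*straight_geom.axial_extent, 129)
        p_in, g_in = inlet_conditions(straight_geom, wall, fluid, 1, OMEGA0, 0.3)
        p, g, _ = solve_harmonic_pressure(
            straight_geom, wall, fluid, 1, OMEGA0, x, p_in, g_in
        )
        lam = characteristic_root(straight_geom, wall, fluid, 1, OMEGA0)
        # constant-coefficient exact solution from the same initial data
        xi = x - x[0]
        a = (p_in + g_in / lam) / 2.0
        b = (p_in - g_in / lam) / 2.0
        exact = a * np.exp(lam * xi) + b * np.exp(-lam * xi)
        np.testing.assert_allclose(p, exact, rtol=1e-6)

    def test_forward_root_travels_downstream(self, straight_geom, wall, fluid):
        lam = characteristic_root(straight_geom, wall, fluid, 1, OMEGA0)
        assert lam.imag < 0  # e^{j(wt + Im(lam) x)}: phase moves toward +x

    def test_overflow_guard_names_harmonic(self, straight_geom, wall):
        thick = st.FluidProperties(rho=1050.0, mu=1e-9)
        with pytest.raises(st.SimulationError, match="n=3"):
            x = np.linspace(*straight_geom.axial_extent, 17)
            solve_harmonic_pressure(straight_geom, wall, thick, 3, OMEGA0, x, 1.0, 0.0)


class TestVelocityField:
    def test_no_slip_and_axis_conditions(self, solution, geom, fluid):
        x = -20e-3
        R = radius_at(geom, x, solution.t_phase)
        u_wall, _ = st.velocity_from_harmonics(solution, geom, fluid, R, x, 0.21)
        u_axis, v_axis = st.velocity_from_harmonics(solution, geom, fluid, 0.0, x, 0.21)
        assert abs(u_wall) < 1e-8 * abs(u_axis)
        assert v_axis == 0.0

    def test_outside_lumen_rejected(self, solution, geom, fluid):
        with pytest.raises(OutOfLumenError):
            st.velocity_from_harmonics(solution, geom, fluid, 4.2e-3, -20e-3, 0.0)

    def test_steady_only_profile_is_parabolic(self, straight_geom, fluid, wall):
        wf = st.InletWaveform(TP, np.array([0.25 + 0j]))
        sol = st.solve_pulsatile(straight_geom, wall, fluid, wf)
        r = np.linspace(0, 4e-3, 33)
        u, v = st.velocity_from_harmonics(sol, straight_geom, fluid, r, 0.0, 0.0)
        np.testing.assert_allclose(u, 0.25 * (1 - (r / 4e-3) ** 2), rtol=1e-9)
        np.testing.assert_allclose(v, 0.0, atol=1e-15)

    def test_fd_oracle_momentum_equation(self, fluid):
        """Womersley profile vs a finite-difference momentum solve, < 1e-4."""
        R, n, dpdx = 4e-3, 2, -300.0 + 150.0j
        npts = 200
        r = np.linspace(0, R, npts)
        hh = r[1] - r[0]
        jw = 1j * n * OMEGA0 * fluid.rho
        A = np.zeros((npts, npts), complex)
        b = np.zeros(npts, complex)
        mu = fluid.mu
        A[0, 0] = -jw - 4 * mu / hh**2
        A[0, 1] = 4 * mu / hh**2
        b[0] = dpdx
        for i in range(1, npts - 1):
            A[i, i - 1] = mu * (1 / hh**2 - 1 / (2 * hh * r[i]))
            A[i, i] = -2 * mu / hh**2 - jw
            A[i, i + 1] = mu * (1 / hh**2 + 1 / (2 * hh * r[i]))
            b[i] = dpdx
        A[-1, -1] = 1.0
        u_fd = np.linalg.solve(A, b)
        u_an, _ = harmonic_velocity(fluid, n, OMEGA0, R, 0.0, 0.0, dpdx, 0.0, r)
        scale = np.abs(u_an).max()
        assert np.abs(u_fd - u_an).max() / scale < 1e-4

    def test_poiseuille_limit(self, fluid):
        """Scaling the fundamental down 1000x recovers the parabola within 1%."""
        R, dpdx = 4e-3, -200.0
        omega_small = OMEGA0 * 1e-3
        r = np.linspace(0, R, 101)
        u, _ = harmonic_velocity(fluid, 1, omega_small, R, 0.0, 0.0, dpdx, 0.0, r)
        parabola = -dpdx * (R**2 - r**2) / (4 * fluid.mu)
        assert np.abs(u.real - parabola).max() / parabola.max() < 0.01

    def test_mass_conservation_of_harmonic_pair(self, solution, geom, fluid):
        """(1/r) d(r v)/dr must cancel du/dx exactly (analytic identity)."""
        from scipy.special import jv

        n = 2
        i = np.argmin(np.abs(solution.x + 20e-3))
        x = solution.x[i]
        R = radius_at(geom, x, solution.t_phase)
        Rp = radius_x_derivative(geom, x, solution.t_phase)
        dp, d2 = solution.dpdx[n][i], solution.d2pdx2[n][i]
        lam = st.womersley_beta(fluid, OMEGA0, n) * J32
        jw = 1j * n * OMEGA0 * fluid.rho
        r = np.linspace(1e-5, 0.98 * R, 200)
        j0r, j0R = jv(0, lam * r), jv(0, lam * R)
        j1R = jv(1, lam * R)
        dudx = (d2 * (j0r / j0R - 1) + dp * lam * j1R * Rp * j0r / j0R**2) / jw
        div_rv = (d2 * (1 - j0r / j0R) - dp * Rp * lam * j1R * j0r / j0R**2) / jw
        np.testing.assert_allclose(dudx, -div_rv, rtol=1e-12)

    def test_wall_coupling_condition(self, solution, geom, wall, fluid):
        """v_n(R) equals j n omega0 xi_n within solver tolerance."""
        i = np.argmin(np.abs(solution.x + 30e-3))
        x = solution.x[i]
        R = radius_at(geom, x, solution.t_phase)
        Rp = radius_x_derivative(geom, x, solution.t_phase)
        for n in (1, 4, 9):
            _, v_n = harmonic_velocity(
                fluid, n, OMEGA0, R, Rp,
                solution.p[n][i], solution.dpdx[n][i], solution.d2pdx2[n][i], R,
            )
            xi_n = solution.p[n][i] * R**2 / (wall.B * geom.h)
            target = 1j * n * OMEGA0 * xi_n
            assert abs(v_n - target) < 1e-9 * abs(target) + 1e-18

    def test_conjugate_symmetric_sum_is_real(self, solution, geom, fluid):
        """Two-sided summation with c_{-n} = conj(c_n) has negligible imag part."""
        x, t = -25e-3, 0.3
        r = np.linspace(0, 0.9 * radius_at(geom, x, solution.t_phase), 17)
        total = np.zeros(r.shape, complex)
        i = np.argmin(np.abs(solution.x - x))
        R = radius_at(geom, solution.x[i], solution.t_phase)
        Rp = radius_x_derivative(geom, solution.x[i], solution.t_phase)
        for n in range(1, solution.p.shape[0]):
            u_n, _ = harmonic_velocity(
                fluid, n, OMEGA0, R, Rp,
                solution.p[n][i], solution.dpdx[n][i], solution.d2pdx2[n][i], r,
            )
            ph = np.exp(1j * OMEGA0 * n * t)
            total += 0.5 * (u_n * ph + np.conj(u_n * ph))
        assert np.abs(total.imag).max() < 1e-10 * max(np.abs(total.real).max(), 1e-30)
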