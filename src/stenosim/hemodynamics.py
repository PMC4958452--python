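"""Linearised pulsatile flow in the compliant stenosed tube.

The periodic flow is decomposed into a steady component plus ``N`` complex
harmonics at multiples of the fundamental ``omega0 = 2*pi/tp``.  For each
harmonic the axial momentum equation admits the classical Womersley solution
in terms of zero/first-order Bessel functions of the complex argument
``beta_n * j^{3/2} * r`` with ``beta_n = sqrt(rho n omega0 / mu)``; the radial
velocity follows from continuity.  Imposing no-slip, axis regularity and the
quasi-static elastic wall response couples the harmonics to a second-order
variable-coefficient ODE for the pressure harmonic p_n(x), integrated along
the axis by adaptive Runge-Kutta.  The steady component obeys the lubrication
balance (R/4) p0'' + p0' dR/dx = 0, i.e. dp0/dx proportional to R^-4.

Sign and branch conventions (fixed, documented):

* time convention ``exp(+j n omega0 t)``, physical fields are real parts;
* principal branch ``j^{3/2} = exp(j 3 pi / 4)``;
* the inlet (x_min) is driven by the centerline-velocity harmonics of the
  inlet waveform; the inlet pressure follows from the forward-travelling
  characteristic root of the straight-tube reduction of the pressure ODE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.special import jv

from .errors import ConfigurationError, OutOfLumenError, SimulationError
from .geometry import (
    FluidProperties,
    VesselGeometry,
    WallProperties,
    radius_at,
    radius_x_derivative,
)

J32 = np.exp(1j * 3.0 * np.pi / 4.0)  # principal branch of j^(3/2)

DEFAULT_N_HARMONICS = 14


# ---------------------------------------------------------------------------
# Inlet waveform
# ---------------------------------------------------------------------------


@dataclass
class InletWaveform:
    """Fourier representation of the inlet centerline-velocity waveform.

    ``harmonics[i]`` is the complex coefficient c_i; the physical signal is
    ``c_0 + sum_i Re[c_i exp(j omega0 i t)]``.  ``c_0`` is real.
    """

    tp: float
    harmonics: np.ndarray

    def __post_init__(self):
        if self.tp <= 0:
            raise ConfigurationError("cardiac period tp must be positive")
        self.harmonics = np.asarray(self.harmonics, dtype=complex)
        if abs(self.harmonics[0].imag) > 1e-9 * (abs(self.harmonics[0]) + 1e-30):
            raise ConfigurationError("c_0 must be real")
        self.harmonics[0] = self.harmonics[0].real

    @property
    def omega0(self) -> float:
        return 2.0 * np.pi / self.tp

    @property
    def N(self) -> int:
        return self.harmonics.size - 1

    def reconstruct(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, float(self.harmonics[0].real))
        for i in range(1, self.harmonics.size):
            out = out + np.real(self.harmonics[i] * np.exp(1j * self.omega0 * i * t))
        return out


def fourier_decompose(signal, n_harmonics: int = DEFAULT_N_HARMONICS, *, tp: float = 2.0 / 3.0) -> InletWaveform:
    """Least-squares Fourier coefficients of one uniformly sampled period.

    If the first and last samples coincide (periodic closure) the duplicate
    endpoint is dropped.  At least ``2*n_harmonics + 1`` distinct samples are
    required for the coefficients to be identifiable.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1:
        raise ConfigurationError("signal must be one-dimensional")
    if s.size > 1 and np.isclose(s[0], s[-1], rtol=1e-9, atol=1e-12 * max(1.0, np.abs(s).max())):
        s = s[:-1]
    m = s.size
    need = 2 * n_harmonics + 1
    if m < need:
        raise ConfigurationError(
            f"need at least {need} samples for {n_harmonics} harmonics, got {m}"
        )
    spec = np.fft.rfft(s) / m
    c = np.zeros(n_harmonics + 1, dtype=complex)
    c[0] = spec[0].real
    k = min(n_harmonics, spec.size - 1)
    c[1 : k + 1] = 2.0 * spec[1 : k + 1]
    return InletWaveform(tp=tp, harmonics=c)


def synth_cca_waveform(tp: float, peak: float = 0.8, seed: int | None = None, n_samples: int = 256):
    """Parametric one-cycle carotid centerline-velocity waveform.

    A diastolic baseline plus a systolic Gaussian pulse (centre 0.30*tp,
    width 0.06*tp) and a dicrotic bump (0.55*tp); the steepest systolic rise
    therefore falls at t/tp ~ 0.24, inside the physiological systolic
    acceleration band 0.22-0.26.  Periodic by construction (wrapped
    Gaussians); the whole shape is scaled so its maximum equals ``peak``
    (m/s).  ``seed`` adds small reproducible amplitude jitter without moving
    the bump centres.

    Returns ``(times, velocity)`` with an inclusive endpoint so that the
    first and last samples are equal.
    """
    if tp <= 0:
        raise ConfigurationError("tp must be positive")
    a_dia, a_sys, a_dic = 0.22, 1.0, 0.25
    if seed is not None:
        rng = np.random.default_rng(seed)
        a_sys *= 1.0 + 0.03 * float(np.clip(rng.standard_normal(), -2, 2))
        a_dic *= 1.0 + 0.05 * float(np.clip(rng.standard_normal(), -2, 2))
        a_dia *= 1.0 + 0.05 * float(np.clip(rng.standard_normal(), -2, 2))

    times = np.linspace(0.0, tp, n_samples)
    tau = times / tp

    def wrapped_gauss(center, width):
        out = np.zeros_like(tau)
        for k in (-1, 0, 1):
            out += np.exp(-0.5 * ((tau - center + k) / width) ** 2)
        return out

    shape = a_dia + a_sys * wrapped_gauss(0.30, 0.060) + a_dic * wrapped_gauss(0.55, 0.045)
    m = shape.max()
    u = peak * shape / m if m > 0 else np.zeros_like(shape)
    if peak == 0:
        u = np.zeros_like(shape)
    return times, u


# ---------------------------------------------------------------------------
# Womersley machinery
# ---------------------------------------------------------------------------


def womersley_beta(fluid: FluidProperties, omega0: float, n: int) -> float:
    """beta_n = sqrt(rho n omega0 / mu) (1/m)."""
    return float(np.sqrt(fluid.rho * n * omega0 / fluid.mu))


def _check_bessel_arg(lam: complex, R: float, n: int):
    if abs(lam) * R * np.sin(3.0 * np.pi / 4.0) > 690.0:
        raise SimulationError(
            f"Bessel argument overflow for harmonic n={n}: |beta_n R| too large"
        )


@dataclass
class HarmonicPressureSolution:
    """Pressure harmonics p_n(x) and gradients on an axial grid.

    Row ``n`` of ``p``/``dpdx``/``d2pdx2`` holds harmonic ``n`` (row 0 is the
    steady component and is real).  The geometry is frozen at the wall phase
    ``t_phase`` (quasi-static treatment of the slow wall oscillation).
    """

    x: np.ndarray
    p: np.ndarray
    dpdx: np.ndarray
    d2pdx2: np.ndarray
    beta: np.ndarray
    omega0: float
    t_phase: float
    geom: VesselGeometry = field(repr=False, default=None)
    wall: WallProperties = field(repr=False, default=None)
    fluid: FluidProperties = field(repr=False, default=None)

    @property
    def n_harmonics(self) -> int:
        return self.p.shape[0] - 1

    def _interp_row(self, arr_row: np.ndarray, x):
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.x, arr_row.real) + 1j * np.interp(
            x, self.x, arr_row.imag
        )

    def pressure_harmonics_at(self, x):
        """Complex p_n interpolated to positions ``x`` → array (N+1, ...)."""
        return np.stack([self._interp_row(self.p[n], x) for n in range(self.p.shape[0])])

    def pulsatile_pressure(self, x, t):
        """Real pulsatile pressure (harmonics n>=1 only) at (x, t)."""
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        ph = self.pressure_harmonics_at(x)
        out = np.zeros(np.broadcast(x, t).shape)
        for n in range(1, ph.shape[0]):
            out = out + np.real(ph[n] * np.exp(1j * self.omega0 * n * t))
        return out


def solve_steady_pressure(
    geom: VesselGeometry,
    fluid: FluidProperties,
    x_grid: np.ndarray,
    inlet_centerline_u: float,
    t_phase: float = 0.0,
):
    """Steady pressure p0 and gradient from the lubrication balance.

    Integrates ``(R/4) p0'' + p0' dR/dx = 0`` — equivalently ``dp0/dx
    proportional to R^-4`` (constant steady flux) — with the inlet gradient
    chosen so the steady centerline velocity ``-p0'(x_in) R_in^2 / (4 mu)``
    matches ``inlet_centerline_u``.  Returns ``(p0, dp0dx, d2p0dx2)``.
    """
    x = np.asarray(x_grid, dtype=float)
    R = radius_at(geom, x, t_phase)
    if np.any(R <= 0):
        raise SimulationError("singular geometry: lumen radius reached zero")
    Rp = radius_x_derivative(geom, x, t_phase)
    R_in = R[0]
    g_in = -4.0 * fluid.mu * inlet_centerline_u / R_in**2
    dp0dx = g_in * (R_in / R) ** 4
    p0 = cumulative_trapezoid(dp0dx, x, initial=0.0)
    d2p0dx2 = -4.0 * dp0dx * Rp / R
    return p0, dp0dx, d2p0dx2


def _ode_coefficients(geom, wall, fluid, n, omega0, t_phase):
    """Return callables A(x), C(x), D(x) of the pressure-harmonic ODE."""
    beta = womersley_beta(fluid, omega0, n)
    lam = beta * J32
    Bh = wall.B * geom.h
    w2 = (n * omega0) ** 2 * fluid.rho

    def coeffs(x):
        R = radius_at(geom, x, t_phase)
        Rp = radius_x_derivative(geom, x, t_phase)
        z = lam * R
        j0 = jv(0, z)
        j1 = jv(1, z)
        A = (R / 2.0 - j1 / (lam * j0)) / w2
        C = -(Rp * (j1 / j0) ** 2) / w2
        D = R**2 / Bh
        return A, C, D

    return coeffs, lam


def characteristic_root(geom, wall, fluid, n, omega0, t_phase=0.0, x=None):
    """Forward-travelling axial wavenumber of the straight-tube reduction.

    At a station with dR/dx = 0 the pressure ODE reduces to
    ``A p'' + D p = 0`` whose solutions are ``exp(+-lambda x)`` with
    ``lambda = sqrt(-D/A)``.  Under the ``exp(+j n omega0 t)`` convention the
    forward (downstream-travelling, non-growing) branch has negative
    imaginary part; ties favour negative real part (downstream decay).
    """
    if x is None:
        x = geom.axial_extent[0]
    coeffs, lam = _ode_coefficients(geom, wall, fluid, n, omega0, t_phase)
    _check_bessel_arg(lam, radius_at(geom, x, t_phase), n)
    A, _, D = coeffs(x)
    root = np.sqrt(-D / A + 0j)
    for cand in (root, -root):
        if cand.imag < -1e-12 * abs(cand):
            return cand
    return root if root.real < 0 else -root


def inlet_conditions(geom, wall, fluid, n, omega0, c_n, t_phase=0.0):
    """Inlet (p_n, dp_n/dx) reproducing centerline-velocity harmonic c_n.

    The gradient follows from the rigid straight-tube Womersley profile
    evaluated on the axis; the pressure level follows from the forward
    characteristic root (tube wave impedance), making the velocity waveform
    the single primary input.
    """
    x_in = geom.axial_extent[0]
    beta = womersley_beta(fluid, omega0, n)
    lam = beta * J32
    R_in = radius_at(geom, x_in, t_phase)
    _check_bessel_arg(lam, R_in, n)
    denom = 1.0 / jv(0, lam * R_in) - 1.0
    dpdx_in = 1j * n * omega0 * fluid.rho * c_n / denom
    lam_fwd = characteristic_root(geom, wall, fluid, n, omega0, t_phase, x=x_in)
    p_in = dpdx_in / lam_fwd
    return p_in, dpdx_in


def solve_harmonic_pressure(
    geom: VesselGeometry,
    wall: WallProperties,
    fluid: FluidProperties,
    n: int,
    omega0: float,
    x_grid: np.ndarray,
    inlet_p: complex,
    inlet_dpdx: complex,
    t_phase: float = 0.0,
    rtol: float = 1e-10,
):
    """Integrate the pressure-harmonic ODE by adaptive Runge-Kutta.

    The second-order complex ODE ``A(x) p'' + C(x) p' + D(x) p = 0`` (wall
    coupling through ``D = R^2/(B h)``) is reduced to a first-order system
    and marched from ``x_min`` with ``scipy.integrate.solve_ivp`` (RK45).
    Returns ``(p, dpdx, d2pdx2)`` on ``x_grid``; the curvature is recovered
    from the ODE itself so the wall coupling condition holds identically.
    """
    if n < 1:
        raise ConfigurationError("harmonic index n must be >= 1")
    x = np.asarray(x_grid, dtype=float)
    coeffs, lam = _ode_coefficients(geom, wall, fluid, n, omega0, t_phase)
    _check_bessel_arg(lam, float(np.max(radius_at(geom, x, t_phase))), n)

    def rhs(xv, y):
        A, C, D = coeffs(xv)
        return [y[1], -(C * y[1] + D * y[0]) / A]

    y0 = np.array([inlet_p, inlet_dpdx], dtype=complex)
    if inlet_p == 0 and inlet_dpdx == 0:
        z = np.zeros_like(x, dtype=complex)
        return z, z.copy(), z.copy()
    scale = max(abs(inlet_p), abs(inlet_dpdx), 1e-30)
    sol = solve_ivp(
        rhs,
        (x[0], x[-1]),
        y0,
        t_eval=x,
        method="RK45",
        rtol=rtol,
        atol=1e-12 * scale,
    )
    if not sol.success:
        raise SimulationError(f"pressure ODE integration failed for n={n}: {sol.message}")
    p, dpdx = sol.y[0], sol.y[1]
    A, C, D = coeffs(x)
    d2pdx2 = -(C * dpdx + D * p) / A
    return p, dpdx, d2pdx2


def _solve_harmonics_stacked(
    geom, wall, fluid, omega0, x, inlet_p, inlet_g, t_phase, rtol=1e-10
):
    """Integrate all harmonic pressure ODEs as one stacked complex system.

    Equivalent to calling :func:`solve_harmonic_pressure` per harmonic but
    evaluates the Bessel coefficients for every harmonic at once per RK
    step.  Returns ``(p, dpdx, d2pdx2)`` of shape (N, nx) for n = 1..N.
    """
    N = inlet_p.size
    n_idx = np.arange(1, N + 1)
    beta = np.sqrt(fluid.rho * n_idx * omega0 / fluid.mu)
    lam = beta * J32
    w2 = (n_idx * omega0) ** 2 * fluid.rho
    Bh = wall.B * geom.h
    _check_bessel_arg(lam[-1], float(np.max(radius_at(geom, x, t_phase))), N)

    def coeffs(xv):
        R = radius_at(geom, xv, t_phase)
        Rp = radius_x_derivative(geom, xv, t_phase)
        z = lam * R
        j0 = jv(0, z)
        j1 = jv(1, z)
        A = (R / 2.0 - j1 / (lam * j0)) / w2
        C = -(Rp * (j1 / j0) ** 2) / w2
        D = R**2 / Bh
        return A, C, D

    def rhs(xv, y):
        p, g = y[:N], y[N:]
        A, C, D = coeffs(xv)
        return np.concatenate([g, -(C * g + D * p) / A])

    y0 = np.concatenate([inlet_p, inlet_g]).astype(complex)
    scale = max(np.abs(y0).max(), 1e-30)
    sol = solve_ivp(rhs, (x[0], x[-1]), y0, t_eval=x, method="RK45",
                    rtol=rtol, atol=1e-12 * scale)
    if not sol.success:
        raise SimulationError(f"stacked pressure ODE failed: {sol.message}")
    p = sol.y[:N]
    g = sol.y[N:]
    # recompute coefficients on the full grid (vectorised over x)
    R = np.asarray(radius_at(geom, x, t_phase))
    Rp = np.asarray(radius_x_derivative(geom, x, t_phase))
    z = lam[:, None] * R[None, :]
    j0 = jv(0, z)
    j1 = jv(1, z)
    A = (R[None, :] / 2.0 - j1 / (lam[:, None] * j0)) / w2[:, None]
    C = -(Rp[None, :] * (j1 / j0) ** 2) / w2[:, None]
    D = (R**2 / Bh)[None, :]
    d2 = -(C * g + D * p) / A
    return p, g, d2


def solve_pulsatile(
    geom: VesselGeometry,
    wall: WallProperties,
    fluid: FluidProperties,
    waveform: InletWaveform,
    x_grid: np.ndarray | None = None,
    t_phase: float = 0.0,
    n_points: int = 257,
) -> HarmonicPressureSolution:
    """Solve steady + all harmonic pressure components for one wall phase."""
    if x_grid is None:
        x_grid = np.linspace(*geom.axial_extent, n_points)
    x = np.asarray(x_grid, dtype=float)
    N = waveform.N
    omega0 = waveform.omega0
    p = np.zeros((N + 1, x.size), dtype=complex)
    dpdx = np.zeros_like(p)
    d2 = np.zeros_like(p)
    p0, g0, h0 = solve_steady_pressure(
        geom, fluid, x, float(waveform.harmonics[0].real), t_phase
    )
    p[0], dpdx[0], d2[0] = p0, g0, h0
    beta = np.zeros(N + 1)
    if N >= 1:
        inlet_p = np.zeros(N, complex)
        inlet_g = np.zeros(N, complex)
        for n in range(1, N + 1):
            beta[n] = womersley_beta(fluid, omega0, n)
            inlet_p[n - 1], inlet_g[n - 1] = inlet_conditions(
                geom, wall, fluid, n, omega0, waveform.harmonics[n], t_phase
            )
        p[1:], dpdx[1:], d2[1:] = _solve_harmonics_stacked(
            geom, wall, fluid, omega0, x, inlet_p, inlet_g, t_phase
        )
    return HarmonicPressureSolution(
        x=x, p=p, dpdx=dpdx, d2pdx2=d2, beta=beta, omega0=omega0,
        t_phase=t_phase, geom=geom, wall=wall, fluid=fluid,
    )


# ---------------------------------------------------------------------------
# Velocity reconstruction
# ---------------------------------------------------------------------------


def steady_velocity(fluid, R, Rp, dp0dx, d2p0dx2, r):
    """Poiseuille-type steady components (u0, v0) at radius r.

    u0 = -(dp0/dx)(R^2 - r^2)/(4 mu); v0 follows from continuity and
    vanishes on both the axis and the wall when the steady pressure obeys
    the lubrication balance.
    """
    u0 = -dp0dx * (R**2 - r**2) / (4.0 * fluid.mu)
    v0 = (d2p0dx2 * (2.0 * R**2 * r - r**3) / 16.0 + dp0dx * R * Rp * r / 4.0) / fluid.mu
    return u0, v0


def harmonic_velocity(fluid, n, omega0, R, Rp, p_n, dpdx_n, d2pdx2_n, r):
    """Complex Womersley velocity harmonics (u_n, v_n) at radius r.

    u_n is the classical annular-Bessel profile; v_n is the continuity-
    consistent radial component (its second term carries the dR/dx geometry
    coupling).  Exact at the boundaries: u_n(R) = 0 and v_n(0) = 0.
    """
    beta = womersley_beta(fluid, omega0, n)
    lam = beta * J32
    jw = 1j * n * omega0 * fluid.rho
    j0R = jv(0, lam * R)
    j1R = jv(1, lam * R)
    j0r = jv(0, lam * r)
    j1r = jv(1, lam * r)
    u_n = dpdx_n / jw * (j0r / j0R - 1.0)
    v_n = (
        d2pdx2_n * (r / 2.0 - j1r / (lam * j0R))
        - dpdx_n * Rp * j1R * j1r / j0R**2
    ) / jw
    return u_n, v_n


def velocity_from_harmonics(
    sol: HarmonicPressureSolution,
    geom: VesselGeometry,
    fluid: FluidProperties,
    r,
    x,
    t,
    rtol_lumen: float = 1e-9,
):
    """Real axial/radial velocities (u, v) at points (r, x) and time t.

    Sums the steady component and the real parts of all harmonics under the
    ``exp(+j n omega0 t)`` convention.  Points with ``r > R(x)`` (geometry at
    the solution's wall phase) raise :class:`OutOfLumenError`.
    """
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    r, x = np.broadcast_arrays(r, x)
    R = np.asarray(radius_at(geom, x, sol.t_phase))
    if np.any(r > R * (1.0 + rtol_lumen)):
        raise OutOfLumenError("evaluation point outside the lumen (r > R)")
    if np.any(r < 0):
        raise OutOfLumenError("negative radial coordinate")
    Rp = np.asarray(radius_x_derivative(geom, x, sol.t_phase))

    def row(arr, n):
        return np.interp(x, sol.x, arr[n].real) + 1j * np.interp(x, sol.x, arr[n].imag)

    u0, v0 = steady_velocity(
        fluid, R, Rp, row(sol.dpdx, 0).real, row(sol.d2pdx2, 0).real, r
    )
    u = np.asarray(u0, dtype=float).copy()
    v = np.asarray(v0, dtype=float).copy()
    for n in range(1, sol.p.shape[0]):
        u_n, v_n = harmonic_velocity(
            fluid, n, sol.omega0, R, Rp,
            row(sol.p, n), row(sol.dpdx, n), row(sol.d2pdx2, n), r,
        )
        phase = np.exp(1j * sol.omega0 * n * t)
        u += np.real(u_n * phase)
        v += np.real(v_n * phase)
    return u, v
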