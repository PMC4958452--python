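"""Case orchestration: hemodynamics -> phantom -> RF -> images -> tracking.

The pipeline freezes the slow wall oscillation one frame at a time
(quasi-static re-solve of the pressure harmonics per frame), tabulates the
velocity field on a (normalised radius, axial position, time) grid for the
scatterer advection, and drives wall/tissue scatterers with the analytic
wall-surface trajectory W(s, t) = R(s, t) + xi(s, t).  The same W provides
the numerical reference against which ultrasound-derived wall displacement
is scored: the reference trace is the exact radial position of the
beam/lumen-surface intersection the M-mode line actually interrogates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import acoustics, imaging, phantom, tracking
from .config import RunConfig
from .geometry import radius_at, radius_x_derivative
from .hemodynamics import (
    HarmonicPressureSolution,
    harmonic_velocity,
    solve_pulsatile,
    steady_velocity,
)
from .tracking import DisplacementTrace, ErrorReport

log = logging.getLogger(__name__)


class WallMotionModel:
    """Per-frame pressure harmonics and the resulting wall-surface motion.

    Solves the pulsatile problem at ``n_frames`` wall phases across the
    requested time window and exposes the wall surface
    ``W(s, t) = R(s, t) + xi(s, t)`` with the compliance displacement
    ``xi = p R^2 (1 - sigma^2)/(E h)`` driven by the local pulsatile
    pressure (harmonics n >= 1; the steady pressure only offsets the mean).
    """

    def __init__(self, geom, wall, fluid, waveform, t_frames, n_axial=257):
        self.geom, self.wall, self.fluid, self.waveform = geom, wall, fluid, waveform
        self.t_frames = np.asarray(t_frames, dtype=float)
        self.x_grid = np.linspace(*geom.axial_extent, n_axial)
        self.solutions: list[HarmonicPressureSolution] = [
            solve_pulsatile(geom, wall, fluid, waveform, self.x_grid, t_phase=t)
            for t in self.t_frames
        ]
        N = waveform.N
        P = np.stack([sol.p for sol in self.solutions])  # (nf, N+1, nx)
        self._p_interp = []
        for n in range(N + 1):
            re = RegularGridInterpolator(
                (self.t_frames, self.x_grid), P[:, n, :].real,
                bounds_error=False, fill_value=None,
            )
            im = RegularGridInterpolator(
                (self.t_frames, self.x_grid), P[:, n, :].imag,
                bounds_error=False, fill_value=None,
            )
            self._p_interp.append((re, im))

    def pressure_harmonic(self, n, s, t):
        """Complex p_n at axial position(s) s and wall phase(s) t."""
        s = np.asarray(s, float)
        t = np.asarray(t, float)
        s, t = np.broadcast_arrays(s, t)
        tq = np.clip(t, self.t_frames[0], self.t_frames[-1])
        sq = np.clip(s, self.x_grid[0], self.x_grid[-1])
        pts = np.column_stack([tq.ravel(), sq.ravel()])
        re, im = self._p_interp[n]
        return (re(pts) + 1j * im(pts)).reshape(s.shape)

    def pulsatile_pressure(self, s, t):
        s = np.asarray(s, float)
        t = np.asarray(t, float)
        s, t = np.broadcast_arrays(s, t)
        omega0 = self.waveform.omega0
        out = np.zeros(s.shape)
        for n in range(1, self.waveform.N + 1):
            out += np.real(self.pressure_harmonic(n, s, t) * np.exp(1j * omega0 * n * t))
        return out

    def surface(self, s, t):
        """Wall lumen-surface radius W(s, t) = R(s, t) + xi(s, t) (m)."""
        s = np.asarray(s, float)
        t = np.asarray(t, float)
        s, t = np.broadcast_arrays(s, t)
        R = np.asarray(radius_at(self.geom, s, t))
        p = self.pulsatile_pressure(s, t)
        xi = p * R**2 * (1.0 - self.wall.sigma**2) / (self.wall.E * self.geom.h)
        return R + xi


def build_flow_interpolator(
    model: WallMotionModel,
    s_halfspan: float,
    n_eta: int = 33,
    n_x: int = 49,
) -> phantom.FlowInterpolator:
    """Tabulate (u, v) on a (eta, x, t) grid around the imaging corridor."""
    geom, fluid = model.geom, model.fluid
    eta = np.linspace(0.0, 1.0, n_eta)
    xs = np.linspace(-s_halfspan, s_halfspan, n_x)
    nt = model.t_frames.size
    u = np.zeros((n_eta, n_x, nt))
    v = np.zeros_like(u)
    omega0 = model.waveform.omega0
    for k, (tk, sol) in enumerate(zip(model.t_frames, model.solutions)):
        R = np.asarray(radius_at(geom, xs, tk))
        Rp = np.asarray(radius_x_derivative(geom, xs, tk))
        r = eta[:, None] * R[None, :]

        def row(arr, n):
            return np.interp(xs, sol.x, arr[n].real) + 1j * np.interp(
                xs, sol.x, arr[n].imag
            )

        u0, v0 = steady_velocity(
            fluid, R[None, :], Rp[None, :],
            row(sol.dpdx, 0).real[None, :], row(sol.d2pdx2, 0).real[None, :], r,
        )
        uk = np.array(u0, dtype=float)
        vk = np.array(v0, dtype=float)
        for n in range(1, model.waveform.N + 1):
            u_n, v_n = harmonic_velocity(
                fluid, n, omega0, R[None, :], Rp[None, :],
                row(sol.p, n)[None, :], row(sol.dpdx, n)[None, :],
                row(sol.d2pdx2, n)[None, :], r,
            )
            ph = np.exp(1j * omega0 * n * tk)
            uk += np.real(u_n * ph)
            vk += np.real(v_n * ph)
        u[:, :, k] = uk
        v[:, :, k] = vk
    # the wall surface carries cardiac harmonics well above the frame rate,
    # so its lookup table gets its own fine time grid
    t_fine = np.linspace(model.t_frames[0], model.t_frames[-1],
                         max(256, 8 * nt))
    W = model.surface(xs[:, None], t_fine[None, :])
    return phantom.FlowInterpolator(eta, xs, model.t_frames, u, v, geom,
                                    surface=W, surface_t_grid=t_fine)


# ---------------------------------------------------------------------------
# M-mode wall-tracking case
# ---------------------------------------------------------------------------


@dataclass
class MModeTrackingResult:
    times: np.ndarray
    est: DisplacementTrace
    ref: DisplacementTrace
    report: ErrorReport
    per_seed_positions: np.ndarray
    mmode_db: np.ndarray | None = None
    despeckled: np.ndarray | None = None
    depth_axis: np.ndarray | None = None


class MModeCase:
    """One (stenosis, wall-frequency) M-mode tracking case.

    The hemodynamic model, flow table, scan plan and reference trace are
    built once; :meth:`run_seed` then simulates one speckle realisation.
    """

    def __init__(self, config: RunConfig):
        config.validate()
        if config.mode != "mmode":
            raise ValueError("MModeCase requires mode='mmode'")
        self.config = config
        self.geom = config.make_geometry()
        self.wall = config.make_wall()
        self.fluid = config.make_fluid()
        self.waveform = config.make_waveform()
        self.tx = config.make_transducer()
        tp = config.waveform.tp
        # the acquisition is padded ~9% of a cycle at both ends so that the
        # temporal filters have no endpoint bias inside the scored cycle
        self.pad = 0.09 * tp
        duration = tp + 2.0 * self.pad
        nf = int(np.ceil(config.n_frames * duration / tp))
        t_frames = np.linspace(0.0, duration, nf)
        self.model = WallMotionModel(
            self.geom, self.wall, self.fluid, self.waveform, t_frames,
            n_axial=config.n_axial,
        )
        self.s_halfspan = 12e-3
        self.flow = build_flow_interpolator(self.model, self.s_halfspan)

        self.angle = config.phantom.angle_deg
        self.axis_depth = self.tx.focus
        th = np.deg2rad(self.angle)
        self._sin, self._cos = np.sin(th), np.cos(th)

        # scan plan over one padded cardiac cycle
        z_half = (self.geom.R0 + self.geom.h) / self._sin + 3e-3
        self.plan = acoustics.make_mmode_plan(
            self.tx, duration,
            depth_window=(self.axis_depth - z_half, self.axis_depth + 1e-3),
        )
        self.times = self.plan.emission_times()
        self.scored = (self.times >= self.pad) & (self.times < self.pad + tp)

        # wall-surface table on (s, emission-time) for scatterer driving
        self.s_grid = np.linspace(-self.s_halfspan, self.s_halfspan, 121)
        self.Wgrid = self.model.surface(
            self.s_grid[:, None], self.times[None, :]
        )

        self.ref = self._reference_trace()

    # -- reference --------------------------------------------------------
    def _reference_trace(self) -> DisplacementTrace:
        """Radial position of the near-wall beam/surface intersection.

        Along the M-line a point at distance d above the vessel axis has
        vessel coordinates (s, r) = (-d cos, d sin); the echo interface
        satisfies d sin(angle) = W(-d cos(angle), t), solved by fixed-point
        iteration (the contraction factor is |dW/ds| / tan(angle) << 1).
        """
        t = self.times
        d = np.full(t.shape, self.geom.R0 / self._sin)
        sign = -1.0 if self.config.tracking.side == "near" else 1.0
        for _ in range(12):
            W = self.model.surface(sign * d * self._cos, t)
            d = W / self._sin
        return DisplacementTrace(times=t, position=d * self._sin, source="numerical")

    # -- one speckle realisation ------------------------------------------
    def simulate_image(self, seed: int):
        """One M-mode envelope acquisition: returns ``(envelope, depth)``.

        The image is cropped in depth to the tracked-wall neighbourhood.
        """
        cfg = self.config
        cloud = phantom.init_cloud(
            self.geom, self.tx,
            density=cfg.phantom.density, angle_deg=self.angle, seed=seed,
            mode="mmode", axis_depth=self.axis_depth,
            blood_s_halfspan=self.s_halfspan,
        )
        blood = cloud.region == phantom.BLOOD
        dt = 1.0 / self.plan.prf
        state = {"k": 0}

        # blood advects (its slow-time correlation is physical); the wall and
        # tissue band is regenerated every emission from the current wall
        # state, mirroring the per-line phantom regeneration of the full
        # coupling scheme — successive M-mode columns carry independent
        # speckle, which the SRAD stage then averages down
        def provider(k):
            while state["k"] < k:
                phantom.advance_blood(cloud, self.flow, dt)
                phantom.refresh_amplitudes(cloud)
                state["k"] += 1
            pos_b = cloud.frame.vessel_to_beam(
                cloud.s[blood], cloud.r[blood], cloud.phi[blood]
            )
            wt_pos, wt_amp = phantom.draw_wall_tissue_snapshot(
                cloud, self.s_grid, self.Wgrid[:, 0], self.Wgrid[:, k],
                self.geom.h, cfg.phantom.R_range,
            )
            return (
                np.vstack([pos_b, wt_pos]),
                np.concatenate([cloud.amplitudes[blood], wt_amp]),
            )

        rf = acoustics.acquire(provider, self.tx, self.plan)
        iq = imaging.demodulate(rf, decimation=cfg.imaging.decimation)
        env = iq.envelope[:, 0, :]
        depth = iq.depth_axis

        ref_pos = self.ref.position
        w_lo, w_hi = ref_pos.min(), ref_pos.max()
        z_lo = self.axis_depth - (w_hi + 2.0e-3) / self._sin
        z_hi = self.axis_depth - (w_lo - 2.0e-3) / self._sin
        rows = (depth >= z_lo) & (depth <= z_hi)
        env_c = env[rows]
        depth_c = depth[rows]

        return env_c, depth_c

    def run_seed(self, seed: int, return_images: bool = False):
        """Track one speckle realisation; returns the extracted trace."""
        env_c, depth_c = self.simulate_image(seed)
        est, den = self._track(env_c**2, depth_c)
        if return_images:
            db = imaging._log_compress(env_c, self.config.imaging.dynamic_range)
            return est, db, den, depth_c
        return est

    def _srad_region(self, depth_c):
        """Homogeneous lumen reference rectangle (radii well inside)."""
        radii = (self.axis_depth - depth_c) * self._sin
        w_lo = self.ref.position.min()
        lum = np.nonzero((radii > w_lo - 1.9e-3) & (radii < w_lo - 0.9e-3))[0]
        return (int(lum.min()), int(lum.max()) + 1, None)

    def _track(self, intensity, depth_c):
        """SRAD + threshold tracking of one (possibly compounded) image."""
        cfg = self.config
        r0, r1, _ = self._srad_region(depth_c)
        region = (r0, r1, 0, intensity.shape[1])
        den = tracking.srad(
            intensity, n_iter=cfg.tracking.srad_iters,
            time_step=cfg.tracking.srad_dt, rect_homogeneous_region=region,
        )
        w_lo = self.ref.position.min()
        lumen_depth = self.axis_depth - (w_lo - 1.0e-3) / self._sin
        est = tracking.extract_wall(
            den, depth_c, self.times, lumen_depth,
            threshold_fraction=cfg.tracking.threshold, side=cfg.tracking.side,
            angle_deg=self.angle, axis_depth=self.axis_depth,
            method=cfg.tracking.method, threshold_mode=cfg.tracking.threshold_mode,
        )
        return est, den

    # -- multi-seed experiment --------------------------------------------
    def run(self, seeds, return_images: bool = False) -> MModeTrackingResult:
        """Compound the speckle realisations and score the tracked wall.

        The per-seed M-mode intensity images are ensemble-averaged (each
        emission carries independent speckle, so seeds multiply the look
        count), compounded over a short sliding time window (the wall moves
        by far less than a pixel within it), despeckled with SRAD, tracked
        by thresholding, and the tracked trace is smoothed with a low-order
        polynomial filter.  The resulting displacement is scored against
        the numerical reference, both taken about their own cycle mean.
        """
        from scipy.ndimage import uniform_filter1d
        from scipy.signal import savgol_filter

        I = None
        depth_c = None
        for seed in seeds:
            env_c, depth_c = self.simulate_image(seed)
            e2 = env_c**2
            I = e2 if I is None else I + e2
        I /= len(seeds)

        # sliding-window temporal compounding: ~45 ms of independent columns
        w = int(round(0.045 * self.plan.prf))
        if w > 1:
            I = uniform_filter1d(I, w, axis=1, mode="nearest")
        est, den = self._track(I, depth_c)
        pos = est.position
        # low-order polynomial smoothing of the trace (~70 ms window)
        sg = int(round(0.07 * self.plan.prf)) // 2 * 2 + 1
        if sg >= 5 and pos.size > sg:
            pos = savgol_filter(pos, sg, 2)
        # score the central (unpadded) cardiac cycle
        sc = self.scored
        avg = DisplacementTrace(self.times[sc], pos[sc], "ultrasound")
        ref_sc = DisplacementTrace(self.times[sc], self.ref.position[sc], "numerical")
        report = tracking.displacement_errors(avg.demeaned(), ref_sc.demeaned())
        db = imaging._log_compress(np.sqrt(I), self.config.imaging.dynamic_range)
        return MModeTrackingResult(
            times=self.times[sc], est=avg, ref=ref_sc, report=report,
            per_seed_positions=np.asarray(est.position)[None, :],
            mmode_db=db if return_images else None,
            despeckled=den if return_images else None,
            depth_axis=depth_c,
        )


def wall_tracking_experiment(
    stenosis_pct: float,
    wall_freq_factor: float,
    n_seeds: int = 10,
    base_seed: int = 1,
    prf: float = 768.0,
    n_frames: int = 48,
    return_images: bool = False,
) -> MModeTrackingResult:
    """Full M-mode + SRAD + threshold wall-displacement evaluation.

    Runs one cardiac cycle at the given stenosis degree (percent radius
    reduction) and wall oscillation frequency (multiple of the flow
    fundamental), averaging the extracted traces over ``n_seeds`` speckle
    realisations, and reports mean/max relative errors against the
    numerical reference.
    """
    cfg = RunConfig(mode="mmode", prf_override=prf, n_frames=n_frames)
    cfg.geometry.stenosis_pct = stenosis_pct
    cfg.geometry.wall_freq_factor = wall_freq_factor
    # half-wavelength depth pixels are ample for sub-pixel band tracking
    cfg.imaging.decimation = 8
    case = MModeCase(cfg)
    seeds = [(int(base_seed) * 7919 + 101 * i) % (2**31 - 1) for i in range(n_seeds)]
    return case.run(seeds, return_images=return_images)


# ---------------------------------------------------------------------------
# Color-flow case
# ---------------------------------------------------------------------------


@dataclass
class CFIResult:
    cfm: imaging.ColorFlowImage
    line_lats: np.ndarray
    peak_velocity: float
    t_center: float


def robust_peak_velocity(cfm: imaging.ColorFlowImage, q: float = 0.9) -> float:
    """Mean of the top (1-q) fraction of |v| over valid gates."""
    vals = np.abs(cfm.velocity[~cfm.low_power_mask])
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0.0
    thr = np.quantile(vals, q)
    return float(vals[vals >= thr].mean())


class CFICase:
    """Color-flow acquisition around one instant of the cardiac cycle."""

    def __init__(self, config: RunConfig):
        config.validate()
        if config.mode != "cfi":
            raise ValueError("CFICase requires mode='cfi'")
        self.config = config
        self.geom = config.make_geometry()
        self.wall = config.make_wall()
        self.fluid = config.make_fluid()
        self.waveform = config.make_waveform()
        self.tx = config.make_transducer()
        tp = config.waveform.tp
        self.t_center = config.imaging.t_center_frac * tp
        im = config.imaging
        self.duration = im.n_lines * im.ensemble / self.tx.prf
        t_frames = np.linspace(self.t_center, self.t_center + self.duration, 3)
        self.model = WallMotionModel(
            self.geom, self.wall, self.fluid, self.waveform, t_frames,
            n_axial=config.n_axial,
        )
        self.s_halfspan = 12e-3
        self.flow = build_flow_interpolator(self.model, self.s_halfspan)
        self.axis_depth = self.tx.focus
        th = np.deg2rad(config.phantom.angle_deg)
        z_half = self.geom.R0 / np.sin(th) + 1.5e-3
        self.plan = acoustics.make_cfi_plan(
            self.tx, im.n_lines, im.line_span, im.ensemble,
            depth_window=(self.axis_depth - z_half, self.axis_depth + z_half),
        )

    def run_seed(self, seed: int) -> CFIResult:
        cfg = self.config
        cloud = phantom.init_cloud(
            self.geom, self.tx,
            density=cfg.phantom.density, angle_deg=cfg.phantom.angle_deg,
            seed=seed, mode="cfi", axis_depth=self.axis_depth,
            lat_halfwidth=cfg.imaging.line_span / 2 + 1.5e-3,
            blood_s_halfspan=self.s_halfspan,
        )
        cloud.time = self.t_center
        dt = 1.0 / self.plan.prf
        state = {"k": 0}

        def provider(k):
            while state["k"] < k:
                phantom.advance_blood(cloud, self.flow, dt)
                state["k"] += 1
            return cloud

        rf = acoustics.acquire(provider, self.tx, self.plan)
        iq = imaging.demodulate(rf, decimation=cfg.imaging.decimation)
        if cfg.imaging.wall_filter:
            iq = imaging.polynomial_wall_filter(iq)
        cfm = imaging.kasai_velocity(iq)
        return CFIResult(
            cfm=cfm, line_lats=self.plan.line_lats,
            peak_velocity=robust_peak_velocity(cfm), t_center=self.t_center,
        )


def cfi_peak_velocity(
    stenosis_pct: float, wall_freq_factor: float, seed: int = 1, **cfg_kw
) -> float:
    """Robust peak color-flow velocity for one case (fixed seed)."""
    cfg = RunConfig(mode="cfi")
    cfg.geometry.stenosis_pct = stenosis_pct
    cfg.geometry.wall_freq_factor = wall_freq_factor
    for k, v in cfg_kw.items():
        setattr(cfg.imaging, k, v)
    case = CFICase(cfg)
    return case.run_seed(seed).peak_velocity


# ---------------------------------------------------------------------------
# B-mode case and top-level dispatch
# ---------------------------------------------------------------------------


class BModeCase:
    """Single-frame brightness sweep across the vessel."""

    def __init__(self, config: RunConfig, n_lines: int = 40, span: float = 10e-3):
        config.validate()
        self.config = config
        self.geom = config.make_geometry()
        self.wall = config.make_wall()
        self.fluid = config.make_fluid()
        self.waveform = config.make_waveform()
        self.tx = config.make_transducer()
        tp = config.waveform.tp
        self.t_center = config.imaging.t_center_frac * tp
        self.duration = n_lines / self.tx.prf
        t_frames = np.linspace(self.t_center, self.t_center + self.duration, 3)
        self.model = WallMotionModel(
            self.geom, self.wall, self.fluid, self.waveform, t_frames,
            n_axial=config.n_axial,
        )
        self.s_halfspan = 14e-3
        self.flow = build_flow_interpolator(self.model, self.s_halfspan)
        self.axis_depth = self.tx.focus
        th = np.deg2rad(config.phantom.angle_deg)
        z_half = (self.geom.R0 + self.geom.h) / np.sin(th) + 3e-3
        self.plan = acoustics.make_bmode_plan(
            self.tx, n_lines, span,
            depth_window=(self.axis_depth - z_half, self.axis_depth + z_half),
        )
        self.span = span

    def run_seed(self, seed: int) -> imaging.BModeImage:
        cfg = self.config
        cloud = phantom.init_cloud(
            self.geom, self.tx,
            density=cfg.phantom.density, angle_deg=cfg.phantom.angle_deg,
            seed=seed, mode="bmode", axis_depth=self.axis_depth,
            lat_halfwidth=self.span / 2 + 2e-3,
            blood_s_halfspan=self.s_halfspan,
        )
        cloud.time = self.t_center
        dt = 1.0 / self.plan.prf
        s_grid = np.linspace(-self.s_halfspan, self.s_halfspan, 121)
        times = self.t_center + self.plan.emission_times()
        Wg = self.model.surface(s_grid[:, None], times[None, :])
        wt = (cloud.region == phantom.WALL) | (cloud.region == phantom.TISSUE)
        s_wt = cloud.s[wt]
        state = {"k": 0, "W": np.interp(s_wt, s_grid, Wg[:, 0])}

        def provider(k):
            while state["k"] < k:
                kk = state["k"] + 1
                w_now = np.interp(s_wt, s_grid, Wg[:, kk])
                phantom.advance_wall_tissue(
                    cloud, w_now - state["W"], cfg.phantom.R_range,
                    origin=np.minimum(state["W"], cloud.r[wt]),
                )
                phantom.advance_blood(cloud, self.flow, dt)
                state["W"] = w_now
                state["k"] = kk
            return cloud

        rf = acoustics.acquire(provider, self.tx, self.plan)
        return imaging.form_bmode(
            rf, dynamic_range=cfg.imaging.dynamic_range,
            decimation=cfg.imaging.decimation,
        )


def run_case(config: RunConfig, mode: str | None = None, write: bool = True):
    """Run one configured case end to end; optionally write the bundle.

    Returns the mode-specific result object.  With ``write=True`` the
    results (arrays, config, seed, error report where applicable) go to an
    HDF5 container under ``config.outdir``.
    """
    if mode is not None:
        config.mode = mode
    config.validate()
    from . import io as sio

    if config.mode == "mmode":
        case = MModeCase(config)
        result = case.run([config.seed], return_images=True)
        if write:
            sio.write_mmode_bundle(config, result)
        return result
    if config.mode == "cfi":
        case = CFICase(config)
        result = case.run_seed(config.seed)
        if write:
            sio.write_cfi_bundle(config, result)
        return result
    case = BModeCase(config)
    result = case.run_seed(config.seed)
    if write:
        sio.write_bmode_bundle(config, result)
    return result
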