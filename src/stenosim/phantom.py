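"""Point-scatterer phantom of blood, wall and surrounding tissue.

Scatterers live in vessel coordinates (axial position ``s`` along the tube
axis, radius ``r`` from the axis, azimuth ``phi``); the tube axis is tilted
45 degrees (configurable) to the ultrasound beam, which points straight down
+z from the transducer face at z = 0.  Blood scatterers are advected with the
interpolated hemodynamic velocity field and recycled axially; wall and tissue
scatterers move only radially, with a displacement that decays linearly to
zero at the edge of the radial scan range.

Region backscatter amplitudes follow the per-mode table (arbitrary units):

    =========  ====  =====  ======
    mode       wall  blood  tissue
    =========  ====  =====  ======
    B-mode       50      5      10
    M-mode       50      5       0
    CFI           0      5       0
    =========  ====  =====  ======

Amplitudes are zero-mean Gaussian with the tabulated value as standard
deviation, so speckle is fully developed and zero-valued regions are
genuinely echo-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .acoustics import TransducerConfig
from .errors import ConfigurationError, SimulationError
from .geometry import VesselGeometry, radius_at

log = logging.getLogger(__name__)

BLOOD, WALL, TISSUE = 0, 1, 2
REGION_NAMES = {BLOOD: "blood", WALL: "wall", TISSUE: "tissue"}

REGION_AMPLITUDES = {
    "bmode": {WALL: 50.0, BLOOD: 5.0, TISSUE: 10.0},
    "mmode": {WALL: 50.0, BLOOD: 5.0, TISSUE: 0.0},
    "cfi": {WALL: 0.0, BLOOD: 5.0, TISSUE: 0.0},
}

@dataclass(frozen=True)
class BeamVesselFrame:
    """Mapping between vessel coordinates and beam (lab) coordinates.

    The vessel axis passes through ``(0, 0, axis_depth)`` with direction
    ``(sin angle, 0, cos angle)`` — i.e. tilted ``angle_deg`` away from the
    beam axis within the imaging plane.
    """

    angle_deg: float = 45.0
    axis_depth: float = 4e-2

    @property
    def axis_dir(self):
        th = np.deg2rad(self.angle_deg)
        return np.array([np.sin(th), 0.0, np.cos(th)])

    @property
    def normal_dir(self):
        th = np.deg2rad(self.angle_deg)
        return np.array([np.cos(th), 0.0, -np.sin(th)])

    def vessel_to_beam(self, s, r, phi):
        s, r, phi = np.broadcast_arrays(
            np.asarray(s, float), np.asarray(r, float), np.asarray(phi, float)
        )
        center = np.array([0.0, 0.0, self.axis_depth])
        a, n1 = self.axis_dir, self.normal_dir
        n2 = np.array([0.0, 1.0, 0.0])
        pts = (
            center[None, :]
            + s.reshape(-1, 1) * a
            + (r * np.cos(phi)).reshape(-1, 1) * n1
            + (r * np.sin(phi)).reshape(-1, 1) * n2
        )
        return pts.reshape(s.shape + (3,))

    def beam_to_vessel(self, pts):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        rel = pts - np.array([0.0, 0.0, self.axis_depth])
        s = rel @ self.axis_dir
        c1 = rel @ self.normal_dir
        c2 = rel[:, 1]
        r = np.hypot(c1, c2)
        phi = np.arctan2(c2, c1)
        return s, r, phi


@dataclass
class ScattererCloud:
    """Scatterer ensemble in vessel coordinates plus its beam frame.

    ``region`` holds integer labels (0 blood, 1 wall, 2 tissue); labels never
    change after creation.  ``time`` is the simulation time of the snapshot
    and advances with every motion update.  The cloud owns its random
    generator so that amplitude refreshes on recycling are reproducible.
    """

    s: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    amplitudes: np.ndarray
    region: np.ndarray
    frame: BeamVesselFrame
    rng_seed: int
    mode: str = "bmode"
    time: float = 0.0
    s_bounds: tuple[float, float] | None = None
    # sampling box (lat_halfwidth, elev_halfwidth, z_lo, z_hi) and number
    # density used at creation; kept so snapshots can be redrawn
    box: tuple[float, float, float, float] | None = None
    n_per_m3: float | None = None
    rng: np.random.Generator = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng(self.rng_seed)
        n = self.s.size
        for name in ("r", "phi", "amplitudes", "region"):
            if getattr(self, name).size != n:
                raise ConfigurationError(f"cloud field {name} has mismatched length")

    @property
    def n(self) -> int:
        return self.s.size

    @property
    def radial_coord(self) -> np.ndarray:
        return self.r

    @property
    def positions(self) -> np.ndarray:
        """Beam-coordinate (x, y, z) positions, shape (N, 3)."""
        return self.frame.vessel_to_beam(self.s, self.r, self.phi)

    def region_counts(self) -> dict[str, int]:
        return {
            REGION_NAMES[k]: int(np.count_nonzero(self.region == k))
            for k in (BLOOD, WALL, TISSUE)
        }


def resolution_cell_volume(cfg: TransducerConfig) -> float:
    """Axial footprint x lateral FWHM at focus x elevation FWHM (m^3)."""
    lat = 2.355 * float(cfg.sigma_lateral(cfg.focus))
    elev = 2.355 * float(cfg.sigma_elevation(cfg.focus))
    return cfg.axial_resolution * lat * elev


def _draw_amplitudes(rng, strength, n):
    # zero-mean Gaussian scattering amplitude; the tabulated per-region
    # "amplitude value" is the Gaussian scale (fully developed speckle)
    if strength == 0.0:
        return np.zeros(n)
    return rng.normal(0.0, abs(strength), n)


def init_cloud(
    geom: VesselGeometry,
    transducer: TransducerConfig,
    density: float = 10.0,
    angle_deg: float = 45.0,
    seed: int = 0,
    mode: str = "bmode",
    axis_depth: float | None = None,
    lat_halfwidth: float | None = None,
    elev_halfwidth: float | None = None,
    depth_margin: float = 3e-3,
    blood_s_halfspan: float | None = None,
) -> ScattererCloud:
    """Populate blood, wall and tissue scatterers around the imaging region.

    ``density`` is scatterers per resolution cell (default ten).  Wall and
    tissue scatterers are sampled uniformly in a beam-aligned box enclosing
    the insonified corridor and classified by their vessel radius at t = 0;
    blood scatterers are sampled uniformly in the lumen volume of an axial
    span that covers the corridor plus recycling headroom.  Identical seeds
    give bit-identical clouds.
    """
    if density <= 0:
        raise ConfigurationError("scatterer density must be positive")
    if mode not in REGION_AMPLITUDES:
        raise ConfigurationError(f"unknown imaging mode {mode!r}")
    frame = BeamVesselFrame(
        angle_deg=angle_deg,
        axis_depth=transducer.focus if axis_depth is None else axis_depth,
    )
    rng = np.random.default_rng(seed)
    cell = resolution_cell_volume(transducer)
    n_per_m3 = density / cell
    means = REGION_AMPLITUDES[mode]

    th = np.deg2rad(angle_deg)
    if lat_halfwidth is None:
        lat_halfwidth = max(8e-4, 3.0 * float(transducer.sigma_lateral(frame.axis_depth)))
    if elev_halfwidth is None:
        elev_halfwidth = 3.0 * float(transducer.sigma_elevation(frame.axis_depth))
    outer = geom.R0 + geom.h
    z_half = outer / max(np.sin(th), 0.2) + depth_margin
    z_lo, z_hi = frame.axis_depth - z_half, frame.axis_depth + z_half
    if z_lo <= 0:
        raise ConfigurationError("vessel box reaches the transducer face")

    # --- wall + tissue: uniform box in beam coordinates, classified ------
    vol_box = (2 * lat_halfwidth) * (2 * elev_halfwidth) * (z_hi - z_lo)
    n_box = rng.poisson(n_per_m3 * vol_box)
    pts = np.column_stack(
        [
            rng.uniform(-lat_halfwidth, lat_halfwidth, n_box),
            rng.uniform(-elev_halfwidth, elev_halfwidth, n_box),
            rng.uniform(z_lo, z_hi, n_box),
        ]
    )
    s_b, r_b, phi_b = frame.beam_to_vessel(pts)
    R_here = np.asarray(radius_at(geom, s_b, 0.0))
    is_wall = (r_b >= R_here) & (r_b < R_here + geom.h)
    is_tissue = r_b >= R_here + geom.h
    keep = is_wall | is_tissue
    s_wt, r_wt, phi_wt = s_b[keep], r_b[keep], phi_b[keep]
    reg_wt = np.where(is_wall[keep], WALL, TISSUE)

    # --- blood: uniform in the lumen over an axial span ------------------
    if blood_s_halfspan is None:
        blood_s_halfspan = z_half / max(np.cos(th), 0.2) + 2e-3
    s_axis = np.linspace(-blood_s_halfspan, blood_s_halfspan, 201)
    R_axis = np.asarray(radius_at(geom, s_axis, 0.0))
    area = np.pi * R_axis**2
    lumen_vol = np.trapezoid(area, s_axis)
    n_blood = rng.poisson(n_per_m3 * lumen_vol)
    cdf = np.concatenate([[0.0], np.cumsum((area[1:] + area[:-1]) / 2 * np.diff(s_axis))])
    cdf /= cdf[-1]
    s_bl = np.interp(rng.uniform(0, 1, n_blood), cdf, s_axis)
    R_bl = np.asarray(radius_at(geom, s_bl, 0.0))
    r_bl = R_bl * np.sqrt(rng.uniform(0, 1, n_blood)) * 0.999
    phi_bl = rng.uniform(0, 2 * np.pi, n_blood)

    s_all = np.concatenate([s_bl, s_wt])
    r_all = np.concatenate([r_bl, r_wt])
    phi_all = np.concatenate([phi_bl, phi_wt])
    region = np.concatenate([np.full(n_blood, BLOOD), reg_wt]).astype(np.int8)
    amps = np.empty(s_all.size)
    for code in (BLOOD, WALL, TISSUE):
        m = region == code
        amps[m] = _draw_amplitudes(rng, means[code], int(m.sum()))
    if s_all.size == 0:
        raise ConfigurationError("degenerate region volume: no scatterers generated")
    return ScattererCloud(
        s=s_all, r=r_all, phi=phi_all, amplitudes=amps, region=region,
        frame=frame, rng_seed=seed, mode=mode, time=0.0,
        s_bounds=(-blood_s_halfspan, blood_s_halfspan),
        box=(lat_halfwidth, elev_halfwidth, z_lo, z_hi), n_per_m3=n_per_m3,
        rng=rng,
    )


def draw_wall_tissue_snapshot(
    cloud: ScattererCloud,
    s_grid,
    W_ref,
    W_now,
    h: float,
    R_range: float,
):
    """Fresh wall/tissue scatterer draw consistent with the current wall state.

    The full-coupling acquisition regenerates scatterer positions and
    amplitudes after every RF line.  A new uniform draw is taken in the
    cloud's sampling box and classified against the reference (initial) wall
    surface ``W_ref(s)``; each kept scatterer's radius is then mapped through
    the integrated radial tissue-motion law

        r = r0 + [W_now(s) - W_ref(s)] * (1 - (r0 - W_ref) / (R_range - W_ref))

    so the lumen surface carries the full wall displacement while the motion
    decays linearly to zero at ``R_range``.  Statistically this equals
    advecting a frozen population, but successive snapshots carry
    independent speckle.  Returns ``(positions, amplitudes)`` in beam
    coordinates, drawn from the cloud's own generator (reproducible).
    """
    lat_hw, elev_hw, z_lo, z_hi = cloud.box
    rng = cloud.rng
    vol = (2 * lat_hw) * (2 * elev_hw) * (z_hi - z_lo)
    n = rng.poisson(cloud.n_per_m3 * vol)
    pts = np.column_stack(
        [
            rng.uniform(-lat_hw, lat_hw, n),
            rng.uniform(-elev_hw, elev_hw, n),
            rng.uniform(z_lo, z_hi, n),
        ]
    )
    s, r0, phi = cloud.frame.beam_to_vessel(pts)
    w0 = np.interp(s, s_grid, W_ref)
    is_wall = (r0 >= w0) & (r0 < w0 + h)
    is_tissue = r0 >= w0 + h
    keep = is_wall | is_tissue
    s, r0, phi, w0 = s[keep], r0[keep], phi[keep], w0[keep]
    delta = np.interp(s, s_grid, np.asarray(W_now) - np.asarray(W_ref))
    factor = np.clip(1.0 - (r0 - w0) / (R_range - w0), 0.0, 1.0)
    r = r0 + delta * factor
    means = REGION_AMPLITUDES[cloud.mode]
    amps = np.where(
        is_wall[keep],
        _draw_amplitudes(rng, means[WALL], s.size),
        _draw_amplitudes(rng, means[TISSUE], s.size),
    )
    return cloud.frame.vessel_to_beam(s, r, phi), amps


class FlowInterpolator:
    """Trilinear interpolation of the hemodynamic velocity field.

    The axial and radial velocities are tabulated on a grid of normalised
    radius ``eta = r / R(x, t)`` in [0, 1], axial position ``x`` and time
    ``t``.  Queries normalise the scatterer radius by the instantaneous
    lumen radius, so the no-slip surface always maps to ``eta = 1``;
    queries outside the tabulated axial span return zero velocity.
    """

    def __init__(self, eta_grid, x_grid, t_grid, u, v, geom: VesselGeometry,
                 surface=None, surface_t_grid=None):
        self.eta_grid = np.asarray(eta_grid, float)
        self.x_grid = np.asarray(x_grid, float)
        self.t_grid = np.asarray(t_grid, float)
        self.geom = geom
        self._u_tab = np.asarray(u, float)
        self._v_tab = np.asarray(v, float)
        # optional lumen-surface table W(x, t) = R + xi: the actual moving
        # boundary that blood scatterers must respect (the advection clamp);
        # falls back to the prescribed radius R(x, t) when absent.  The
        # surface carries higher temporal frequencies than the flow frames,
        # hence its own (finer) time grid.
        self._W_tab = None if surface is None else np.asarray(surface, float)
        self._W_t_grid = self.t_grid if surface_t_grid is None else np.asarray(
            surface_t_grid, float)

    @staticmethod
    def _time_blend(table, t_grid, t):
        """Linear blend of the last axis of ``table`` at scalar time t."""
        t = float(np.clip(t, t_grid[0], t_grid[-1]))
        i = int(np.clip(np.searchsorted(t_grid, t) - 1, 0, t_grid.size - 2))
        w = (t - t_grid[i]) / (t_grid[i + 1] - t_grid[i])
        return (1.0 - w) * table[..., i] + w * table[..., i + 1]

    def surface_at(self, s, t):
        """Lumen boundary radius at (s, t): W = R + xi if tabulated, else R."""
        s = np.asarray(s, float)
        if self._W_tab is None:
            return np.asarray(radius_at(self.geom, s, np.broadcast_to(t, s.shape)))
        Wcol = self._time_blend(self._W_tab, self._W_t_grid, np.median(t) if np.ndim(t) else t)
        return np.interp(s, self.x_grid, Wcol)

    def __call__(self, r, s, t):
        r = np.asarray(r, float)
        s = np.asarray(s, float)
        R = np.asarray(radius_at(self.geom, s, t))
        eta = np.clip(r / R, 0.0, 1.0)
        u2 = self._time_blend(self._u_tab, self.t_grid, t)
        v2 = self._time_blend(self._v_tab, self.t_grid, t)
        # bilinear gather on the uniform (eta, x) grid
        de = self.eta_grid[1] - self.eta_grid[0]
        dx = self.x_grid[1] - self.x_grid[0]
        fi = np.clip((eta - self.eta_grid[0]) / de, 0.0, self.eta_grid.size - 1.000001)
        fj = np.clip((s - self.x_grid[0]) / dx, 0.0, self.x_grid.size - 1.000001)
        i0 = fi.astype(int)
        j0 = fj.astype(int)
        wi = fi - i0
        wj = fj - j0
        w00 = (1 - wi) * (1 - wj)
        w01 = (1 - wi) * wj
        w10 = wi * (1 - wj)
        w11 = wi * wj
        u = (w00 * u2[i0, j0] + w01 * u2[i0, j0 + 1]
             + w10 * u2[i0 + 1, j0] + w11 * u2[i0 + 1, j0 + 1])
        v = (w00 * v2[i0, j0] + w01 * v2[i0, j0 + 1]
             + w10 * v2[i0 + 1, j0] + w11 * v2[i0 + 1, j0 + 1])
        outside = (s < self.x_grid[0]) | (s > self.x_grid[-1])
        if np.any(outside):
            u = np.where(outside, 0.0, u)
            v = np.where(outside, 0.0, v)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise SimulationError("flow interpolation returned non-finite velocity")
        return u, v


def advance_blood(cloud: ScattererCloud, flow: FlowInterpolator, dt: float) -> ScattererCloud:
    """Advect blood scatterers one emission interval.

    Forward-Euler update ``r += v dt``, ``s += u dt`` with velocities
    interpolated at the scatterer positions.  Scatterers crossing the axial
    bounds re-enter at the opposite end with a fresh amplitude draw; radii
    are reflected at the axis and clipped just inside the instantaneous
    lumen surface.  Counts per region are conserved.  The cloud is updated
    in place (and returned) with its clock advanced by ``dt``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    m = cloud.region == BLOOD
    t_now = cloud.time
    r_old = cloud.r[m]
    u, v = flow(r_old, cloud.s[m], t_now)
    s_new = cloud.s[m] + u * dt
    r_new = r_old + v * dt
    # the prescribed stenosis oscillation dilates the lumen quasi-statically;
    # the harmonic flow solution carries only the compliance part of the wall
    # velocity, so the dilation field v = (r/R) dR/dt is added kinematically
    # (it satisfies no-penetration at the oscillating wall and vanishes on
    # the axis)
    R_old = np.asarray(radius_at(flow.geom, cloud.s[m], t_now))
    R_new_t = np.asarray(radius_at(flow.geom, s_new, t_now + dt))
    r_new = r_new + (R_new_t - R_old) * (r_old / R_old)
    # near the moving lumen surface the discrete update accumulates error
    # (inward wall motion would pile scatterers on the clamp boundary);
    # blood within the outermost ~15% of the radius rides the surface at
    # constant normalised radius instead (no-penetration enforced exactly)
    W_old = flow.surface_at(cloud.s[m], t_now)
    W_new = flow.surface_at(s_new, t_now + dt)
    eta_old = r_old / W_old
    beta = np.clip((eta_old - 0.85) / 0.15, 0.0, 1.0)
    r_new = (1.0 - beta) * r_new + beta * eta_old * W_new
    neg = r_new < 0
    r_new[neg] = -r_new[neg]
    cloud.phi[m] = np.where(neg, cloud.phi[m] + np.pi, cloud.phi[m])

    if cloud.s_bounds is not None:
        lo, hi = cloud.s_bounds
        span = hi - lo
        wrapped = (s_new > hi) | (s_new < lo)
        s_new = lo + np.mod(s_new - lo, span)
        if np.any(wrapped):
            mean = REGION_AMPLITUDES[cloud.mode][BLOOD]
            amps = cloud.amplitudes[m]
            amps[wrapped] = _draw_amplitudes(cloud.rng, mean, int(wrapped.sum()))
            cloud.amplitudes[m] = amps

    t_new = t_now + dt
    r_new = np.minimum(r_new, 0.999 * W_new)
    cloud.s[m] = s_new
    cloud.r[m] = r_new
    cloud.time = t_new
    return cloud


def refresh_amplitudes(cloud: ScattererCloud) -> ScattererCloud:
    """Redraw every scatterer amplitude from its region distribution.

    The full-coupling acquisition regenerates scatterer amplitudes after
    each RF line, so successive emissions carry independent speckle; wall
    tracking then sees an unbiased, time-decorrelated interface instead of a
    frozen speckle pattern.  (Velocity estimation ensembles keep amplitudes
    fixed — slow-time correlation is the very signal there.)
    """
    means = REGION_AMPLITUDES[cloud.mode]
    for code in (BLOOD, WALL, TISSUE):
        m = cloud.region == code
        if np.any(m):
            cloud.amplitudes[m] = _draw_amplitudes(cloud.rng, means[code], int(m.sum()))
    return cloud


def advance_wall_tissue(
    cloud: ScattererCloud,
    delta_radius,
    R_range: float,
    origin=0.0,
) -> ScattererCloud:
    """Move wall/tissue scatterers radially with linearly decaying amplitude.

    Each wall or tissue scatterer at radius ``rho`` moves by

        delta_radius * (1 - (rho - origin) / (R_range - origin))

    clamped at zero beyond ``R_range`` — the printed tissue-motion law with a
    configurable measurement origin.  With ``origin = 0`` the decay is
    measured from the vessel axis; the imaging pipeline passes the local wall
    radius as ``origin`` so the lumen surface follows ``delta_radius``
    exactly while distant tissue stays still.  ``delta_radius`` and
    ``origin`` may be scalars or per-scatterer arrays (evaluated on the
    wall/tissue subset).
    """
    if R_range <= 0:
        raise ConfigurationError("R_range must be positive")
    m = (cloud.region == WALL) | (cloud.region == TISSUE)
    rho = cloud.r[m]
    origin_a = np.broadcast_to(np.asarray(origin, float), rho.shape)
    delta_a = np.broadcast_to(np.asarray(delta_radius, float), rho.shape)
    denom = R_range - origin_a
    if np.any(denom <= 0):
        raise ConfigurationError("R_range must exceed the decay origin")
    factor = 1.0 - (rho - origin_a) / denom
    beyond = factor < 0
    if np.any(beyond):
        log.warning(
            "advance_wall_tissue: %d scatterers beyond R_range; motion clamped to 0",
            int(beyond.sum()),
        )
    factor = np.clip(factor, 0.0, None)
    cloud.r[m] = rho + delta_a * factor
    return cloud
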