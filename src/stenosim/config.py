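"""Run configuration: defaults, YAML parsing and object factories.

Defaults reproduce the reference parameter set of the modelled carotid
geometry (radius 4 mm, wall 0.3 mm, stenosis half-length 40 mm, blood density
1050 kg/m^3, viscosity 3.5e-3 Pa s, Young's modulus 978 kPa, Poisson ratio
0.5, cardiac period 2/3 s, fundamental 3*pi rad/s) and the per-mode
transducer setups.  Everything is SI internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acoustics import TransducerConfig
from .errors import ConfigurationError
from .geometry import FluidProperties, VesselGeometry, WallProperties
from .hemodynamics import InletWaveform, fourier_decompose, synth_cca_waveform


@dataclass
class GeometryConfig:
    R0: float = 4e-3
    x0: float = 40e-3
    h: float = 0.3e-3
    stenosis_pct: float = 25.0
    alpha: float = 0.05
    wall_freq_factor: float = 1.0  # omega_wall = factor * omega0


@dataclass
class WallConfig:
    E: float = 978e3
    sigma: float = 0.5
    rho_w: float = 1100.0


@dataclass
class FluidConfig:
    rho: float = 1050.0
    mu: float = 3.5e-3


@dataclass
class WaveformConfig:
    tp: float = 2.0 / 3.0
    peak: float = 0.8
    n_harmonics: int = 14
    n_samples: int = 256
    seed: int | None = None


@dataclass
class PhantomConfig:
    density: float = 10.0
    angle_deg: float = 45.0
    R_range: float = 30e-3


@dataclass
class ImagingConfig:
    ensemble: int = 8
    n_lines: int = 10
    line_span: float = 3e-3
    dynamic_range: float = 50.0
    decimation: int = 4
    wall_filter: bool = False
    t_center_frac: float = 0.24  # CFI / B-mode evaluation instant, t/tp


@dataclass
class TrackingConfig:
    # the pipeline smooths harder than the bare srad() defaults because its
    # M-mode columns carry independent speckle (the phantom is regenerated
    # every emission); see docs/methods.md
    srad_iters: int = 300
    srad_dt: float = 0.05
    threshold: float = 0.5
    threshold_mode: str = "column"  # per-column maximum normalisation
    side: str = "near"
    method: str = "band_centroid"


@dataclass
class RunConfig:
    """Full configuration of one simulation case."""

    mode: str = "mmode"
    seed: int = 0
    outdir: str = "runs"
    n_frames: int = 48
    prf_override: float | None = None
    n_axial: int = 257
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    wall: WallConfig = field(default_factory=WallConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)

    # -- factories --------------------------------------------------------
    @property
    def omega0(self) -> float:
        return 2.0 * np.pi / self.waveform.tp

    def make_geometry(self) -> VesselGeometry:
        g = self.geometry
        return VesselGeometry(
            R0=g.R0,
            delta=g.stenosis_pct / 100.0 * g.R0,
            alpha=g.alpha,
            omega_wall=g.wall_freq_factor * self.omega0,
            x0=g.x0,
            h=g.h,
        )

    def make_wall(self) -> WallProperties:
        return WallProperties(E=self.wall.E, sigma=self.wall.sigma, rho_w=self.wall.rho_w)

    def make_fluid(self) -> FluidProperties:
        return FluidProperties(rho=self.fluid.rho, mu=self.fluid.mu)

    def make_waveform(self) -> InletWaveform:
        w = self.waveform
        _, u = synth_cca_waveform(w.tp, w.peak, seed=w.seed, n_samples=w.n_samples)
        return fourier_decompose(u, w.n_harmonics, tp=w.tp)

    def make_transducer(self) -> TransducerConfig:
        kw = {}
        if self.prf_override is not None:
            kw["prf"] = self.prf_override
        return TransducerConfig.preset(self.mode, **kw)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _build_dataclass(cls, dict(d), "config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        """Instantiate every derived object; raises on the offending key."""
        if self.mode not in ("bmode", "mmode", "cfi"):
            raise ConfigurationError(f"mode: unknown imaging mode {self.mode!r}")
        self.make_geometry()
        self.make_wall()
        self.make_fluid()
        self.make_waveform()
        self.make_transducer()
        if self.n_frames < 2:
            raise ConfigurationError("n_frames: need at least 2 flow frames")
        if not 0 < self.tracking.threshold < 1:
            raise ConfigurationError("tracking.threshold: must lie in (0, 1)")


_SECTION_TYPES = {
    "geometry": GeometryConfig,
    "wall": WallConfig,
    "fluid": FluidConfig,
    "waveform": WaveformConfig,
    "phantom": PhantomConfig,
    "imaging": ImagingConfig,
    "tracking": TrackingConfig,
}


def _build_dataclass(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{where}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        sub = _SECTION_TYPES.get(key)
        if sub is not None and isinstance(val, dict):
            kwargs[key] = _build_dataclass(sub, val, f"{where}.{key}")
        else:
            kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{where}: {exc}") from exc
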