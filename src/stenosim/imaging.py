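"""Image formation: envelope imaging and Kasai autocorrelation velocimetry.

RF ensembles are quadrature-demodulated at the centre frequency to complex
baseband (IQ); the envelope feeds log-compressed B-/M-mode images, and the
lag-one autocorrelation phase across the slow-time ensemble yields the mean
axial velocity per depth gate:

    v_z = c / (4 pi f0 T_PRF) * atan2( sum(y_i x_{i-1} - x_i y_{i-1}),
                                       sum(x_i x_{i-1} + y_i y_{i-1}) )

with x, y the real/imaginary baseband parts.  A positive phase increment
between emissions maps to positive v_z; magnitudes wrap at the Nyquist
velocity c*PRF/(4 f0).  No clutter filter is applied by default — images
deliberately contain the low-frequency, high-amplitude wall clutter a real
scanner would have to suppress; a polynomial-regression wall filter hook is
available but off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .acoustics import RFEnsemble, TransducerConfig
from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class IQEnsemble:
    """Complex baseband samples, ``iq[depth, line, emission]``."""

    iq: np.ndarray
    t0: float
    fs: float
    f0: float
    T_prf: float
    c: float

    @property
    def depth_axis(self):
        return self.c * (self.t0 + np.arange(self.iq.shape[0]) / self.fs) / 2.0

    @property
    def envelope(self):
        return np.abs(self.iq)


def demodulate(rf: RFEnsemble, decimation: int = 4, numtaps: int = 101) -> IQEnsemble:
    """Quadrature demodulation of an RF ensemble to complex baseband.

    Mixes with ``exp(-j 2 pi f0 t)``, zero-phase low-pass filters (FIR,
    cutoff at the centre frequency) and decimates.  The baseband magnitude
    equals the RF envelope.
    """
    cfg = rf.cfg
    f0 = cfg.center_frequency
    if rf.fs < 4.0 * f0:
        raise ConfigurationError("RF is undersampled: need fs >= 4 f0 to demodulate")
    ns = rf.rf.shape[0]
    t = rf.t0 + np.arange(ns) / rf.fs
    mixed = rf.rf * (2.0 * np.exp(-2j * np.pi * f0 * t))[:, None, None]
    taps = sps.firwin(numtaps, f0, fs=rf.fs)
    iq = sps.filtfilt(taps, [1.0], mixed, axis=0)
    iq = iq[::decimation]
    return IQEnsemble(
        iq=iq, t0=rf.t0, fs=rf.fs / decimation, f0=f0,
        T_prf=1.0 / rf.plan.prf, c=cfg.c,
    )


@dataclass
class ColorFlowImage:
    """Axial velocity estimates (m/s) on a depth x line grid."""

    velocity: np.ndarray
    nyquist: float
    variance: np.ndarray
    power: np.ndarray
    low_power_mask: np.ndarray
    depth_axis: np.ndarray


def kasai_velocity(
    iq: IQEnsemble,
    avg_window: int | None = None,
    power_rel_threshold: float = 1e-4,
) -> ColorFlowImage:
    """Mean axial velocity per depth gate from the lag-one IQ phase.

    ``avg_window`` axially averages the complex correlation sums (default:
    one pulse length worth of samples) before taking the phase, the usual
    variance-reduction step.  Gates whose mean power falls below
    ``power_rel_threshold`` times the frame maximum are zeroed and flagged.
    The estimate is invariant to overall IQ amplitude scaling and wraps at
    the Nyquist velocity.
    """
    z = iq.iq
    if z.ndim != 3 or z.shape[2] < 2:
        raise ConfigurationError("kasai_velocity needs an ensemble of >= 2 emissions")
    r1 = np.sum(z[:, :, 1:] * np.conj(z[:, :, :-1]), axis=2)
    r0 = np.mean(np.abs(z) ** 2, axis=2)
    if avg_window is None:
        avg_window = max(1, int(round(2.5 / iq.f0 * iq.fs)))
    if avg_window > 1:
        kern = np.ones(avg_window) / avg_window
        r1 = sps.convolve(r1.real, kern[:, None], mode="same") + 1j * sps.convolve(
            r1.imag, kern[:, None], mode="same"
        )
        r0 = sps.convolve(r0, kern[:, None], mode="same")
    nyq = iq.c / (4.0 * iq.f0 * iq.T_prf)
    phase = np.arctan2(r1.imag, r1.real)
    v = iq.c / (4.0 * np.pi * iq.f0 * iq.T_prf) * phase
    power = r0
    low = power < power_rel_threshold * max(power.max(), 1e-300)
    v = np.where(low, 0.0, v)
    mag = np.abs(r1) / np.maximum(power * (z.shape[2] - 1), 1e-300)
    variance = np.clip(1.0 - mag, 0.0, 1.0)
    return ColorFlowImage(
        velocity=v, nyquist=nyq, variance=variance, power=power,
        low_power_mask=low, depth_axis=iq.depth_axis,
    )


def polynomial_wall_filter(iq: IQEnsemble, order: int = 1) -> IQEnsemble:
    """Slow-time polynomial-regression clutter filter (hook; off by default).

    Removes the best-fit polynomial of the given order from each gate's
    slow-time series, suppressing near-DC wall clutter.
    """
    z = iq.iq
    n = z.shape[2]
    t = np.arange(n, dtype=float)
    V = np.polynomial.polynomial.polyvander(t, order)
    proj = V @ np.linalg.pinv(V)
    resid = z - np.einsum("ij,dkj->dki", proj, z)
    return IQEnsemble(resid, iq.t0, iq.fs, iq.f0, iq.T_prf, iq.c)


# ---------------------------------------------------------------------------
# Brightness-mode images
# ---------------------------------------------------------------------------


@dataclass
class BModeImage:
    """Log-compressed envelope in dB (0 at frame max, floor at -DR)."""

    data: np.ndarray
    depth_axis: np.ndarray
    lateral_axis: np.ndarray
    dynamic_range: float


@dataclass
class MModeImage:
    data: np.ndarray
    depth_axis: np.ndarray
    times: np.ndarray
    dynamic_range: float


def _log_compress(env: np.ndarray, dynamic_range: float) -> np.ndarray:
    peak = env.max()
    if peak <= 0:
        log.warning("all-zero frame: returning uniform floor image")
        return np.full_like(env, -dynamic_range)
    db = 20.0 * np.log10(np.maximum(env / peak, 10 ** (-dynamic_range / 20.0 - 1)))
    return np.clip(db, -dynamic_range, 0.0)


def form_bmode(rf: RFEnsemble, dynamic_range: float = 50.0, decimation: int = 4) -> BModeImage:
    """Envelope -> per-frame peak normalisation -> 20 log10, clipped."""
    iq = demodulate(rf, decimation=decimation)
    env = iq.envelope[:, :, 0]
    return BModeImage(
        data=_log_compress(env, dynamic_range),
        depth_axis=iq.depth_axis,
        lateral_axis=rf.plan.line_lats,
        dynamic_range=dynamic_range,
    )


def form_mmode(rf: RFEnsemble, dynamic_range: float = 50.0, decimation: int = 4) -> MModeImage:
    """Single-line brightness over time; columns ordered by emission time."""
    if rf.rf.shape[1] != 1:
        raise ConfigurationError("M-mode expects a single-line ensemble")
    iq = demodulate(rf, decimation=decimation)
    env = iq.envelope[:, 0, :]
    return MModeImage(
        data=_log_compress(env, dynamic_range),
        depth_axis=iq.depth_axis,
        times=rf.plan.emission_times(),
        dynamic_range=dynamic_range,
    )


def beam_to_vessel_projection(v_z, angle_deg: float):
    """Convert beam-axial velocity to velocity along the vessel axis.

    For flow along a vessel tilted ``angle_deg`` from the beam the measured
    axial component is ``v_axis cos(angle)``; the projection divides it back
    out.  Angles at or beyond 90 degrees leave the axial component
    unobservable and are rejected.
    """
    if not 0.0 <= angle_deg < 90.0:
        raise ConfigurationError("angle must lie in [0, 90) degrees")
    return np.asarray(v_z, float) / np.cos(np.deg2rad(angle_deg))
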