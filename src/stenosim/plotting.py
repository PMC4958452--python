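"""Presentation helpers (kept out of the computation path).

Each function renders to a matplotlib figure and returns it; callers decide
whether to save or show.  Stored data stay in physical units — colour maps
and dB scales live only here.
"""

from __future__ import annotations

import numpy as np


def plot_bmode(image, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(
        image.data,
        extent=[
            image.lateral_axis[0] * 1e3, image.lateral_axis[-1] * 1e3,
            image.depth_axis[-1] * 1e3, image.depth_axis[0] * 1e3,
        ],
        cmap="gray", vmin=-image.dynamic_range, vmax=0, aspect="auto",
    )
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    return ax.figure


def plot_mmode(image, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(
        image.data,
        extent=[image.times[0], image.times[-1],
                image.depth_axis[-1] * 1e3, image.depth_axis[0] * 1e3],
        cmap="gray", vmin=-image.dynamic_range, vmax=0, aspect="auto",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("depth (mm)")
    return ax.figure


def plot_cfm(cfm, line_lats, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = np.where(cfm.low_power_mask, np.nan, cfm.velocity)
    m = ax.imshow(
        v,
        extent=[line_lats[0] * 1e3, line_lats[-1] * 1e3,
                cfm.depth_axis[-1] * 1e3, cfm.depth_axis[0] * 1e3],
        cmap="RdBu_r", vmin=-cfm.nyquist, vmax=cfm.nyquist, aspect="auto",
    )
    ax.figure.colorbar(m, ax=ax, label="axial velocity (m/s)")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    return ax.figure


def plot_tracking(result, ax=None):
    """Reference vs ultrasound-derived wall displacement (micrometres)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.times, result.ref.displacement * 1e6, "r", label="numerical")
    ax.plot(result.times, result.est.displacement * 1e6, "b", label="ultrasound")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("wall displacement (um)")
    ax.legend()
    return ax.figure
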