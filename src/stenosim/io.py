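"""HDF5 bundle output and plain-text exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np


def _open_bundle(config, tag: str):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{tag}_s{config.geometry.stenosis_pct:g}_w{config.geometry.wall_freq_factor:g}_seed{config.seed}.h5"
    fh = h5py.File(path, "w")
    fh.attrs["config_json"] = json.dumps(config.to_dict())
    fh.attrs["seed"] = config.seed
    return fh, path


def write_mmode_bundle(config, result):
    fh, path = _open_bundle(config, "mmode")
    with fh:
        g = fh.create_group("tracking")
        g.create_dataset("times", data=result.times)
        g.create_dataset("est_position", data=result.est.position)
        g.create_dataset("ref_position", data=result.ref.position)
        g.create_dataset("per_time_errors_pct", data=result.report.per_time_errors)
        g.attrs["mean_relative_error_pct"] = result.report.mean_relative_error
        g.attrs["max_relative_error_pct"] = result.report.max_relative_error
        if result.mmode_db is not None:
            im = fh.create_group("images")
            im.create_dataset("mmode_db", data=result.mmode_db)
            im.create_dataset("despeckled", data=result.despeckled)
            im.create_dataset("depth_axis", data=result.depth_axis)
    return path


def write_cfi_bundle(config, result):
    fh, path = _open_bundle(config, "cfi")
    with fh:
        g = fh.create_group("cfm")
        g.create_dataset("velocity", data=result.cfm.velocity)
        g.create_dataset("variance", data=result.cfm.variance)
        g.create_dataset("power", data=result.cfm.power)
        g.create_dataset("low_power_mask", data=result.cfm.low_power_mask)
        g.create_dataset("depth_axis", data=result.cfm.depth_axis)
        g.create_dataset("line_lats", data=result.line_lats)
        g.attrs["nyquist_velocity"] = result.cfm.nyquist
        g.attrs["peak_velocity"] = result.peak_velocity
        g.attrs["t_center"] = result.t_center
    return path


def write_bmode_bundle(config, image):
    fh, path = _open_bundle(config, "bmode")
    with fh:
        g = fh.create_group("bmode")
        g.create_dataset("image_db", data=image.data)
        g.create_dataset("depth_axis", data=image.depth_axis)
        g.create_dataset("lateral_axis", data=image.lateral_axis)
        g.attrs["dynamic_range"] = image.dynamic_range
    return path


def write_harmonic_solution(path, sol):
    """Serialise a pressure-harmonic solution: one group per harmonic.

    Each group ``harmonic_<n>`` holds ``p``, ``dpdx`` and ``d2pdx2`` datasets
    (complex); the axial grid and solver metadata live at the root.
    """
    with h5py.File(path, "w") as fh:
        fh.create_dataset("x", data=sol.x)
        fh.attrs["omega0"] = sol.omega0
        fh.attrs["t_phase"] = sol.t_phase
        fh.create_dataset("beta", data=sol.beta)
        for n in range(sol.p.shape[0]):
            g = fh.create_group(f"harmonic_{n}")
            g.create_dataset("p", data=sol.p[n])
            g.create_dataset("dpdx", data=sol.dpdx[n])
            g.create_dataset("d2pdx2", data=sol.d2pdx2[n])
    return path


def read_harmonic_solution(path):
    """Load the arrays written by :func:`write_harmonic_solution`."""
    with h5py.File(path, "r") as fh:
        x = fh["x"][:]
        beta = fh["beta"][:]
        n_harm = sum(1 for k in fh if k.startswith("harmonic_"))
        p = np.stack([fh[f"harmonic_{n}/p"][:] for n in range(n_harm)])
        dpdx = np.stack([fh[f"harmonic_{n}/dpdx"][:] for n in range(n_harm)])
        d2 = np.stack([fh[f"harmonic_{n}/d2pdx2"][:] for n in range(n_harm)])
        meta = dict(fh.attrs)
    return dict(x=x, beta=beta, p=p, dpdx=dpdx, d2pdx2=d2, **meta)


def write_cloud_snapshot(group: h5py.Group, cloud, time: float):
    """One phantom snapshot: positions (N, 3), amplitudes, region codes."""
    group.create_dataset("positions", data=cloud.positions)
    group.create_dataset("amplitudes", data=cloud.amplitudes)
    group.create_dataset("region", data=cloud.region)
    group.attrs["time"] = time


def export_centerline_profile(path, x, u_centerline, header="x_m\tu_mps"):
    """Plain-text centerline velocity profile export."""
    arr = np.column_stack([x, u_centerline])
    np.savetxt(path, arr, delimiter="\t", header=header)


def export_error_table(path, table):
    """Write the stenosis-by-frequency error table as TSV."""
    table.to_csv(path, sep="\t", float_format="%.3f")
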