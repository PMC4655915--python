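"""Format readers and writers.

Meshes travel as VTK legacy ASCII (unstructured grid of tetrahedra with
per-cell tissue label and conductivity); electrode layouts, protocols, QC
masks and comparison tables as delimited text; raw/demodulated recordings
as HDF5 with channel and trial metadata; images as NIfTI (see
:meth:`ConductivityImage.to_nifti`).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .electrodes import ElectrodeArray
from .mesh import Mesh
from .signals import DemodulatedRecord, RawChannelRecord, TrialTimeline


# ----------------------------------------------------------------------
# VTK legacy ASCII meshes

def write_vtk_mesh(mesh: Mesh, path) -> None:
    """Unstructured-grid VTK legacy ASCII with label/conductivity cell data."""
    p = Path(path)
    with open(p, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tetrahedral EIT mesh (mm, S/m)\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {m * 5}\n")
        cells = np.column_stack([np.full(m, 4), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10), fmt="%d")  # VTK_TETRA
        fh.write(f"CELL_DATA {m}\n")
        fh.write("SCALARS tissue_label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.labels, fmt="%d")
        fh.write("SCALARS conductivity_S_m double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.conductivity, fmt="%.9g")


def read_vtk_mesh(path) -> Mesh:
    """Read a mesh written by :func:`write_vtk_mesh`."""
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nodes = elements = labels = cond = None
    while i < len(lines):
        line = lines[i].strip()
        up = line.upper()
        if up.startswith("POINTS"):
            n = int(line.split()[1])
            vals = _read_numbers(lines, i + 1, n * 3)
            nodes = np.array(vals, dtype=float).reshape(n, 3)
        elif up.startswith("CELLS"):
            m = int(line.split()[1])
            total = int(line.split()[2])
            vals = _read_numbers(lines, i + 1, total)
            arr = np.array(vals, dtype=int).reshape(m, 5)
            if (arr[:, 0] != 4).any():
                raise ValueError("only tetrahedral cells are supported")
            elements = arr[:, 1:]
        elif up.startswith("SCALARS"):
            name = line.split()[1]
            m = len(elements)
            vals = _read_numbers(lines, i + 2, m)  # skip LOOKUP_TABLE
            if name == "tissue_label":
                labels = np.array(vals, dtype=int)
            elif name == "conductivity_S_m":
                cond = np.array(vals, dtype=float)
        i += 1
    if nodes is None or elements is None:
        raise ValueError("not a tetrahedral VTK legacy ASCII file")
    if labels is None:
        labels = np.zeros(len(elements), dtype=int)
    if cond is None:
        raise ValueError("mesh file lacks conductivity cell data")
    return Mesh(nodes, elements, labels, cond)


def _read_numbers(lines, start, count):
    out = []
    i = start
    while len(out) < count and i < len(lines):
        out.extend(lines[i].split())
        i += 1
    if len(out) < count:
        raise ValueError("truncated VTK file")
    return out[:count]


# ----------------------------------------------------------------------
# electrode layouts

def write_electrodes_csv(array: ElectrodeArray, path) -> None:
    pd.DataFrame({
        "electrode": np.arange(array.n_electrodes),
        "x_mm": array.positions[:, 0],
        "y_mm": array.positions[:, 1],
        "z_mm": array.positions[:, 2],
        "node": array.node_indices,
        "diameter_mm": array.diameter,
        "pitch_mm": array.pitch,
    }).to_csv(path, index=False)


def read_electrodes_csv(path) -> ElectrodeArray:
    df = pd.read_csv(path)
    return ElectrodeArray(
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        df["node"].to_numpy(),
        float(df["diameter_mm"].iloc[0]),
        float(df["pitch_mm"].iloc[0]))


# ----------------------------------------------------------------------
# recordings (HDF5)

def _timeline_attrs(tl: TrialTimeline) -> dict:
    return {"trial_s": tl.trial_s, "deflections_s": list(tl.deflections_s),
            "n_trials": tl.n_trials, "interstim_start_s": tl.interstim_start_s,
            "interstim_guard_s": tl.interstim_guard_s,
            "response_s": tl.response_s}


def _timeline_from_attrs(a) -> TrialTimeline:
    return TrialTimeline(float(a["trial_s"]), tuple(a["deflections_s"]),
                         int(a["n_trials"]), float(a["interstim_start_s"]),
                         float(a["interstim_guard_s"]), float(a["response_s"]))


def write_raw_records(records: list[RawChannelRecord], path) -> None:
    """One HDF5 group per injection with channel/trial metadata."""
    with h5py.File(path, "w") as f:
        for k, r in enumerate(records):
            g = f.create_group(f"injection_{k:03d}")
            g.create_dataset("data", data=r.data, compression="gzip")
            g.attrs["fs"] = r.fs
            g.attrs["carrier_hz"] = r.carrier_hz
            if r.pair is not None:
                g.attrs["pair"] = list(r.pair)
            if r.channel_electrodes is not None:
                g.create_dataset("channel_electrodes", data=r.channel_electrodes)
            g.create_dataset("trial_starts", data=r.trial_starts)
            for key, val in _timeline_attrs(r.timeline).items():
                g.attrs[f"timeline_{key}"] = val


def read_raw_records(path) -> list[RawChannelRecord]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            tl = _timeline_from_attrs(
                {k[len("timeline_"):]: g.attrs[k] for k in g.attrs
                 if k.startswith("timeline_")})
            out.append(RawChannelRecord(
                g["data"][()], float(g.attrs["fs"]),
                float(g.attrs["carrier_hz"]), tl,
                trial_starts=g["trial_starts"][()],
                channel_electrodes=(g["channel_electrodes"][()]
                                    if "channel_electrodes" in g else None),
                pair=(tuple(int(x) for x in g.attrs["pair"])
                      if "pair" in g.attrs else None)))
    return out


def write_demodulated_records(records: list[DemodulatedRecord], path) -> None:
    with h5py.File(path, "w") as f:
        for k, r in enumerate(records):
            g = f.create_group(f"injection_{k:03d}")
            g.create_dataset("z_real", data=r.z.real, compression="gzip")
            g.create_dataset("z_imag", data=r.z.imag, compression="gzip")
            g.create_dataset("baseline_v", data=r.baseline_v)
            g.create_dataset("dz_percent", data=r.dz_percent, compression="gzip")
            g.create_dataset("interstim_sd_percent", data=r.interstim_sd_percent)
            if r.ep is not None:
                g.create_dataset("ep", data=r.ep, compression="gzip")
            if r.baseline_phase is not None:
                g.create_dataset("baseline_phase", data=r.baseline_phase)
            if r.channel_electrodes is not None:
                g.create_dataset("channel_electrodes", data=r.channel_electrodes)
            g.attrs["fs"] = r.fs
            if r.pair is not None:
                g.attrs["pair"] = list(r.pair)
            for key, val in _timeline_attrs(r.timeline).items():
                g.attrs[f"timeline_{key}"] = val


def read_demodulated_records(path) -> list[DemodulatedRecord]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            tl = _timeline_from_attrs(
                {k[len("timeline_"):]: g.attrs[k] for k in g.attrs
                 if k.startswith("timeline_")})
            out.append(DemodulatedRecord(
                z=g["z_real"][()] + 1j * g["z_imag"][()],
                baseline_v=g["baseline_v"][()],
                dz_percent=g["dz_percent"][()],
                interstim_sd_percent=g["interstim_sd_percent"][()],
                fs=float(g.attrs["fs"]), timeline=tl,
                ep=g["ep"][()] if "ep" in g else None,
                channel_electrodes=(g["channel_electrodes"][()]
                                    if "channel_electrodes" in g else None),
                pair=(tuple(int(x) for x in g.attrs["pair"])
                      if "pair" in g.attrs else None),
                baseline_phase=(g["baseline_phase"][()]
                                if "baseline_phase" in g else None)))
    return out
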