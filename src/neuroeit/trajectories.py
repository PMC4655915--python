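"""4D spatiotemporal trajectories of reconstructed activity.

The propagation of a conductivity change is summarized by integrating
streamlines of the velocity-like field

    v(r, t) = grad( d sigma(r, t) / dt )

with a first-order Euler scheme whose time step obeys the longest-step
condition: delta_t = r_z / max|v| over the frame, with r_z = 50 um, so no
spatial step exceeds r_z.  1000 trajectories are seeded on a uniform
lattice in a 500 x 500 x 500 um region around the centre of activity.
Lateral segments (horizontal displacement exceeding vertical) are counted
per 50 um depth bin to obtain the depth-connection profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .reconstruction import ConductivityImage


class Termination(Enum):
    TIME_END = "time-range end"
    LEFT_GRID = "left grid"
    STAGNATION = "stagnation"


@dataclass
class VelocityField:
    """grad(d sigma / dt) sampled on the image grid per frame.

    ``values``: (n_times, nx, ny, nz, 3) in % / (ms mm); times in ms.
    Trilinear interpolation between voxel centres.
    """

    values: np.ndarray
    times_ms: np.ndarray
    grid: "object"  # InverseGrid

    def __post_init__(self):
        if not np.isfinite(self.values).all():
            raise ValueError("velocity field contains non-finite values")
        g = self.grid
        axes = [g.origin[k] + (np.arange(g.shape[k]) + 0.5) * g.pitch
                for k in range(3)]
        self._interp = [
            RegularGridInterpolator(axes, self.values[i], bounds_error=False,
                                    fill_value=np.nan)
            for i in range(len(self.times_ms))]

    def sample(self, frame: int, points: np.ndarray) -> np.ndarray:
        return self._interp[frame](np.atleast_2d(points))

    def frame_max_speed(self, frame: int) -> float:
        return float(np.linalg.norm(self.values[frame], axis=-1).max())


@dataclass
class Trajectory:
    """Time-stamped 3D polyline started at ``r_start``."""

    times_ms: np.ndarray
    points: np.ndarray           # (n, 3) mm
    r_start: np.ndarray
    termination: Termination

    def steps(self) -> np.ndarray:
        return np.diff(self.points, axis=0)


@dataclass
class TrajectoryConfig:
    r_z_um: float = 50.0          # longest spatial step
    n_trajectories: int = 1000
    seed_roi_um: float = 500.0    # edge of the cubic seeding ROI
    time_window_ms: tuple[float, float] | None = None
    stagnation_rtol: float = 1e-6

    def __post_init__(self):
        if self.r_z_um <= 0:
            raise ValueError("r_z must be positive")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


# ----------------------------------------------------------------------

def center_of_activity(image: ConductivityImage, t_ms: float,
                       threshold_frac: float = 0.5) -> np.ndarray:
    """|dsigma|-weighted centroid of voxels >= threshold x frame peak.

    Returns NaNs (sentinel) for an all-zero frame.
    """
    frame = np.abs(image.frame(t_ms))
    peak = frame.max()
    if peak == 0:
        return np.full(3, np.nan)
    w = np.where(frame >= threshold_frac * peak, frame, 0.0).ravel()
    centers = image.grid.voxel_centers
    return (w @ centers) / w.sum()


def velocity_field(image: ConductivityImage) -> VelocityField:
    """Temporal derivative (central differences; one-sided at the ends)
    followed by the spatial gradient on the voxel grid."""
    if image.n_times < 2:
        raise ValueError("velocity field needs at least 2 time steps")
    v = image.values
    dt = np.gradient(image.times_ms)
    dvdt = np.gradient(v, axis=0) / dt[:, None, None, None]
    out = np.empty(v.shape + (3,))
    for i in range(v.shape[0]):
        gx, gy, gz = np.gradient(dvdt[i], image.grid.pitch)
        out[i, ..., 0], out[i, ..., 1], out[i, ..., 2] = gx, gy, gz
    return VelocityField(out, image.times_ms, image.grid)


def seed_lattice(center: np.ndarray, config: TrajectoryConfig) -> np.ndarray:
    """Deterministic uniform lattice of seeds in the cubic ROI."""
    n_side = int(round(config.n_trajectories ** (1 / 3)))
    while n_side ** 3 < config.n_trajectories:
        n_side += 1
    edge = config.seed_roi_um / 1000.0
    ax = (np.arange(n_side) + 0.5) / n_side * edge - edge / 2
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])[:config.n_trajectories]
    return pts + np.asarray(center)


def integrate_trajectories(field: VelocityField,
                           config: TrajectoryConfig | None = None,
                           seeds: np.ndarray | None = None,
                           center: np.ndarray | None = None) -> list[Trajectory]:
    """Euler integration under the longest-step condition.

    Within each frame interval, Euler sub-steps of delta_t = r_z / max|v|
    (max over the frame) advance the trajectories, so no spatial step
    exceeds r_z.  A frame with zero maximum speed is crossed in a single
    stagnant step.  Trajectories terminate at the window end, on leaving
    the grid, or when the local speed falls below ``stagnation_rtol`` of
    the frame maximum.
    """
    config = config or TrajectoryConfig()
    if seeds is None:
        if center is None:
            raise ValueError("provide seeds or a centre of activity")
        seeds = seed_lattice(np.asarray(center), config)
    times = field.times_ms
    t0, t1 = config.time_window_ms or (times[0], times[-1])
    r_z_mm = config.r_z_um / 1000.0

    trajs = []
    for s in np.atleast_2d(seeds):
        pts = [s.copy()]
        ts = [t0]
        term = Termination.TIME_END
        t = t0
        pos = s.copy()
        alive = True
        while alive and t < t1 - 1e-12:
            frame = int(np.clip(np.searchsorted(times, t + 1e-12) - 1, 0,
                                len(times) - 1))
            frame_end = times[frame + 1] if frame + 1 < len(times) else t1
            vmax = field.frame_max_speed(frame)
            if vmax == 0:
                # stagnant frame: jump to its end
                t = min(frame_end, t1)
                ts.append(t)
                pts.append(pos.copy())
                term = Termination.STAGNATION
                continue
            dt = r_z_mm / vmax
            while t < min(frame_end, t1) - 1e-12:
                step_dt = min(dt, min(frame_end, t1) - t)
                v = field.sample(frame, pos)[0]
                if np.isnan(v).any():
                    term = Termination.LEFT_GRID
                    alive = False
                    break
                speed = np.linalg.norm(v)
                if speed < config.stagnation_rtol * vmax:
                    term = Termination.STAGNATION
                    alive = False
                    break
                pos = pos + v * step_dt
                t += step_dt
                ts.append(t)
                pts.append(pos.copy())
        trajs.append(Trajectory(np.array(ts), np.array(pts), s.copy(), term))
    return trajs


def depth_connection_profile(trajectories: list[Trajectory],
                             bin_um: float = 50.0,
                             depth_range_mm: tuple[float, float] | None = None
                             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Count lateral trajectory segments per depth bin.

    A segment is lateral when its horizontal displacement exceeds its
    vertical one; it is binned at its midpoint depth.  Returns
    ``(bin_edges_mm, counts, argmax_depth_mm)`` where the argmax depth is
    the centre of the most-connected bin (NaN if no lateral segments).
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    mids, lateral = [], []
    for tr in trajectories:
        d = tr.steps()
        if len(d) == 0:
            continue
        horiz = np.linalg.norm(d[:, :2], axis=1)
        vert = np.abs(d[:, 2])
        mid_z = (tr.points[:-1, 2] + tr.points[1:, 2]) / 2
        sel = horiz > vert
        mids.append(mid_z[sel])
        lateral.append(sel.sum())
    mids = np.concatenate(mids) if mids else np.array([])
    if depth_range_mm is None:
        zs = np.concatenate([tr.points[:, 2] for tr in trajectories])
        depth_range_mm = (float(np.floor(zs.min() * 20) / 20),
                          float(np.ceil(zs.max() * 20) / 20))
    h = bin_um / 1000.0
    edges = np.arange(depth_range_mm[0], depth_range_mm[1] + h / 2, h)
    counts, _ = np.histogram(mids, bins=edges)
    if counts.sum() == 0:
        return edges, counts, np.nan
    k = int(np.argmax(counts))
    return edges, counts, float((edges[k] + edges[k + 1]) / 2)


def trajectories_to_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Delimited-polyline export: id, t_ms, x, y, z (mm)."""
    rows = []
    for i, tr in enumerate(trajectories):
        for t, p in zip(tr.times_ms, tr.points):
            rows.append((i, t, p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=["id", "t_ms", "x", "y", "z"])


def trajectories_to_vtk(trajectories: list[Trajectory], path) -> None:
    """3D polylines as VTK legacy ASCII (POLYDATA/LINES) with a per-point
    time scalar, for visualization."""
    pts = np.concatenate([tr.points for tr in trajectories])
    times = np.concatenate([tr.times_ms for tr in trajectories])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("activity trajectories (mm, ms)\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        np.savetxt(fh, pts, fmt="%.6g")
        sizes = [len(tr.points) for tr in trajectories]
        fh.write(f"LINES {len(sizes)} {sum(sizes) + len(sizes)}\n")
        off = 0
        for n in sizes:
            fh.write(" ".join(map(str, [n, *range(off, off + n)])) + "\n")
            off += n
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS time_ms double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, times, fmt="%.6g")
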