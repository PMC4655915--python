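"""Synthetic phantoms and fixtures: every pipeline stage is testable
without animal data.

The activity phantom is an analytic spatiotemporal conductivity-increase
field emulating the evoked response of whisker barrel cortex: onset in
layer IV (default 790 um depth, 8 ms post-stimulus), spread downward into
infragranular layers after 1.5 ms and upward toward layer I after 3.5 ms,
with an optional lateral lobe confined to the layer II/III band (default
400-500 um) propagating row-wise.  Every depth activates with an explicit
delay, so the field is exactly zero before its local activation time and
the true onset chronology is known in closed form for recovery tests.

Raw-recording synthesis projects the phantom through the linearized
forward model onto boundary voltages, amplitude-modulates the 1725 Hz,
50 uA carrier accordingly (continuous carrier, random phase per injection
— carrier and demodulator share a clock, as in lock-in acquisition), adds
the evoked potential and white channel noise, and organizes the result in
1 s trials (forward deflection at 0 s, backward at 0.5 s, 15 trials per
injection pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ForwardModel, InverseGrid, _MM
from .mesh import Mesh
from .reconstruction import ConductivityImage
from .signals import RawChannelRecord, TrialTimeline
from .csda import LaminarLFP


# ----------------------------------------------------------------------
# phantom

@dataclass
class ActivityPhantom:
    """Analytic dsigma(%) field with known onset chronology.

    ``element_values`` caches the field at the forward-mesh element
    centroids for each frame; :meth:`evaluate` gives the analytic field at
    arbitrary points/times (used for LFP synthesis and truth profiles).
    """

    mesh: Mesh
    frame_times_ms: np.ndarray
    element_values: np.ndarray      # (n_frames, n_elements) percent
    center_xy: np.ndarray
    onset_ms: float
    onset_depth_um: float
    peak_percent: float
    infra_delay_ms: float
    supra_delay_ms: float
    lateral_band_um: tuple[float, float]
    lateral_fraction: float
    params: dict = field(default_factory=dict)

    def evaluate(self, points_mm: np.ndarray, t_ms: float) -> np.ndarray:
        return _phantom_field(points_mm, t_ms, self)

    def activation_delay_ms(self, z_mm: np.ndarray) -> np.ndarray:
        return _activation_delay(np.asarray(z_mm), self)

    def truth_image(self, grid: InverseGrid) -> ConductivityImage:
        """Phantom rasterized on an inverse grid (volume-weighted)."""
        import scipy.sparse as sp
        vox = grid.point_to_voxel(self.mesh.element_centroids)
        ok = vox >= 0
        vol = self.mesh.element_volumes
        P = sp.csr_matrix((vol[ok], (vox[ok], np.flatnonzero(ok))),
                          shape=(grid.n_voxels, self.mesh.n_elements))
        vv = np.asarray(P.sum(axis=1)).ravel()
        frames = np.stack([
            np.where(vv > 0, P @ f / np.maximum(vv, 1e-300), 0.0)
            for f in self.element_values])
        return ConductivityImage(frames.reshape(-1, *grid.shape),
                                 self.frame_times_ms, grid)


def _activation_delay(z_mm: np.ndarray, ph: "ActivityPhantom") -> np.ndarray:
    """Delay (ms) after the phantom onset at which depth z activates."""
    p = ph.params
    z0 = ph.onset_depth_um / 1000.0
    upper = p["depth_upper_um"] / 1000.0
    lower = p["depth_lower_um"] / 1000.0
    delay = np.zeros_like(z_mm, dtype=float)
    above = z_mm < z0
    below = z_mm > z0
    delay[above] = ph.supra_delay_ms * np.clip(
        (z0 - z_mm[above]) / max(z0 - upper, 1e-9), 0, None)
    delay[below] = ph.infra_delay_ms * np.clip(
        (z_mm[below] - z0) / max(lower - z0, 1e-9), 0, None)
    return delay


def _envelope(u_ms: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Smooth rise/decay envelope; exactly zero for u < 0."""
    u = np.asarray(u_ms, dtype=float)
    out = np.zeros_like(u)
    r = (u >= 0) & (u < rise_ms)
    out[r] = np.sin(np.pi * u[r] / (2 * rise_ms)) ** 2
    d = (u >= rise_ms) & (u < rise_ms + decay_ms)
    out[d] = np.cos(np.pi * (u[d] - rise_ms) / (2 * decay_ms)) ** 2
    return out


def _phantom_field(points_mm: np.ndarray, t_ms: float, ph: "ActivityPhantom") -> np.ndarray:
    pts = np.atleast_2d(points_mm)
    p = ph.params
    x0, y0 = ph.center_xy
    z = pts[:, 2]
    u = t_ms - ph.onset_ms - _activation_delay(z, ph)
    tempo = _envelope(u, p["rise_ms"], p["decay_ms"])
    lat2 = ((pts[:, 0] - x0) ** 2 + (pts[:, 1] - y0) ** 2)
    g_xy = np.exp(-lat2 / (2 * p["sigma_xy_mm"] ** 2))
    # depth reach: inside [upper, lower] with soft Gaussian shoulders
    upper = p["depth_upper_um"] / 1000.0
    lower = p["depth_lower_um"] / 1000.0
    sz = p["sigma_z_mm"]
    reach = np.ones_like(z)
    reach = np.where(z < upper, np.exp(-((z - upper) / sz) ** 2 / 2), reach)
    reach = np.where(z > lower, np.exp(-((z - lower) / sz) ** 2 / 2), reach)
    out = ph.peak_percent * tempo * g_xy * reach
    # lateral lobe: row-wise (x) moving blob confined to the II/III band
    if ph.lateral_fraction > 0:
        b0, b1 = ph.lateral_band_um[0] / 1000.0, ph.lateral_band_um[1] / 1000.0
        zc, zw = (b0 + b1) / 2, (b1 - b0) / 2
        band = np.exp(-((z - zc) / max(zw, 1e-9)) ** 2 / 2)
        t_lat = t_ms - ph.onset_ms - _activation_delay(np.array([zc]), ph)[0]
        if t_lat > 0:
            shift = p["lateral_speed_mm_ms"] * t_lat
            g_lat = np.exp(-(((pts[:, 0] - x0 - shift) ** 2
                              + (pts[:, 1] - y0) ** 2)
                             / (2 * p["sigma_xy_mm"] ** 2)))
            tempo_lat = _envelope(np.full_like(z, t_lat), p["rise_ms"],
                                  p["decay_ms"])
            out = out + (ph.peak_percent * ph.lateral_fraction
                         * tempo_lat * band * g_lat)
    return out


def make_activity_phantom(
    mesh: Mesh,
    center_xy=None,
    onset_ms: float = 8.0,
    onset_depth_um: float = 790.0,
    peak_percent: float = 0.05,
    infra_delay_ms: float = 1.5,
    supra_delay_ms: float = 3.5,
    lateral_band_um: tuple[float, float] = (400.0, 500.0),
    lateral_fraction: float = 0.5,
    lateral_speed_mm_ms: float = 0.25,
    sigma_xy_mm: float = 0.4,
    sigma_z_mm: float = 0.1,
    depth_upper_um: float = 150.0,
    depth_lower_um: float = 1500.0,
    rise_ms: float = 3.0,
    decay_ms: float = 6.0,
    frame_times_ms=None,
) -> ActivityPhantom:
    """Build the default evoked-activity phantom on a forward mesh.

    Defaults mirror the imaged physiology: onset 8 ms post-stimulus at
    790 um (layer IV), peak amplitude 0.05% conductivity increase, spread
    to layer VI over 1.5 ms and toward layer I over 3.5 ms, lateral
    spread confined to 400-500 um (layers II/III).
    """
    lo, hi = mesh.bounding_box
    if not (lo[2] <= onset_depth_um / 1000.0 <= hi[2]):
        raise ValueError("onset depth lies outside the mesh depth range")
    if depth_lower_um / 1000.0 > hi[2] + 0.5:
        raise ValueError("phantom depth band extends outside the mesh")
    if center_xy is None:
        center_xy = (lo[:2] + hi[:2]) / 2
    if frame_times_ms is None:
        frame_times_ms = np.arange(0.0, 31.0, 1.0)
    ph = ActivityPhantom(
        mesh=mesh, frame_times_ms=np.asarray(frame_times_ms, dtype=float),
        element_values=np.empty(0), center_xy=np.asarray(center_xy, dtype=float),
        onset_ms=onset_ms, onset_depth_um=onset_depth_um,
        peak_percent=peak_percent, infra_delay_ms=infra_delay_ms,
        supra_delay_ms=supra_delay_ms, lateral_band_um=tuple(lateral_band_um),
        lateral_fraction=lateral_fraction,
        params=dict(rise_ms=rise_ms, decay_ms=decay_ms,
                    sigma_xy_mm=sigma_xy_mm, sigma_z_mm=sigma_z_mm,
                    depth_upper_um=depth_upper_um, depth_lower_um=depth_lower_um,
                    lateral_speed_mm_ms=lateral_speed_mm_ms))
    cent = mesh.element_centroids
    ph.element_values = np.stack([_phantom_field(cent, t, ph)
                                  for t in ph.frame_times_ms])
    return ph


# ----------------------------------------------------------------------
# raw boundary-voltage synthesis

def _synthetic_ep_waveform(t_s: np.ndarray, fs: float) -> np.ndarray:
    """Causal band-limited evoked potential: Gamma-envelope 80 Hz
    oscillation peaking ~9 ms post-stimulus.  The envelope has third-order
    contact with zero at onset, so its spectrum decays as f^-4 and the
    leak into the carrier band is negligible, as for physiological EPs."""
    tau = 0.003
    u = np.maximum(t_s, 0.0) / tau
    env = (u ** 3) * np.exp(3.0 - u) / 27.0
    return np.where(t_s > 0, env * np.sin(2 * np.pi * 80 * t_s), 0.0)


def synthesize_raw_recordings(
    phantom: ActivityPhantom,
    model: ForwardModel,
    protocol,
    timeline: TrialTimeline | None = None,
    noise_sd_v: float | str = "auto",
    seed: int | None = 0,
    backward_scale: float = 0.8,
    ep_amplitude_v: float = 200e-6,
) -> list[RawChannelRecord]:
    """Carrier-modulated raw records, one per injection pair.

    Boundary-voltage changes are the phantom projected through the
    linearized (adjoint) sensitivity of each pair; the carrier is
    continuous at the protocol frequency with a random phase per
    injection; the backward-deflection response is a scaled copy of the
    forward one (forward is the preferred direction); white Gaussian
    channel noise is added.  ``noise_sd_v="auto"`` picks the noise so the
    trial-averaged interstimulus dZ SD is about one third of the median
    responder peak |dZ| — exercising the 3 x SD rules meaningfully.
    """
    timeline = timeline or TrialTimeline()
    if model.mesh is not phantom.mesh:
        if model.mesh.n_elements != phantom.mesh.n_elements:
            raise ValueError("phantom and forward model use different meshes")
    rng = np.random.default_rng(seed)
    fs = 8000.0
    L = timeline.n_samples(fs)
    n_tr = timeline.n_trials
    t_trial = np.arange(L) / fs

    # absolute per-element conductivity change per frame, S/m
    dsig_abs = phantom.element_values / 100.0 * model.mesh.conductivity[None, :]
    cur = protocol.amplitude_ua * 1e-6
    vol = model.mesh.element_volumes
    G = {e: model.element_gradients(model.lead_fields[e])
         for e in range(model.array.n_electrodes)}

    # per-pair channel responses at frame times
    records = []
    frame_of_sample: dict[int, np.ndarray] = {}
    for d in timeline.deflections_s:
        rel = (t_trial - d) * 1000.0
        idx = np.searchsorted(phantom.frame_times_ms, rel + 1e-9) - 1
        ok = (rel >= phantom.frame_times_ms[0]) & (rel <= phantom.frame_times_ms[-1] + 1.0)
        frame_of_sample[int(d * fs)] = (idx, ok)

    peak_ratios = []
    pair_data = []
    for k, (a, b) in enumerate(protocol.pairs):
        meas = np.array([m for m in range(model.array.n_electrodes)
                         if m not in (a, b)])
        v0 = model.solve((a, b), protocol.amplitude_ua).electrode_voltages[meas]
        gab = G[a] - G[b]
        S = np.stack([-(_MM * cur) * ((G[m] * gab).sum(axis=1) * vol)
                      for m in meas])                     # (n_meas, n_elem)
        dv_frames = S @ dsig_abs.T                        # (n_meas, n_frames)
        amp = np.repeat(v0[:, None], L, axis=1)
        for d in timeline.deflections_s:
            scale = 1.0 if d == timeline.deflections_s[0] else backward_scale
            idx, ok = frame_of_sample[int(d * fs)]
            add = np.where(ok[None, :], dv_frames[:, np.clip(idx, 0, None)], 0.0)
            amp += scale * add
        peak_ratios.append(np.abs(dv_frames / v0[:, None]).max(axis=1))
        pair_data.append((meas, v0, amp))

    if noise_sd_v == "auto":
        pk = np.concatenate(peak_ratios)
        responders = pk[pk >= np.quantile(pk, 0.8)]
        target_frac = np.median(responders) / 3.0       # envelope SD target
        v0_all = np.concatenate([np.abs(v0) for _, v0, _ in pair_data])
        # envelope noise ~ sd * sqrt(2 bw / nyq) / sqrt(n_trials)
        bw_factor = np.sqrt(2 * 500.0 / (fs / 2)) / np.sqrt(n_tr)
        noise_sd_v = float(target_frac * np.median(v0_all) / bw_factor)

    f = protocol.carrier_hz
    t_full = np.arange(L * n_tr) / fs
    for k, (meas, v0, amp) in enumerate(pair_data):
        phase = rng.uniform(0, 2 * np.pi)
        ep = ep_amplitude_v * sum(
            np.roll(_synthetic_ep_waveform(t_trial, fs), int(d * fs))
            for d in timeline.deflections_s)
        carrier = np.sin(2 * np.pi * f * t_full + phase)
        sigl = np.tile(amp, (1, n_tr)) * carrier[None, :]
        sigl += np.tile(ep, n_tr)[None, :]
        sigl += rng.normal(0.0, noise_sd_v, sigl.shape)
        records.append(RawChannelRecord(
            sigl, fs, f, timeline,
            channel_electrodes=meas, pair=protocol.pairs[k]))
    return records


# ----------------------------------------------------------------------
# laminar LFP synthesis

def synthesize_lfp_from_phantom(
    phantom: ActivityPhantom,
    probe_xy=None,
    n_contacts: int = 16,
    pitch_um: float = 100.0,
    csd_amplitude: float = 4.3,
    noise_sd: float = 0.02,
    seed: int | None = 0,
    timeline: TrialTimeline | None = None,
    fs: float = 8000.0,
    sigma_t_s_m: float = 0.3,
) -> tuple[LaminarLFP, np.ndarray, np.ndarray]:
    """Laminar LFP whose underlying CSD follows the phantom chronology.

    The target CSD on a 50 um grid is the time derivative of the phantom
    field along the probe, scaled to ``csd_amplitude`` (units of the CSD
    map).  The LFP is obtained by integrating d2V/dz2 = -CSD/sigma_t twice
    in depth with V = 0 at both probe ends, sampled at the 16 contacts,
    tiled over trials with additive white noise.

    Returns ``(lfp, true_csd_grid, true_csd)`` for round-trip tests.
    """
    if probe_xy is None:
        probe_xy = phantom.center_xy
    tl = timeline or TrialTimeline()
    rng = np.random.default_rng(seed)
    span = n_contacts * pitch_um            # nominal coverage, um
    # integrate over a domain extended well past the probe so the probe
    # samples volume-conduction-consistent potentials: clamping V = 0 at
    # the probe ends themselves would inject spurious edge curvature
    # (hence spurious edge sources) that real recordings do not have
    pad_mm = 0.25
    zext = np.arange(-pad_mm, span / 1000.0 + pad_mm + 1e-9, 0.05)
    pts = np.column_stack([np.full_like(zext, probe_xy[0]),
                           np.full_like(zext, probe_xy[1]), zext])
    L = tl.n_samples(fs)
    t_trial = np.arange(L) / fs

    # analytic phantom profile along the probe, per sample, both deflections
    prof = np.zeros((len(zext), L))
    for d in tl.deflections_s:
        rel = (t_trial - d) * 1000.0
        sel = np.flatnonzero((rel >= -1) & (rel <= 35))
        for j in sel:
            prof[:, j] += phantom.evaluate(pts, rel[j])
    dcsd = np.gradient(prof, axis=1) * fs / 1000.0      # d/dt, per ms
    peak = np.abs(dcsd).max()
    csd_ext = dcsd / peak * csd_amplitude if peak > 0 else dcsd

    # integrate -CSD/sigma twice in z (mm), zero potential at the far
    # (extended) boundaries
    h = 0.05
    rhs = -csd_ext / sigma_t_s_m * h
    v1 = np.vstack([np.zeros_like(rhs[:1]),
                    np.cumsum((rhs[:-1] + rhs[1:]) / 2, axis=0)]) * h
    v = np.cumsum(np.vstack([np.zeros_like(v1[:1]), (v1[:-1] + v1[1:]) / 2]),
                  axis=0)
    z = np.arange(len(zext))[:, None]
    v = v - v[:1] - (v[-1:] - v[:1]) * z / (len(zext) - 1)

    on_probe = (zext >= -1e-9) & (zext < span / 1000.0 - 1e-9)
    zgrid = zext[on_probe]
    true_csd = csd_ext[on_probe]

    depths = (np.arange(n_contacts) + 0.5) * pitch_um / 1000.0  # contact mm
    contact_v = np.empty((n_contacts, L))
    for j in range(L):
        contact_v[:, j] = np.interp(depths, zext, v[:, j])
    data = np.tile(contact_v, (1, tl.n_trials))
    data += rng.normal(0.0, noise_sd * np.abs(contact_v).max() + 1e-300,
                       data.shape)
    lfp = LaminarLFP(data, depths * 1000.0, fs, tl, tl.n_trials)
    return lfp, zgrid * 1000.0, true_csd
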