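"""Time-difference Tikhonov image reconstruction and population statistics.

Per 1 ms time step the real-component boundary-voltage differences (vs the
interstimulus baseline) over QC-retained channels are inverted through the
linearized sensitivity matrix with zeroth-order Tikhonov regularization and
a noise-based correction: rows are weighted by inverse channel noise SD and
the regularization parameter is chosen by the discrepancy principle (the
weighted residual norm equals sqrt(channel count), i.e. the residual is
consistent with the measured noise).  Images are expressed as per-voxel
conductivity change in percent of the background (dsigma %), conductivity
increase positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .forward import InverseGrid, SensitivityMatrix
from .signals import DemodulatedRecord, QCMask


@dataclass
class ConductivityImage:
    """4D dsigma(%) image: (n_times, nx, ny, nz) on an inverse grid."""

    values: np.ndarray
    times_ms: np.ndarray
    grid: InverseGrid
    lam: float | None = None   # regularization parameter actually used

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("conductivity image contains non-finite values")

    @property
    def n_times(self) -> int:
        return len(self.times_ms)

    def frame(self, t_ms: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times_ms - t_ms)))
        return self.values[i]

    def peak_map(self, sign: int = 0) -> np.ndarray:
        """Per-voxel peak dsigma over time (signed value of largest |dsigma|,
        or restricted to one sign)."""
        v = self.values
        if sign > 0:
            return v.max(axis=0)
        if sign < 0:
            return v.min(axis=0)
        idx = np.abs(v).argmax(axis=0)
        return np.take_along_axis(v, idx[None], axis=0)[0]

    def to_nifti(self, path) -> None:
        import nibabel as nib
        data = np.moveaxis(self.values, 0, -1)  # x,y,z,t
        img = nib.Nifti1Image(data.astype(np.float32), self.grid.affine)
        img.header.set_xyzt_units("mm", "msec")
        nib.save(img, str(path))


# ----------------------------------------------------------------------
# difference data

@dataclass
class DifferenceData:
    """Per-timestep real-component voltage differences over retained channels."""

    matrix: np.ndarray        # (n_times, n_retained) volts
    times_ms: np.ndarray
    channel_index: np.ndarray  # indices into the Jacobian's channel rows
    noise_sd_v: np.ndarray     # per retained channel


def baseline_signs(model, protocol) -> np.ndarray:
    """Forward-model polarity of every protocol channel's baseline voltage.

    Lock-in demodulation recovers the carrier amplitude only up to sign
    (the phase is known modulo pi without the source's phase reference), so
    channels whose baseline transfer impedance is negative would report a
    sign-flipped voltage difference.  The forward model predicts the
    baseline polarity; multiplying the measured differences by it restores
    the sign convention of the sensitivity matrix.
    """
    signs = []
    for a, b in protocol.pairs:
        v0 = model.solve((a, b), protocol.amplitude_ua).measured()
        signs.append(np.sign(v0))
    return np.concatenate(signs)


def assemble_difference_data(
    records: list[DemodulatedRecord],
    mask: QCMask,
    deflection: int = 0,
    t_start_ms: float = 0.0,
    t_stop_ms: float = 30.0,
    step_ms: float = 1.0,
    channel_signs: np.ndarray | None = None,
) -> DifferenceData:
    """Stack per-injection records into reconstruction-ready data vectors.

    ``records`` must be ordered as the protocol pairs (one per injection);
    their channels concatenate to the Jacobian's row order.  For each time
    step the real component of the carrier-amplitude difference vs baseline
    is averaged within the 1 ms bin.  Channel noise SD (volts) is the SD of
    the same quantity over the interstimulus window.  ``channel_signs``
    (see :func:`baseline_signs`) restores baseline polarity lost in
    magnitude demodulation.
    """
    if not records:
        raise ValueError("no demodulated records supplied")
    fs = records[0].fs
    tl = records[0].timeline
    d0 = tl.deflections_s[deflection]
    diffs = np.vstack([r.real_difference_v() for r in records])
    if channel_signs is not None:
        diffs = diffs * np.asarray(channel_signs)[:, None]
    keep = mask.retained
    if keep.sum() == 0:
        raise ValueError("all channels rejected by QC: nothing to reconstruct")
    if len(keep) != diffs.shape[0]:
        raise ValueError("QC mask length does not match channel count")
    diffs = diffs[keep]
    # channel noise at the reconstruction's own time resolution: bin the
    # interstimulus window exactly like the response data (1 ms means)
    ismask = tl.interstim_mask(fs)
    bin_n = max(1, int(round(step_ms / 1000.0 * fs)))
    inter = diffs[:, ismask]
    nbins = inter.shape[1] // bin_n
    binned = inter[:, :nbins * bin_n].reshape(diffs.shape[0], nbins, bin_n).mean(axis=2)
    noise = binned.std(axis=1, ddof=1)

    times = np.arange(t_start_ms, t_stop_ms + 1e-9, step_ms)
    out = np.empty((len(times), diffs.shape[0]))
    for i, tms in enumerate(times):
        s0 = int(round((d0 + tms / 1000.0) * fs))
        s1 = max(s0 + 1, int(round((d0 + (tms + step_ms) / 1000.0) * fs)))
        out[i] = diffs[:, s0:s1].mean(axis=1)
    return DifferenceData(out, times, np.flatnonzero(keep), noise)


# ----------------------------------------------------------------------
# Tikhonov solver

class TikhonovSolver:
    """Noise-weighted zeroth-order Tikhonov inversion of a fixed Jacobian.

    Precomputes the SVD of the weighted Jacobian so that solving for many
    data vectors / regularization parameters is cheap.  ``jac_rows`` maps
    voxel dsigma in % to channel volts (use
    :meth:`SensitivityMatrix.percent_scaled` plus row selection).
    """

    def __init__(self, jac_rows: np.ndarray, noise_sd_v: np.ndarray | None,
                 column_normalize: bool = True, depth_floor: float = 0.02):
        m = jac_rows.shape[0]
        if noise_sd_v is None:
            w = np.ones(m)
        else:
            noise_sd_v = np.asarray(noise_sd_v, dtype=float)
            if (noise_sd_v <= 0).any():
                warnings.warn("zero channel-noise SD: weighting disabled")
                w = np.ones(m)
            else:
                w = 1.0 / noise_sd_v
        self.w = w
        wj = jac_rows * w[:, None]
        if column_normalize:
            # sensitivity normalization: equalizes voxel sensitivity so the
            # minimum-norm solution is not drawn toward the electrodes.
            # The floor caps the boost of near-invisible voxels (far
            # corners), which would otherwise amplify noise unboundedly.
            c = np.linalg.norm(wj, axis=0)
            nz = c > 0
            if nz.any():
                c = np.maximum(c, depth_floor * c[nz].max())
            c[~nz] = np.inf
        else:
            c = np.ones(wj.shape[1])
        self.col_scale = c
        self.U, self.s, self.Vt = np.linalg.svd(wj / c[None, :],
                                                full_matrices=False)

    def solve(self, data_v: np.ndarray, lam: float | str = "auto") -> np.ndarray:
        """dsigma(%) voxel vector for one data vector (volts)."""
        b = self.U.T @ (self.w * data_v)
        if isinstance(lam, str):
            lam = self.discrepancy_lambda(data_v)
        f = self.s / (self.s ** 2 + lam)
        return (self.Vt.T @ (f * b)) / self.col_scale

    def residual_norm(self, data_v: np.ndarray, lam: float) -> float:
        wd = self.w * data_v
        b = self.U.T @ wd
        perp2 = float(wd @ wd - b @ b)
        r2 = float(((lam / (self.s ** 2 + lam)) ** 2 * b ** 2).sum()) + max(perp2, 0.0)
        return np.sqrt(r2)

    def discrepancy_lambda(self, data_v: np.ndarray, tau: float = 1.05) -> float:
        """lambda such that the weighted residual ~ tau sqrt(m) (noise level).

        ``tau`` is the usual Morozov safety factor: slightly above 1 so
        that data indistinguishable from noise maps to the heavily
        regularized (near-zero) solution instead of being chased into the
        smallest singular values.
        """
        m = len(data_v)
        target = tau * np.sqrt(m)
        lo, hi = self.s[-1] ** 2 * 1e-8 + 1e-300, self.s[0] ** 2 * 1e8
        if self.residual_norm(data_v, lo) >= target:
            return lo  # data already consistent with noise at minimal smoothing
        if self.residual_norm(data_v, hi) <= target:
            return hi
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if self.residual_norm(data_v, mid) < target:
                lo = mid
            else:
                hi = mid
            if hi / lo < 1 + 1e-10:
                break
        return float(np.sqrt(lo * hi))


def tikhonov_reconstruct(jac: SensitivityMatrix, data_v: np.ndarray,
                         noise_sd_v: np.ndarray | None = None,
                         lam: float | str = "auto",
                         channel_index: np.ndarray | None = None) -> np.ndarray:
    """One-shot inversion: dsigma(%) per inverse-grid voxel."""
    J = jac.percent_scaled()
    if channel_index is not None:
        J = J[channel_index]
    if J.shape[0] != len(data_v):
        raise ValueError("Jacobian rows do not match data length")
    return TikhonovSolver(J, noise_sd_v).solve(np.asarray(data_v, dtype=float), lam)


def reconstruct_image(jac: SensitivityMatrix, diff: DifferenceData,
                      lam: float | str = "auto") -> ConductivityImage:
    """Invert every time step with a common regularization parameter.

    With ``lam="auto"`` the discrepancy-principle lambda is determined on
    the time step with the largest weighted data norm (the peak response)
    and reused for all frames, so the time course is not re-normalized
    frame by frame.
    """
    solver = TikhonovSolver(jac.percent_scaled()[diff.channel_index],
                            diff.noise_sd_v)
    if isinstance(lam, str):
        norms = [np.linalg.norm(solver.w * d) for d in diff.matrix]
        lam = solver.discrepancy_lambda(diff.matrix[int(np.argmax(norms))])
    frames = np.stack([solver.solve(d, lam) for d in diff.matrix])
    vols = frames.reshape(len(diff.times_ms), *jac.grid.shape)
    return ConductivityImage(vols, diff.times_ms, jac.grid, lam=float(lam))


# ----------------------------------------------------------------------
# population statistics

@dataclass
class TScoreMap:
    t: np.ndarray
    df: int
    degenerate: np.ndarray  # zero-variance voxels (t is +-inf sentinel there)


def tscore_map(images: list[ConductivityImage]) -> TScoreMap:
    """One-sample t statistic per voxel of peak dsigma across recordings."""
    if len(images) < 2:
        raise ValueError("need at least 2 recordings for a t map")
    peaks = np.stack([im.peak_map() for im in images])
    n = peaks.shape[0]
    mean = peaks.mean(axis=0)
    sd = peaks.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, np.sign(mean) * np.inf, t)
    return TScoreMap(t, n - 1, degenerate)


@dataclass
class BinomialMask:
    active: np.ndarray
    tail_p: np.ndarray
    n: int
    alpha_voxel: float


def binomial_activity_mask(flags: np.ndarray, alpha_voxel: float = 0.05,
                           p_threshold: float = 1e-4) -> BinomialMask:
    """Reproducibility mask: voxel active when the across-recording count of
    per-recording activity exceeds binomial chance.

    ``flags`` is (n_recordings, ...) boolean; under the null each recording
    flags a voxel with probability ``alpha_voxel``, so the tail probability
    of observing >= k flags among n is ``BinomTail(k; n, alpha)``; voxels
    with tail p below ``p_threshold`` (default p < 0.0001) are active.
    """
    flags = np.asarray(flags, dtype=bool)
    n = flags.shape[0]
    if n == 0:
        raise ValueError("no recordings")
    k = flags.sum(axis=0)
    tail = stats.binom.sf(k - 1, n, alpha_voxel)
    return BinomialMask(tail < p_threshold, tail, n, alpha_voxel)


def activity_flags(images: list[ConductivityImage], alpha_voxel: float = 0.05,
                   null_window_ms: tuple[float, float] = (0.0, 5.0)) -> np.ndarray:
    """Per-recording per-voxel activity flags feeding the binomial mask.

    A voxel is flagged when its peak |dsigma| over the post-null frames
    exceeds the (1 - alpha) quantile of the per-voxel peak |dsigma| within
    the recording's own pre-onset null window, so under the null the flag
    rate is approximately alpha per recording (exact when the two windows
    have equal length; the declared alpha is nominal otherwise).
    """
    out = []
    for im in images:
        sel = (im.times_ms >= null_window_ms[0]) & (im.times_ms < null_window_ms[1])
        if not sel.any() or sel.all():
            raise ValueError("null window must cover a proper subset of frames")
        null_peak = np.abs(im.values[sel]).max(axis=0)
        thr = np.quantile(null_peak.ravel(), 1 - alpha_voxel)
        resp_peak = np.abs(im.values[~sel]).max(axis=0)
        out.append(resp_peak > thr)
    return np.stack(out)


def grand_average(images: list[ConductivityImage]) -> ConductivityImage:
    """Voxelwise mean of peak-normalized recordings (each scaled to peak
    |dsigma| = 1); zero-peak recordings are excluded with a warning."""
    kept = []
    for im in images:
        peak = np.abs(im.values).max()
        if peak == 0:
            warnings.warn("recording with zero peak excluded from grand average")
            continue
        kept.append(im.values / peak)
    if not kept:
        raise ValueError("no nonzero recordings to average")
    ref = images[0]
    return ConductivityImage(np.mean(kept, axis=0), ref.times_ms, ref.grid)
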