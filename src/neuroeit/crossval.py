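"""Cross-validation of EIT images against laminar CSDA.

The comparison is made in a vertical region of interest (ROI) column at
the depth-probe location: 200 x 200 um laterally, 2 mm deep, divided into
40 layers of 50 um.  Per recording the onset time, onset depth and peak
amplitude are extracted from both modalities; onsets are correlated
(Pearson), and translaminar onset latencies — normalized to each
recording's earliest onset — are tested per depth (one-sample t vs the
earliest onset; paired t EIT vs CSDA), Bonferroni-corrected across depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .csda import OnsetProfile, detect_onsets
from .reconstruction import ConductivityImage


@dataclass
class ROIColumn:
    """Vertical ROI column: per-layer dsigma time series.

    ``values``: (n_times, n_layers) mean dsigma(%) per 50 um layer.
    """

    values: np.ndarray
    times_ms: np.ndarray
    depths_um: np.ndarray   # layer centres
    center_xy: np.ndarray


def extract_roi_column(image: ConductivityImage, center_xy,
                       lateral_mm: float = 0.2, depth_mm: float = 2.0,
                       layer_um: float = 50.0) -> ROIColumn:
    """Average voxels laterally within the column, per 50 um layer.

    The column must lie inside the image grid laterally and in depth.
    """
    g = image.grid
    cx, cy = np.asarray(center_xy, dtype=float)
    half = lateral_mm / 2
    cc = g.voxel_centers.reshape(*g.shape, 3)
    in_lat = ((np.abs(cc[..., 0] - cx) <= half + g.pitch / 2)
              & (np.abs(cc[..., 1] - cy) <= half + g.pitch / 2))
    lo, hi = g.origin, g.origin + np.array(g.shape) * g.pitch
    if not (lo[0] <= cx - half and cx + half <= hi[0]
            and lo[1] <= cy - half and cy + half <= hi[1]
            and depth_mm <= hi[2] - lo[2] + 1e-9):
        raise ValueError("ROI column extends outside the image grid")
    n_layers = int(round(depth_mm * 1000 / layer_um))
    depths = (np.arange(n_layers) + 0.5) * layer_um  # um below the surface
    out = np.zeros((image.n_times, n_layers))
    for k in range(n_layers):
        # layers (50 um) are thinner than voxels: sample the voxel slab
        # containing the layer centre, averaged laterally over the column
        zk = depths[k] / 1000.0
        iz = int(np.clip((zk - 0) // g.pitch, 0, g.shape[2] - 1))
        sel = in_lat & (np.arange(g.shape[2])[None, None, :] == iz)
        out[:, k] = image.values[:, sel].mean(axis=1)
    return ROIColumn(out, image.times_ms, depths, np.array([cx, cy]))


def roi_onset_profile(roi: ROIColumn, noise_sd: np.ndarray | float,
                      n_sd: float = 3.0) -> OnsetProfile:
    """Onset chronology of the ROI column using the 3 x interstimulus-SD
    rule (identical to the CSDA-side onset definition)."""
    sd = np.broadcast_to(np.atleast_1d(noise_sd), (roi.values.shape[1],))
    data = np.where(np.abs(roi.values.T) > n_sd * sd[:, None],
                    roi.values.T, 0.0)
    dt_ms = float(np.median(np.diff(roi.times_ms))) if len(roi.times_ms) > 1 else 1.0
    fs = 1000.0 / dt_ms
    # at the image's 1 ms frame resolution whole layer blocks tie for the
    # earliest onset; the strongest tied layer is the robust attribution
    prof = detect_onsets(data, roi.depths_um, fs, tie_rule="strongest")
    # re-reference onsets to the image time axis
    shift = roi.times_ms[0]
    prof.onset_ms += shift
    prof.peak_ms += shift
    prof.earliest_onset_ms += shift
    return prof


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pair_and_correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with two-sided p over paired recordings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def comparison_table(eit_profiles: list[OnsetProfile],
                     csd_profiles: list[OnsetProfile],
                     eit_amplitudes: np.ndarray,
                     csd_amplitudes: np.ndarray) -> pd.DataFrame:
    """Per-recording summary table (one row per recording)."""
    rows = []
    for i, (e, c) in enumerate(zip(eit_profiles, csd_profiles)):
        rows.append({
            "recording": i,
            "eit_onset_ms": e.earliest_onset_ms,
            "csda_onset_ms": c.earliest_onset_ms,
            "eit_onset_depth_um": e.earliest_depth_um,
            "csda_onset_depth_um": c.earliest_depth_um,
            "eit_amplitude_percent": eit_amplitudes[i],
            "csda_amplitude": csd_amplitudes[i],
        })
    return pd.DataFrame(rows)


@dataclass
class TranslaminarResult:
    depths_um: np.ndarray
    eit_mean_latency_ms: np.ndarray
    csd_mean_latency_ms: np.ndarray
    p_eit_vs_earliest: np.ndarray
    p_csd_vs_earliest: np.ndarray
    p_paired: np.ndarray
    significant_paired: np.ndarray
    alpha_corrected: float
    n_excluded: np.ndarray    # per depth, pairs dropped for sentinel onsets


def translaminar_latency_analysis(
    eit: list[OnsetProfile], csd: list[OnsetProfile],
    family_alpha: float = 0.05) -> TranslaminarResult:
    """Per-depth latency statistics, Bonferroni-corrected across depths.

    Onsets are normalized within each recording to its earliest onset.
    Per depth: (a) two-sided one-sample t of the normalized onset against
    zero (difference from the earliest onset), for each modality; (b) a
    paired t-test EIT vs CSDA.  Depths with sentinel (NaN) onsets are
    excluded pairwise and the exclusion count reported.
    """
    depths = eit[0].depths_um
    for p in eit + csd:
        if len(p.depths_um) != len(depths) or not np.allclose(p.depths_um, depths):
            raise ValueError("onset profiles are on unmatched depth grids")
    E = np.stack([p.normalized_onsets() for p in eit])   # (n_rec, n_depth)
    C = np.stack([p.normalized_onsets() for p in csd])
    m = len(depths)
    alpha = family_alpha / m

    def one_sample(A):
        out = np.full(m, np.nan)
        for d in range(m):
            v = A[:, d][np.isfinite(A[:, d])]
            if len(v) >= 2 and v.std(ddof=1) > 0:
                out[d] = stats.ttest_1samp(v, 0.0).pvalue
            elif len(v) >= 2 and np.allclose(v, 0):
                out[d] = 1.0
        return out

    p_e = one_sample(E)
    p_c = one_sample(C)
    p_pair = np.full(m, np.nan)
    n_excl = np.zeros(m, dtype=int)
    for d in range(m):
        ok = np.isfinite(E[:, d]) & np.isfinite(C[:, d])
        n_excl[d] = (~ok).sum()
        e, c = E[ok, d], C[ok, d]
        if len(e) >= 2:
            diff = e - c
            if diff.std(ddof=1) > 0:
                p_pair[d] = stats.ttest_rel(e, c).pvalue
            else:
                p_pair[d] = 1.0 if np.allclose(diff, 0) else 0.0
    with np.errstate(invalid="ignore"):
        sig = p_pair < alpha
    return TranslaminarResult(
        depths_um=depths,
        eit_mean_latency_ms=np.nanmean(E, axis=0),
        csd_mean_latency_ms=np.nanmean(C, axis=0),
        p_eit_vs_earliest=p_e, p_csd_vs_earliest=p_c, p_paired=p_pair,
        significant_paired=np.where(np.isfinite(p_pair), sig, False),
        alpha_corrected=alpha, n_excluded=n_excl)
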