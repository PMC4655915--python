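"""Signal chain: carrier recordings -> evoked potentials, dZ(t), channel QC.

The acquisition scheme records, on every non-injecting electrode, the sum of
a 1725 Hz, 50 uA carrier (whose amplitude is the channel's transfer
impedance, amplitude-modulated by the evoked impedance change of order
0.01-0.1 %) and the low-frequency evoked potential.  The two are separated
in frequency: a zero-phase low-pass at 400 Hz yields the EP, and quadrature
(lock-in) demodulation in a +-500 Hz band around the carrier yields the
complex carrier amplitude, hence dZ(t), with 2 ms time resolution.

All filters are zero-phase FIR (``filtfilt`` over a ``firwin`` design), so
onset latencies are not biased by filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import signal as sps


# ----------------------------------------------------------------------
# trial structure

@dataclass
class TrialTimeline:
    """Stimulation timeline of one trial.

    Default: 1 s trials, forward whisker deflection at 0 s, backward at
    0.5 s, 15 trials per injection pair.  The interstimulus window of each
    half-trial (used for baselines and noise SDs) starts ``interstim_start_s``
    after the deflection and ends just before the next one.
    """

    trial_s: float = 1.0
    deflections_s: tuple[float, ...] = (0.0, 0.5)
    n_trials: int = 15
    interstim_start_s: float = 0.3
    interstim_guard_s: float = 0.02
    response_s: float = 0.030  # imaged response window after each deflection

    def __post_init__(self):
        d = np.asarray(self.deflections_s)
        if (np.diff(np.append(d, self.trial_s)) <= self.interstim_start_s).any():
            raise ValueError("interstimulus window is empty: deflections too close")

    def n_samples(self, fs: float) -> int:
        return int(round(self.trial_s * fs))

    def interstim_mask(self, fs: float) -> np.ndarray:
        """Boolean mask over one trial marking interstimulus samples."""
        n = self.n_samples(fs)
        t = np.arange(n) / fs
        mask = np.zeros(n, dtype=bool)
        ends = list(self.deflections_s[1:]) + [self.trial_s]
        for d, e in zip(self.deflections_s, ends):
            mask |= (t >= d + self.interstim_start_s) & (t < e - self.interstim_guard_s)
        if not mask.any():
            raise ValueError("interstimulus mask is empty")
        return mask

    def response_mask(self, fs: float, deflection: int = 0) -> np.ndarray:
        n = self.n_samples(fs)
        t = np.arange(n) / fs
        d = self.deflections_s[deflection]
        return (t >= d) & (t < d + self.response_s)


@dataclass
class RawChannelRecord:
    """Multichannel raw boundary-voltage recording for one injection pair."""

    data: np.ndarray           # (n_channels, n_samples) volts
    fs: float                  # Hz
    carrier_hz: float
    timeline: TrialTimeline
    trial_starts: np.ndarray | None = None  # sample index of each trial
    channel_electrodes: np.ndarray | None = None
    pair: tuple[int, int] | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.trial_starts is None:
            L = self.timeline.n_samples(self.fs)
            n = self.data.shape[1] // L
            self.trial_starts = np.arange(n) * L
        self.trial_starts = np.asarray(self.trial_starts, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def trials(self, x: np.ndarray | None = None) -> np.ndarray:
        """(n_trials, n_channels, trial_len) view of ``x`` (default raw data)."""
        x = self.data if x is None else np.atleast_2d(x)
        L = self.timeline.n_samples(self.fs)
        return np.stack([x[:, s:s + L] for s in self.trial_starts])


# ----------------------------------------------------------------------
# filters

def _zero_phase(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering with periodic (wrap) edge padding.

    Trial-structured records are periodic by construction (integer carrier
    cycles and one stimulation cycle per trial), so periodic extension is
    the natural boundary rule and leaves no settle transient at the record
    edges — unlike reflection, which kinks the carrier.  With periodic
    boundaries, forward-backward filtering is exactly multiplication by
    |H(f)|^2 in the frequency domain, which is how it is evaluated here
    (O(N log N) instead of O(N x taps)).
    """
    from scipy.fft import irfft, next_fast_len, rfft

    x = np.atleast_2d(x)
    n = x.shape[-1]
    pad = min(3 * len(taps), n)
    # grow the wrap padding to an FFT-friendly length (still periodic)
    m = next_fast_len(n + 2 * pad)
    pl = (m - n) // 2
    pr = m - n - pl
    xp = np.concatenate([x[..., n - pl:], x, x[..., :pr]], axis=-1)
    H = rfft(taps, n=m)
    y = irfft(rfft(xp, axis=-1) * (H * H.conj()).real, n=m, axis=-1)
    return y[..., pl:pl + n]


def _fir_lowpass(x: np.ndarray, cutoff_hz: float, fs: float,
                 numtaps: int | None = None) -> np.ndarray:
    if numtaps is None:
        numtaps = int(6 * fs / cutoff_hz) | 1  # transition ~ cutoff/2
    return _zero_phase(sps.firwin(numtaps, cutoff_hz, fs=fs), x)


def _fir_bandpass(x: np.ndarray, lo_hz: float, hi_hz: float, fs: float,
                  numtaps: int = 401) -> np.ndarray:
    return _zero_phase(sps.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False, fs=fs), x)


def extract_ep(raw: RawChannelRecord, cutoff_hz: float = 400.0) -> np.ndarray:
    """Trial-averaged evoked potentials: zero-phase low-pass then average.

    Returns (n_channels, trial_len) volts.  The carrier lies far above the
    passband and is suppressed by > 40 dB (squared FIR stopband).
    """
    if raw.fs < 2 * cutoff_hz:
        raise ValueError("sampling rate below Nyquist for the EP passband")
    if len(raw.trial_starts) < 2:
        import warnings
        warnings.warn("fewer than 2 trials: EP average degenerates to one trial")
    lp = _fir_lowpass(raw.data, cutoff_hz, raw.fs)
    return raw.trials(lp).mean(axis=0)


def demodulate(raw: RawChannelRecord, carrier_hz: float | None = None,
               bandwidth_hz: float = 500.0) -> np.ndarray:
    """Quadrature (lock-in) demodulation of the carrier amplitude.

    Band-pass at carrier +- bandwidth, multiply by the complex reference
    ``2 exp(-i 2 pi f t)`` and zero-phase low-pass at ``bandwidth_hz``.
    Returns the complex carrier amplitude (n_channels, n_samples), volts:
    ``|z|`` is the instantaneous carrier amplitude, ``arg z`` its phase.
    The +-500 Hz default gives 2 ms time resolution (reciprocal of the
    one-sided bandwidth).  Phase-agnostic: a per-trial random carrier
    phase appears only in ``arg z``.
    """
    f = raw.carrier_hz if carrier_hz is None else carrier_hz
    if bandwidth_hz >= f:
        raise ValueError("demodulation bandwidth must be below the carrier "
                         "(otherwise the band aliases through DC)")
    if f + bandwidth_hz >= raw.fs / 2:
        raise ValueError("carrier + bandwidth exceeds Nyquist")
    x = _fir_bandpass(raw.data, f - bandwidth_hz, f + bandwidth_hz, raw.fs)
    t = np.arange(x.shape[-1]) / raw.fs
    z = x * (2.0 * np.exp(-2j * np.pi * f * t))[None, :]
    zi = _fir_lowpass(z.real, bandwidth_hz, raw.fs)
    zq = _fir_lowpass(z.imag, bandwidth_hz, raw.fs)
    return zi + 1j * zq


# ----------------------------------------------------------------------
# averaging, baselining, QC

@dataclass
class DemodulatedRecord:
    """Averaged per-channel dZ(t) and EP(t) with interstimulus baseline.

    ``z`` is the trial-averaged complex carrier amplitude after aligning
    each trial to its own interstimulus phase (so per-trial random carrier
    phase averages coherently); its phase reference is therefore the
    baseline carrier phase, and the real component of ``z - baseline`` is
    the quantity used for image reconstruction.
    """

    z: np.ndarray                    # (n_channels, trial_len) complex volts
    baseline_v: np.ndarray           # (n_channels,) baseline carrier amplitude
    dz_percent: np.ndarray           # (n_channels, trial_len) % of baseline
    interstim_sd_percent: np.ndarray
    fs: float
    timeline: TrialTimeline
    ep: np.ndarray | None = None
    channel_electrodes: np.ndarray | None = None
    pair: tuple[int, int] | None = None
    baseline_phase: np.ndarray | None = None  # pre-rotation carrier phase

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]

    def real_difference_v(self) -> np.ndarray:
        """Real-component voltage difference vs baseline, volts."""
        return self.z.real - self.baseline_v[:, None]

    def peak_dz_percent(self, response_mask: np.ndarray | None = None) -> np.ndarray:
        sel = slice(None) if response_mask is None else response_mask
        return np.abs(self.dz_percent[:, sel]).max(axis=1)


def average_and_baseline(raw: RawChannelRecord, z: np.ndarray,
                         ep: np.ndarray | None = None) -> DemodulatedRecord:
    """Average demodulated trials and express dZ relative to baseline.

    Each trial is rotated by the conjugate phase of its own interstimulus
    mean before averaging (coherent averaging under per-trial random
    carrier phase); the baseline is the mean interstimulus amplitude of
    the average, and dZ(t) is expressed in % of that baseline.
    """
    zt = raw.trials(z)                         # (n_trials, n_ch, L)
    mask = raw.timeline.interstim_mask(raw.fs)
    ref = zt[:, :, mask].mean(axis=2)          # per-trial baseline phasor
    phase = ref / np.maximum(np.abs(ref), 1e-300)
    zbar = (zt * np.conj(phase)[:, :, None]).mean(axis=0)
    base = zbar[:, mask].mean(axis=1).real
    if (base <= 0).any():
        base = np.maximum(base, 1e-300)
    amp = np.abs(zbar)
    dz = (amp - base[:, None]) / base[:, None] * 100.0
    sd = dz[:, mask].std(axis=1, ddof=1)
    return DemodulatedRecord(
        z=zbar, baseline_v=base, dz_percent=dz, interstim_sd_percent=sd,
        fs=raw.fs, timeline=raw.timeline, ep=ep,
        channel_electrodes=raw.channel_electrodes, pair=raw.pair,
        baseline_phase=np.angle(ref.mean(axis=0)))


def process_raw(raw: RawChannelRecord, bandwidth_hz: float = 500.0) -> DemodulatedRecord:
    """Convenience: demodulate + EP + trial averaging for one record."""
    return average_and_baseline(raw, demodulate(raw, bandwidth_hz=bandwidth_hz),
                                ep=extract_ep(raw))


class ChannelFlag(IntEnum):
    RETAINED = 0
    LOW_VOLTAGE = 1
    HIGH_SD = 2


@dataclass
class QCMask:
    """Per-channel retain/reject flags with reason codes."""

    flags: np.ndarray            # (n_channels,) ChannelFlag values
    sd_threshold_percent: float | None = None

    @property
    def retained(self) -> np.ndarray:
        return self.flags == ChannelFlag.RETAINED

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "channel": np.arange(len(self.flags)),
            "flag": [ChannelFlag(f).name.lower() for f in self.flags],
        }).to_csv(path, index=False)


def reject_channels(
    baseline_v: np.ndarray,
    peak_dz_percent: np.ndarray,
    interstim_sd_percent: np.ndarray,
    min_baseline_v: float = 100e-6,
    responder_factor: float = 3.0,
    preserve_fraction: float = 0.9,
) -> QCMask:
    """Channel quality control.

    Channels with baseline boundary voltage below 100 uV are rejected.
    Channels whose peak |dZ| exceeds ``responder_factor`` times the average
    (across channels) interstimulus SD are "responders"; the SD rejection
    threshold is set at the ``preserve_fraction`` quantile of the
    responders' SDs, so that fraction of responders survives, and every
    channel with SD strictly above the threshold is rejected.  With no
    responders the SD rule is skipped (warning) and only the voltage floor
    applies.
    """
    baseline_v = np.asarray(baseline_v, dtype=float)
    peak = np.asarray(peak_dz_percent, dtype=float)
    sd = np.asarray(interstim_sd_percent, dtype=float)
    flags = np.full(len(baseline_v), int(ChannelFlag.RETAINED))
    flags[baseline_v < min_baseline_v] = int(ChannelFlag.LOW_VOLTAGE)

    ok = flags == int(ChannelFlag.RETAINED)
    thr = None
    mean_sd = sd[ok].mean() if ok.any() else np.nan
    responders = ok & (peak > responder_factor * mean_sd)
    if responders.any():
        n = responders.sum()
        # threshold = smallest responder SD that keeps >= preserve_fraction
        k = max(int(np.ceil(preserve_fraction * n)) - 1, 0)
        thr = float(np.sort(sd[responders])[k])
        flags[ok & (sd > thr)] = int(ChannelFlag.HIGH_SD)
    else:
        import warnings
        warnings.warn("no responder channels: SD-based rejection skipped")
    return QCMask(flags, sd_threshold_percent=thr)
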