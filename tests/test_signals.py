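"""Signal chain: EP extraction, lock-in demodulation, averaging, QC."""

import numpy as np
import pytest

from neuroeit import (RawChannelRecord, TrialTimeline, average_and_baseline,
                      demodulate, extract_ep, reject_channels)
from neuroeit.signals import ChannelFlag, _fir_lowpass

FS = 8000.0
CARRIER = 1725.0


def make_record(signal, n_trials=15, timeline=None):
    tl = timeline or TrialTimeline(n_trials=n_trials)
    return RawChannelRecord(np.atleast_2d(signal), FS, CARRIER, tl)


def carrier_record(amplitude=0.05, phase=0.0, mod=None, n_trials=15):
    tl = TrialTimeline(n_trials=n_trials)
    t = np.arange(tl.n_samples(FS) * n_trials) / FS
    m = np.ones_like(t) if mod is None else mod(t)
    return make_record(amplitude * m * np.sin(2 * np.pi * CARRIER * t + phase),
                       n_trials)


def dip_modulation(depth=5e-4, at_s=0.012, width_s=0.004):
    def mod(t):
        tt = t % 1.0
        out = np.ones_like(t)
        for d in (0.0, 0.5):
            out = out - depth * np.exp(-0.5 * ((tt - d - at_s) / width_s) ** 2)
        return out
    return mod


# ----------------------------------------------------------------------
# EP extraction

def test_pure_carrier_yields_no_ep():
    raw = carrier_record()
    ep = extract_ep(raw)
    assert np.abs(ep).max() < 0.05 * 10 ** (-40 / 20)   # < -40 dB of carrier


def test_known_waveform_recovered():
    tl = TrialTimeline()
    t = np.arange(tl.n_samples(FS) * 15) / FS
    ep_true = 1e-3 * np.sin(2 * np.pi * 50 * t)
    raw = make_record(ep_true + 0.05 * np.sin(2 * np.pi * CARRIER * t))
    ep = extract_ep(raw)
    assert np.abs(ep).max() == pytest.approx(1e-3, rel=0.02)


def test_white_noise_variance_reduced_by_filter_noise_bandwidth(rng):
    """Output/input variance of the zero-phase low-pass equals the mean of
    |H|^4 over frequency (forward-backward filtering)."""
    from scipy.signal import firwin
    x = rng.normal(0, 1.0, (1, 15 * 8000))
    y = _fir_lowpass(x, 400.0, FS)
    taps = firwin(int(6 * FS / 400) | 1, 400.0, fs=FS)
    H = np.fft.fft(taps, 1 << 18)
    expected = float(np.mean(np.abs(H) ** 4))
    assert y.var() / x.var() == pytest.approx(expected, rel=0.05)


# ----------------------------------------------------------------------
# demodulation

def test_unmodulated_carrier_constant_zero_percent():
    raw = carrier_record()
    rec = average_and_baseline(raw, demodulate(raw))
    assert np.abs(rec.dz_percent).max() < 0.02
    assert rec.baseline_v[0] == pytest.approx(0.05, rel=1e-3)


def test_dip_depth_recovered_within_5_percent():
    raw = carrier_record(mod=dip_modulation(5e-4))  # -0.05 % dip, 10 ms scale
    rec = average_and_baseline(raw, demodulate(raw))
    assert rec.dz_percent.min() == pytest.approx(-0.05, rel=0.05)


@pytest.mark.parametrize("phase", [0.0, 1.1, 2.5, 4.4])
def test_demodulation_is_phase_agnostic(phase):
    raw = carrier_record(phase=phase, mod=dip_modulation(5e-4))
    rec = average_and_baseline(raw, demodulate(raw))
    assert rec.dz_percent.min() == pytest.approx(-0.05, rel=0.05)


def test_step_response_time_resolution():
    """+-500 Hz bandwidth -> 2 ms resolution: the 10-90% envelope rise time
    does not exceed the reciprocal one-sided bandwidth."""
    tl = TrialTimeline()
    t = np.arange(tl.n_samples(FS) * 15) / FS
    step = np.where(t % 1.0 > 0.25, 1.0, 0.9)
    raw = make_record(step * np.sin(2 * np.pi * CARRIER * t))
    env = np.abs(demodulate(raw, bandwidth_hz=500.0))[0][:8000]
    seg = env[1900:2300]
    i10 = np.argmax(seg > 0.9 + 0.1 * 0.1)
    i90 = np.argmax(seg > 0.9 + 0.9 * 0.1)
    rise_ms = (i90 - i10) / FS * 1000
    assert 0.2 < rise_ms <= 2.0


@pytest.mark.parametrize("f_mod", [50.0, 120.0, 250.0])
def test_gain_flat_for_modulation_below_half_bandwidth(f_mod):
    def mod(t):
        return 1.0 - 5e-4 * 0.5 * (1 - np.cos(2 * np.pi * f_mod * t))
    raw = carrier_record(mod=mod)
    env = np.abs(demodulate(raw))[0]
    depth = (env[2000:10000].max() - env[2000:10000].min()) / env.mean()
    assert depth == pytest.approx(5e-4, rel=0.05)


def test_bandwidth_at_or_above_carrier_rejected():
    raw = carrier_record()
    with pytest.raises(ValueError):
        demodulate(raw, bandwidth_hz=CARRIER)


# ----------------------------------------------------------------------
# averaging and baselining

def test_identical_trials_average_to_single_trial():
    raw = carrier_record(mod=dip_modulation(5e-4))
    z = demodulate(raw)
    rec = average_and_baseline(raw, z)
    single = RawChannelRecord(raw.data[:, :8000], FS, CARRIER,
                              TrialTimeline(n_trials=1))
    rec1 = average_and_baseline(single, demodulate(single))
    # identical trials: average equals any one trial
    assert np.allclose(rec.dz_percent, rec1.dz_percent, atol=2e-3)


def test_interstim_sd_shrinks_with_trial_averaging(rng):
    tl = TrialTimeline()
    t = np.arange(tl.n_samples(FS) * 15) / FS
    noise = rng.normal(0, 1e-4, t.shape)
    raw = make_record(0.05 * np.sin(2 * np.pi * CARRIER * t) + noise)
    rec15 = average_and_baseline(raw, demodulate(raw))
    single = RawChannelRecord(raw.data[:, :8000], FS, CARRIER,
                              TrialTimeline(n_trials=1))
    rec1 = average_and_baseline(single, demodulate(single))
    ratio = rec1.interstim_sd_percent[0] / rec15.interstim_sd_percent[0]
    assert ratio == pytest.approx(np.sqrt(15), rel=0.35)


def test_dc_offset_leaves_dz_unchanged():
    raw = carrier_record(mod=dip_modulation(5e-4))
    rec = average_and_baseline(raw, demodulate(raw))
    shifted = make_record(raw.data[0] + 0.01)
    rec2 = average_and_baseline(shifted, demodulate(shifted))
    assert np.allclose(rec.dz_percent, rec2.dz_percent, atol=1e-4)


# ----------------------------------------------------------------------
# channel QC

def test_low_voltage_channel_rejected():
    mask = reject_channels(baseline_v=np.array([50e-6, 1e-3]),
                           peak_dz_percent=np.array([0.1, 0.1]),
                           interstim_sd_percent=np.array([0.01, 0.01]))
    assert mask.flags[0] == ChannelFlag.LOW_VOLTAGE
    assert mask.flags[1] == ChannelFlag.RETAINED


def test_exactly_90_percent_of_responders_preserved():
    """10 responders with distinct SDs -> the SD rule keeps exactly 9."""
    n = 10
    sd = np.linspace(0.01, 0.10, n)
    mask = reject_channels(baseline_v=np.full(n, 1e-3),
                           peak_dz_percent=np.full(n, 10.0),
                           interstim_sd_percent=sd)
    assert mask.retained.sum() == 9
    assert mask.flags[-1] == ChannelFlag.HIGH_SD


def test_quiet_channels_all_retained():
    n = 6
    with pytest.warns(UserWarning):
        mask = reject_channels(np.full(n, 1e-3), np.zeros(n), np.full(n, 0.01))
    assert mask.retained.all()


def test_qc_order_independent(rng):
    base = rng.uniform(5e-5, 1e-2, 40)
    peak = rng.uniform(0, 1, 40)
    sd = rng.uniform(0.001, 0.1, 40)
    mask = reject_channels(base, peak, sd)
    perm = rng.permutation(40)
    mask_p = reject_channels(base[perm], peak[perm], sd[perm])
    assert np.array_equal(mask.flags[perm], mask_p.flags)


def test_qc_mask_application_idempotent():
    mask = reject_channels(np.array([50e-6, 1e-3, 1e-3]),
                           np.array([0.0, 10.0, 10.0]),
                           np.array([0.01, 0.01, 0.02]))
    kept = mask.retained
    assert np.array_equal(kept & kept, kept)
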