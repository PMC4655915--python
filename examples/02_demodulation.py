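"""Lock-in demodulation: recover a 0.05 % impedance dip from the carrier.

Synthesizes fifteen 1 s trials of a 1725 Hz carrier whose amplitude dips
by 0.05 % for ~10 ms after each whisker deflection (forward at 0 s,
backward at 0.5 s), demodulates with the +-500 Hz quadrature scheme and
prints the recovered dZ(t).
"""

import numpy as np

from neuroeit import (RawChannelRecord, TrialTimeline, average_and_baseline,
                      demodulate, extract_ep)

fs, carrier = 8000.0, 1725.0
tl = TrialTimeline()                   # 1 s trials, deflections at 0 / 0.5 s
t = np.arange(tl.n_samples(fs) * tl.n_trials) / fs
tt = t % tl.trial_s

mod = np.ones_like(t)
for d in tl.deflections_s:             # -0.05 % amplitude dip at ~12 ms
    mod -= 5e-4 * np.exp(-0.5 * ((tt - d - 0.012) / 0.004) ** 2)
rng = np.random.default_rng(0)
signal = 0.05 * mod * np.sin(2 * np.pi * carrier * t + 0.7)
signal = signal + rng.normal(0, 2e-6, t.shape)   # 2 uV channel noise

raw = RawChannelRecord(signal[None], fs, carrier, tl)
rec = average_and_baseline(raw, demodulate(raw, bandwidth_hz=500.0),
                           ep=extract_ep(raw))

print(f"baseline carrier amplitude: {rec.baseline_v[0]*1e3:.2f} mV (true 50 mV)")
print(f"recovered dip: {rec.dz_percent.min():.4f} % (true -0.0500 %)")
print(f"interstimulus SD after 15-trial averaging: "
      f"{rec.interstim_sd_percent[0]:.5f} %")
print(f"EP leakage from the carrier band: {np.abs(rec.ep).max()*1e6:.3f} uV "
      "(carrier is 50,000 uV -> separation > 80 dB)")
# The dip depth is recovered to a few percent although the modulation is
# one part in 2000 of the carrier: this is the dynamic range the lock-in
# scheme buys.
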