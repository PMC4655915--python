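"""Laminar CSD analysis of a synthetic 16-contact LFP record.

Synthesizes an LFP whose underlying current source density follows the
phantom's laminar chronology (onset in layer IV, spread to infra- and
supragranular layers), then runs the CSDA chain: 500 Hz low-pass, trial
average, 50 um depth interpolation (32 segments), 100 um FWHM Gaussian
smoothing, second-spatial-derivative CSD, 3 x interstimulus-SD
significance and onset detection.
"""

import numpy as np

from neuroeit import (build_slab_mesh, csda_pipeline, make_activity_phantom,
                      synthesize_lfp_from_phantom)

mesh = build_slab_mesh((5, 4, 2), 0.25)
phantom = make_activity_phantom(mesh)
lfp, zgrid_um, true_csd = synthesize_lfp_from_phantom(phantom, seed=2)
print(f"LFP: {lfp.data.shape[0]} contacts at {lfp.pitch_um:.0f} um pitch, "
      f"{lfp.n_trials} trials at {lfp.fs:.0f} Hz")

csd, prof = csda_pipeline(lfp)
print(f"CSD map: {csd.data.shape[0]} depth segments "
      f"(50 um grid over the probe's nominal coverage)")

n_sig = int((csd.data != 0).any(axis=1).sum())
print(f"depths with significant sources/sinks: {n_sig}/32")
print(f"earliest CSDA onset: {prof.earliest_onset_ms:.1f} ms at "
      f"{prof.earliest_depth_um:.0f} um "
      f"(phantom truth {phantom.onset_ms} ms, {phantom.onset_depth_um} um)")

# laminar chronology: onset per depth, normalized to the earliest
norm = prof.normalized_onsets()
for d, o in zip(prof.depths_um[::4], norm[::4]):
    tag = "  (no significant response)" if np.isnan(o) else f" +{o:.1f} ms"
    print(f"  depth {d:6.0f} um:{tag}")
# Deep (infragranular) segments activate ~1.5 ms and superficial ones
# ~3.5 ms after layer IV, reproducing the constructed laminar spread.
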