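"""Localization-accuracy simulation on the two-hemisphere brain analogue.

Places 0.5 mm diameter, +1 % spherical conductivity perturbations on a
grid through a parametric two-hemisphere brain (gray 0.3 / white 0.15 /
CSF 1.75 S/m) carrying two 32-electrode epicortical arrays, simulates
difference voltages with 0.5 uV Gaussian noise, reconstructs each and
reports the centre-of-mass localization error.  Runs a reduced grid
(~3 min); increase --n via the `neuroeit resolution-map` CLI for more.
"""

from neuroeit.resolution import brain_localization_study

df, summary = brain_localization_study(seed=1, n_locations=40)

print(f"brain analogue: {summary['n_elements']} elements, "
      f"{summary['n_channels']} measurement channels")
print(f"locations: {summary['n']} (gray shell: "
      f"{int((df['label'] == 0).sum())})")
print(f"median localization error, all kept locations: "
      f"{summary['median_um']:.0f} um")
print(f"median localization error, gray shell only:   "
      f"{summary['median_gray_um']:.0f} um")
print()
print("error vs depth (median per 2 mm depth bin):")
df["zbin"] = (df.z // 2) * 2
for z, grp in df.groupby("zbin"):
    print(f"  {z:3.0f}-{z+2:.0f} mm: {grp['error_mm'].median()*1000:6.0f} um "
          f"({len(grp)} locations)")
# At this desk scale the 0.5 mm/+1% perturbation produces sub-noise
# boundary signals beyond ~1.5 mm depth with 50 uA injection, so deep
# errors are information-limited; see docs/methods.md for the analysis.
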