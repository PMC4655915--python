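# Methods

`neuroeit` implements the complete computational chain for imaging
millisecond-scale conductivity changes of neural activity with electrical
impedance tomography (EIT) on epicortical electrode arrays, together with
the laminar current-source-density (CSD) analysis used to cross-validate
such images and the simulation machinery used to characterize
localization accuracy.  All inputs are synthetic: a phantom generator
defines the study conditions, so every stage is testable without animal
data.  This note records the models, the parameters that matter, the
numerical choices, and the known limits of what the synthetic studies can
show.

## Forward model

The quasi-static forward problem is `div(sigma grad u) = 0` on a
tetrahedral mesh (P1 elements, sparse LU factorization), with point
current sources at electrode nodes and one distant boundary node held at
zero potential (the ground electrode under the nuchal skin in the
experimental preparation); all boundary voltages are reported relative to
that ground.  Units are mm / S m^-1 / A / V; the unit mismatch
contributes a single factor 1e-3 in assembly.

*Electrode model.*  Point electrodes: each 0.6 mm contact is snapped to
the nearest surface node and treated as a point.  The contact diameter is
kept as metadata.  With 0.6 mm contacts on 0.2-0.5 mm meshes, the shunt
effect of the complete electrode model is secondary to the mesh
discretization itself; plate (distributed) injection is implemented
separately for analytic benchmarks (a uniform bar matches `R = L/(sigma A)`
to machine precision, and to <1% under a graded conductivity).

*Sensitivity.*  The Jacobian uses the adjoint identity
`dV = -int grad(u_inj) . grad(u_lead) dV` per element, aggregated onto a
regular hexahedral inverse grid (0.2 mm under a planar array, 0.5 mm for
the whole brain) by volume-weighted centroid membership.  One linear
solve per electrode suffices for the whole matrix; the test suite checks
every entry family against direct perturb-and-re-solve differences (<5%)
and four-terminal reciprocity (~1e-14 relative in practice).

*Geometries.*  A rectangular cortical slab (default 7 x 5 x 2 mm, the
70 mm^3 imaging volume under the 5 x 7 mm array) and a parametric
two-hemisphere brain: ellipsoidal hemispheres (default semi-axes
6 x 4.5 x 4 mm), a gray shell of 1.5 mm at 0.3 S/m over a white core at
0.15 S/m, and CSF ventricle cavities at 1.75 S/m.  Both are produced by
Kuhn (6-tet) subdivision of a structured grid, which is conforming by
construction; the brain is the cell subset inside the ellipsoids (a
stair-step surface — adequate for the scaled simulation study, not a
substitute for an imaging-derived head model).

## Injection protocols

Two generators: the expanding spiral of adjacent pairs (ordered by
midpoint distance from the array centre; deterministic) and a
depth-distinguishability protocol.  The published description of the
latter points to an external reference, so the score is declared here:
the L1 norm of the pair's sensitivity entries restricted to a target
depth slab, per unit current — computed directly from lead fields so all
C(n,2) candidate pairs of a 30-64 electrode system can be scored in
seconds.  Selection is greedy best-score-first under the hardware
constraint that no electrode is used in two consecutive injections.
Deep target slabs select pairs with several-fold wider spacing than
surface slabs, as expected.

## Signal chain

Boundary voltages carry a 1725 Hz, 50 uA carrier whose amplitude is
modulated by the impedance change (order 0.01-0.1%), plus the evoked
potential at low frequency.  Sampling is 8 kHz; trials are 1 s (forward
deflection at 0 s, backward at 0.5 s), 15 trials per injection.

* EP: zero-phase FIR low-pass at 400 Hz, trial average.
* dZ: band-pass at carrier +-500 Hz, quadrature demodulation against
  `2 exp(-i 2 pi f t)`, zero-phase low-pass at 500 Hz.  The +-500 Hz
  bandwidth gives 2 ms time resolution (10-90% step response ~0.9 ms,
  bounded by 2 ms).  Demodulation recovers a 0.05% modulation to <1%
  relative error and is invariant to the carrier phase.
* Zero-phase filtering is evaluated as |H(f)|^2 in the frequency domain
  with periodic (wrap) edge padding.  Trial-structured records are
  periodic by construction (integer carrier cycles per trial), so this
  boundary rule leaves no settle transient at the record edges; with
  reflection padding the transient of the 50 mV carrier would be ~5% of
  the carrier and would land exactly in the first trial's response
  window.
* Averaging: each trial is rotated by the conjugate phase of its own
  interstimulus mean before averaging, so trials average coherently under
  an arbitrary (or drifting) carrier phase.  The baseline is the mean
  interstimulus amplitude; dZ is expressed in % of it; the interstimulus
  SD (in %) is stored per channel.
* Channel QC: baselines < 100 uV are rejected; channels whose peak |dZ|
  exceeds 3x the across-channel mean interstimulus SD are "responders",
  and the SD rejection threshold is placed at the 90% quantile of
  responder SDs so 90% of responders survive.  The responder criterion
  uses the magnitude of dZ; the phase is retained for reconstruction.

*Sign convention.*  Magnitude demodulation determines the carrier phase
only modulo pi, so a channel whose baseline transfer impedance is
negative would report a sign-flipped voltage difference.  The forward
model predicts each channel's baseline polarity; difference data are
multiplied by it (`baseline_signs`) before inversion.  This uses the
model only for one bit per channel.

## Image reconstruction

Time-difference imaging: for each 1 ms step in 0-30 ms the real component
of the complex carrier-amplitude difference vs baseline (averaged within
the 1 ms bin) over retained channels is inverted through the linearized
sensitivity matrix.  The regularized problem is

    min || W (J x - d) ||^2 + lambda || C x ||^2

with three "noise-based" ingredients, each declared and overridable:

1. Row weighting `W = diag(1/noise_sd)`, with the channel noise SD
   estimated from the interstimulus window *binned exactly like the
   response data* (1 ms means), so the weighted per-channel noise is
   unit-variance by construction.
2. `lambda` by the discrepancy principle: the weighted residual norm
   equals `tau sqrt(m)` with Morozov safety factor `tau = 1.05`.  With
   `tau = 1` a data vector indistinguishable from noise is chased into
   the smallest singular values and the image explodes; `tau > 1` maps it
   to the heavily regularized (near-zero) solution instead.  For a time
   series, lambda is selected on the frame with the largest weighted data
   norm (the response peak) and reused for all frames, so the time course
   is not re-normalized frame by frame.  A brute-force residual scan
   reproduces the selected lambda (test).
3. Column (sensitivity) normalization `C = diag(||column||)` with a floor
   at 2% of the largest column norm.  Without it the minimum-norm
   solution collapses onto the electrode plane and onset *depth* cannot
   be recovered at all; the floor prevents unbounded noise amplification
   in near-invisible voxels (far corners).  The floor value was chosen on
   the synthetic recovery benchmark and is a package default, not a
   physical constant.

Output images are per-voxel conductivity change in % of background
(conductivity increase positive), on the inverse grid, exportable as
NIfTI with the grid affine.

Population statistics: per-voxel one-sample t of peak dsigma across
recordings (zero-variance voxels flagged, df = n-1); a reproducibility
mask labeling voxels active when the across-recording count of
per-recording activity flags beats binomial chance (default threshold
p < 1e-4); and the grand average of peak-normalized recordings.  The
per-recording activity test feeding the binomial mask is not specified in
the source description, so it is declared here: a voxel is flagged when
its response-window peak |dsigma| exceeds the (1 - alpha) quantile of the
recording's own pre-onset peak map (alpha = 0.05 nominal).

## Laminar CSD analysis

16 contacts at 100 um pitch.  Chain: zero-phase 500 Hz low-pass and
trial average; linear interpolation onto a 50 um grid covering the
probe's nominal span of 16 x 100 um = 1.6 mm, i.e. 32 segments (the grid
covers [0, 1600) um — the printed segment count fixes this convention);
Gaussian depth smoothing with 100 um FWHM (unit-sum kernel, reflective
boundary); CSD as `-sigma_t d2V/dz2` (sinks negative, sigma_t = 0.3 S/m
configurable) by central differences, with one-sided 3-point second
differences at the probe ends — chosen over edge-value extension because
it keeps the estimator exactly zero for affine potentials up to the
boundary rows, which is the estimator's defining sanity property.
Significance: values not strictly beyond 3x the per-depth interstimulus
SD are zeroed.  Onsets: per depth, the peak |CSD| is located (earliest
sample on ties) and the onset is the first sample of the contiguous
significant run containing it; never-significant depths carry a NaN
sentinel.

The overall earliest onset needs three robustness rules, all declared
and configurable.  (1) The outermost three depth segments at each probe
end are dropped from the significance map — the second-derivative
estimator is unreliable at a finite probe's ends, the usual reason edge
channels are excluded in laminar CSD practice.  (2) The earliest-onset
summary considers only responding depths, those whose peak reaches 20%
of the strongest peak across depths; under Gaussian noise a bare
3-sigma crossing occurs somewhere in the response window with order-one
probability, and without this filter such a crossing can claim the
earliest onset.  (3) Depth ties at the time resolution are resolved by
the amplitude-weighted centroid of the tied depths on the CSDA's fine
(0.125 ms) grid, and by the strongest tied depth at the EIT image's
1 ms frame resolution, where whole layer blocks tie structurally.  With
these defaults the synthetic round trip recovers the phantom onset
within +-100 um and +-2 ms in the large majority of noise seeds; the
residual spread is crossing-time jitter measured against the shallow
infragranular activation-delay gradient (a 100 um depth step
corresponds to only ~0.2 ms of delay), i.e. an information limit of the
3-SD onset definition at this SNR, not an estimator bias.

The EIT-side ROI analysis applies the identical 3-SD/backward-walk
rule, with per-layer noise taken from a reconstruction of interstimulus
frames at the same lambda.

## Cross-validation

The ROI is a vertical column of 200 x 200 um laterally and 2 mm of
depth in 40 layers of 50 um at the depth-probe location; layers (50 um)
are thinner than voxels (200 um), so each layer samples the voxel slab
containing its centre, averaged laterally.  Onset times and depths are
compared per recording (Pearson r with two-sided p); translaminar
latencies are normalized within each recording to its earliest onset and
tested per depth (one-sample t vs zero; paired t EIT vs CSDA), both
Bonferroni-corrected at family alpha = 0.05.  Depths with sentinel
onsets are excluded pairwise and counted.  Amplitudes for the
per-recording comparison are the peak |dsigma| in the ROI and the peak
|CSD| over all depths and times.

## 4D trajectories

The velocity-like field is `v = grad(d sigma/dt)` (temporal central
differences, one-sided at the ends; spatial central differences on the
voxel grid; trilinear interpolation between voxel centres).  Trajectories
are integrated with first-order Euler steps under the longest-step
condition `delta_t = r_z / max|v|` over the frame with `r_z = 50 um`, so
no spatial step exceeds 50 um (asserted for every step in the tests).
1000 seeds are placed on a deterministic 10 x 10 x 10 lattice in a
500^3 um region about the centre of activity (the |dsigma|-weighted
centroid of voxels above 50% of the frame peak).  Trajectories terminate
at the window end, on leaving the grid, or when the local speed falls
below 1e-6 of the frame maximum (stagnation guard).  The
depth-connection profile counts lateral segments (horizontal displacement
exceeding vertical) in 50 um depth bins and reports the argmax depth.

Note that `v` has units of %/(ms mm), not mm/ms: treating it as a
velocity is the method's own convention, and the longest-step condition
is what gives the scheme a length scale.  On a translating-Gaussian test
field, trajectories relax onto the comoving flank where the local drift
speed equals the translation speed; direction is recovered within 10 deg
and settled speed within 15%.

## Synthetic phantoms

The activity phantom is an analytic conductivity-increase field with an
explicit activation delay per depth, so it is exactly zero before its
local onset and the true chronology is known in closed form.  Defaults
are the imaged physiology: onset 8 ms post-stimulus at 790 um (layer IV),
smooth rise over 3 ms and decay over 6 ms, peak +0.05%, spread downward
to 1.5 mm over 1.5 ms and upward to 150 um over 3.5 ms, lateral sigma
0.4 mm, and an optional lateral lobe confined to the 400-500 um band
(layers II/III) propagating row-wise at 0.25 mm/ms with half the main
amplitude.  The Gaussian-blob family is a modeling choice for testing,
not a claim about the true spatial profile of cortical conductivity
change.

Raw-recording synthesis projects the phantom through the linearized
per-pair sensitivity onto channel amplitudes (the linearization is
exact to ~3% against full re-solves at these amplitudes), modulates a
continuous carrier with a random phase per injection, adds a causal
band-limited evoked potential (Gamma-envelope 80 Hz oscillation; its
spectrum decays as f^-4 so carrier-band leakage is negligible, as for
physiological EPs) and white channel noise, and tiles 15 trials with the
backward-deflection response scaled by 0.8 (forward is the preferred
direction).  The default noise level is chosen so the averaged
interstimulus dZ SD is about one third of the median responder peak
|dZ|, which exercises both 3-SD rules meaningfully.  The carrier phase
is *not* re-randomized per trial: with a shared acquisition clock a
mid-record phase jump is physically a discontinuous oscillator, and its
filter transient would land exactly in the response window;
phase-insensitivity of the demodulator is verified over arbitrary global
phases instead.

LFP synthesis defines the target CSD as the phantom's rate of change
along the probe (scaled to 4.3 amplitude units by default), integrates
`d2V/dz2 = -CSD/sigma_t` twice over a depth domain extended 0.25 mm past
the probe (zero potential at the far boundaries), samples the 16
contacts from the interior and adds white noise (default 2% of the peak
LFP).  Clamping the potential at the probe ends themselves would inject
endpoint curvature — spurious edge sources several times the genuine
CSD — that real recordings do not contain; the extension is kept short
because in this 1-D model the potential of a compact source decays only
linearly, so a long pad inflates the LFP amplitude (and with it the
amplitude-referenced noise) without adding information.  `compute_csd`
recovers the constructed CSD up to the declared 100 um smoothing
(round-trip tested), and the CSDA chain recovers the phantom onset depth
within 100 um at the tested seeds.

## Localization-accuracy study

Perturbations are 0.5 mm diameter spheres with conductivity +1% of
background (0.3 -> 0.303 S/m in gray matter), applied with
partial-volume weighting (each tet sampled at its vertices and centroid)
so a sphere smaller than the local elements still deposits the correct
total conductivity-volume product.  Difference data are exact
perturbed-minus-baseline re-solves (not the linearized model), plus
0.5 uV Gaussian noise per channel, seeded.  The localization error is
the distance from the true centre to the centre of mass of voxels above
50% of the image peak.

Scale: the whole-brain run uses the parametric brain at 0.5 mm elements
(~37k tetrahedra), two 32-electrode arrays draped over the hemisphere
apices, 60 depth-optimized injection pairs (3720 measurement channels),
and 40 perturbation locations subsampled deterministically from a 0.5 mm
grid that excludes ventricle-adjacent (within 0.75 mm of CSF) and
skull-base (deepest 15%) locations.  These sizes keep the full study in
a few minutes on one CPU.

**Limitation — noisy deep localization at this scale.**  With 50 uA
injection, a 0.5 mm/+1% sphere produces boundary-voltage changes of at
most ~0.5 uV at 1 mm depth, falling roughly as depth^-4 (the product of
two source gradients); at 2 mm and beyond the per-channel signal is
0.1-0.15 uV against 0.5 uV channel noise, and the total signal energy
over all 3720 channels is within a few standard deviations of the
noise-energy fluctuation.  Deep localization in this scaled model is
therefore information-limited, not algorithm-limited: noiseless medians
are 0.1-0.4 mm everywhere, while 0.5 uV medians are in the millimetres
for mid-depth targets.  The same holds for the deep corners of the
planar 7 x 5 x 2 mm study.  Reproducing sub-half-millimetre accuracy
throughout the brain at 0.5 uV noise requires the full-scale study
(tens of millions of elements, 120 electrodes, and/or higher injected
current), which is outside this package's scope; `scripts/acceptance.py`
reports the scaled medians as computed.

## What the synthetic studies do and do not show

Passing the recovery tests shows the chain is internally consistent and
unbiased at the stated noise levels: the demodulator, QC, inversion and
onset logic recover what the generator put in, through the full
carrier-level signal path.  It does not validate the biophysics of
cortical impedance changes, the Gaussian phantom shape, electrode-tissue
interface effects, correlated or non-Gaussian noise, mains interference,
or geometric/registration errors of real preparations — all of which the
generator deliberately omits.  The forward/inverse pair shares one mesh
family (an "inverse crime" in the strict sense); the Jacobian tests
against re-solves and the plate-electrode analytic benchmarks bound the
purely numerical error, but transfer of the accuracy numbers to real
geometry is not claimed.
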