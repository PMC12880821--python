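# Methods

This note records the models, conventions, parameter choices and known
limitations behind `cipls`. It is the package's own account of its science;
every number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## The measurement being modelled

Circularly polarized light scattering (CiPLS) probes the size of cell
nuclei inside a turbid medium. In the Mie regime, depolarization of
circularly polarized light (CPL) by multiple scattering depends strongly on
the ratio of particle diameter to wavelength, and CPL retains its helicity
through many forward-peaked scattering events ("circular polarization
memory"), so backscattered CPL carries information from millimetre depths.
Cancerous nuclei are roughly twice the diameter of normal nuclei; probing
at two wavelengths (617 and 850 nm) therefore yields opposite DOCP
responses to buried enlarged-nucleus tissue, and the per-pixel difference

    DeltaDOCP = DOCP(617 nm) - DOCP(850 nm)

cancels wavelength-independent surface terms (specular reflection,
roughness). The degree of circular polarization is kept **signed**,
DOCP = S3/S0, because the helicity of the return carries physics (a single
backscatter flips it, a forward-scattering chain preserves it).

The imaging chain is: CPL illumination at 30 degrees incidence ->
sample -> quarter-wave plate (QWP) -> division-of-focal-plane polarization
camera (2x2 microgrid of linear analyzers at 0/45/90/135 degrees). A QWP
with vertical fast axis maps (S0, S1, S2, S3) to (S0, S1, -S3, S2), so the
camera's "S2 image" is a -S3 image and

    DOCP = -2 (I45 - I135) / (I0 + I45 + I90 + I135),

with the halved four-channel sum as pseudo total intensity (a polarization
camera cannot measure true S0; the four-channel form also averages noise
over four samples).

## Conventions

* **Handedness**: S3 > 0 means right-handed CPL from the receiver's point
  of view. This is config (`PolarimetricConvention`), recorded in outputs,
  never mixed within a run. The underlying data do not pin this down; only
  trend *directions* are treated as meaningful, not absolute signs.
* **Angles**: analyzer angles from the horizontal image axis; QWP fast-axis
  angle from vertical. Degrees at all interfaces.
* **No clipping**: DOCP values outside [-1, 1] (possible under noise) are
  preserved and flagged, because clipping biases ROI means.
* **SD flavor**: ROI error bars are population standard deviations
  (descriptive scatter over the ROI), not standard errors.
* **DeltaDOCP per sample** is reported as the difference of per-wavelength
  ROI means; the ROI mean of the pixelwise difference map is emitted
  alongside (the two differ only through masking).

## Mosaic camera model

Forward model: per sensor pixel, optionally apply the QWP Mueller matrix,
evaluate Malus's law at the pixel's analyzer angle, scale by gain
(counts per unit S0), add Poisson shot noise, round half-up, saturate at
full scale (saturated superpixels are flagged invalid). The scene Stokes
field is defined at superpixel resolution and taken uniform within each
2x2 superpixel; the instantaneous-field-of-view mismatch between the four
sub-pixels is ignored. Demosaicing is superpixel binning (half resolution,
no interpolation); an interpolating demosaic is deliberately not the
default because it correlates noise across Stokes components. The anchor
ordering of the four analyzer angles is sensor-specific and is config; the
default is [[90, 45], [135, 0]] and all 24 permutations are supported and
tested.

## Phantoms

A phantom is a lateral-infinite stack: healthy top layer (thickness T1,
possibly absent), cancerous layer (T2), healthy backing filling to a total
T = 3.5 mm by default (the construction requires T > 3 mm, thick enough
that little probing light is transmitted in the real experiment). The six
shipped samples use (T1, T2) =
(0.0, 1.0), (0.5, 0.1), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0), (1.5, 1.0) mm.
The T1 sweep (samples 1, 4, 5, 6; fixed T2 = 1.0 mm) probes burial depth;
the T2 sweep (samples 2, 3, 4; fixed T1 = 0.5 mm) probes cancer-layer
volume.

The only scatterers are cell nuclei, modelled as homogeneous spheres. This
follows the stated contrast mechanism; fibrous-tissue anisotropy is
omitted because it affects the azimuth of depolarized light but not DOCP.

## Polarized Monte Carlo

Meridian-plane method: each packet's Stokes vector is referenced to the
plane containing its direction and the depth axis. A scattering event
rotates the Stokes vector into the scattering plane (R(phi)), applies the
sphere Mueller matrix M(theta), rotates into the new meridian (R(psi),
computed from explicit 3D basis vectors rather than spherical-trigonometry
shortcuts), and renormalizes S0 to 1 so intensity lives in the packet
weight. Sampling is from the *polarized* phase function: theta from the
m11 marginal by inverse-CDF lookup (4096 quantiles; the marginal over phi
is polarization-independent because the azimuthal term integrates to
zero), then phi | theta by rejection against
1 + (m12/m11)(S1 cos 2phi + S2 sin 2phi) under the envelope
1 + |m12/m11| sqrt(S1^2 + S2^2). Because (theta, phi) are drawn
proportionally to the scattered S0, renormalizing is unbiased.

* **Steps**: exponential with the local mu_s + mu_a; partial steps at layer
  boundaries with memoryless resampling. Internal boundaries are
  index-matched (all layers share the host index 1.36), so no internal
  Fresnel events.
* **Surface**: the 30-degree entry beam suffers stochastic unpolarized
  Fresnel reflection (specular bucket, excluded from detection).  Exits
  are decided stochastically by the unpolarized Fresnel reflectance;
  internal reflections are treated as ideal near-normal mirrors
  (S3 -> -S3, S2 -> -S2), an approximation that is exact at normal
  incidence and ignores total-internal-reflection phase shifts.
* **Detection**: top-surface exits within a 20-degree (half-angle,
  measured in air) acceptance cone about the normal, emulating a distant
  normal-viewing camera; the Stokes vector is rotated to the laboratory
  meridian at detection (S3, the quantity analysed, is invariant under
  this frame rotation).
* **Absorption/termination**: weight times albedo per event; Russian
  roulette below weight 1e-4 with survival probability 0.1; a step cap of
  1e5 guards against pathological paths (capped weight is audited
  separately). The weight audit (specular + detected + escaped +
  transmitted + absorbed + roulette + cap = injected) closes to
  floating-point precision and is asserted in tests.
* **RNG**: splitmix64, one counter-based stream per photon keyed by
  (seed, photon index): results are bit-reproducible regardless of
  execution order. Seeds are kept below 2^31 at all interfaces.
* **Illumination**: packets start with Stokes (1, 0, 0, DOCP0), DOCP0
  drawn from the elliptical spot profile: center +1.00, edge +0.880
  (617 nm) / +0.955 (850 nm), linear in normalized elliptical radius,
  area-uniform launch. The footprint follows the 30-degree obliquity
  (minor axis 25 mm, major = minor / cos 30 ~ 29 mm). The slab is
  laterally uniform, so the profile enters only through DOCP0. The
  polarization change of the refracted beam at entry (s/p transmission
  mismatch) is ignored; the delivered-beam impurity is already captured by
  the measured spot profile.
* **Statistics**: the aggregate DOCP is S3/S0 of the summed detected
  Stokes vectors; its standard error comes from the delta method for a
  ratio of correlated per-photon sums (zero contributions included).

## Mie tables

The single-scattering inputs (m11, m12, m33, m34 on a 1801-point angle
grid, Qsca, Qext, g) are computed from the Mie series with downward
recurrence for the logarithmic derivative and upward recurrence for the
Riccati-Bessel functions, truncated at the Wiscombe order. The test suite
checks the tables against an independently written evaluation (scipy
spherical Bessel functions; associated-Legendre angular functions) to
1e-6 relative, against the classic Qext(x=10, m=1.5) = 2.8820 benchmark,
and against the Rayleigh limit -m12/m11(90 deg) -> 1.

## Optical parameter calibration (shipped defaults)

No optical parameters for the phantom media are published alongside the
measurement this package emulates, so the defaults are the package's own,
fixed by the calibration procedure in `scripts/calibrate_optics.py` and
frozen:

1. The per-event helicity decay rate sigma_c = -ln <m33/m11> (mean over
   the phase function) was scanned against nucleus diameter at both
   wavelengths. sigma_c(d) is strongly oscillatory (morphology
   resonances at bead-phantom index contrasts), and the wavelength flip
   requires the *healthy* diameter to sit on a 617 nm depolarization
   resonance and the *cancerous* (twice as large) diameter on an 850 nm
   resonance.
2. The shipped pair is d = 6.5 um (healthy, particle index 1.68,
   melamine-bead-like) and d = 13.0 um (cancerous, exactly 2:1, index
   1.56, polystyrene-like) in a 1.36 host. At these points
   sigma_c(617) = 0.074 (healthy) vs 0.013 (cancerous) -- the healthy
   medium scrambles helicity ~5x faster per event at 617 nm -- while
   sigma_c(850) = 0.031 (healthy) vs 0.042 (cancerous) with a much larger
   cancerous scattering cross-section, reversing the contrast at 850 nm.
   The slightly lower index of the enlarged nuclei is consistent with
   chromatin dilution on nuclear swelling; bead-grade contrasts are the
   regime of this method's phantom-validation literature -- at a soft
   biological contrast (~1.40/1.36) the per-event depolarization is an
   order of magnitude weaker and the flip, though present, is not
   resolvable at desk-scale photon budgets.
3. Number densities (1.3e5 / 1.6e5 mm^-3, of the order of one nucleus
   per cell volume) give mu_s ~ 9 mm^-1 (healthy) and ~42 mm^-1
   (cancerous): per-mm helicity-decay rates of 0.67 (healthy) vs 0.54
   (cancerous) at 617 nm and 0.28 vs 1.8 at 850 nm. The healthy medium's
   moderate turbidity keeps the depth response slow enough that the whole
   0-1.5 mm burial-depth sweep stays resolvable, while the dense
   cancerous medium strongly self-shields its own lower boundary at
   850 nm -- the physical reason the cancer-layer *thickness* moves the
   signal far less than its *depth*. mu_a = 0.02 mm^-1 throughout.
4. The shipped values were verified by Monte Carlo at 1e5 photons:
   semi-infinite healthy vs cancerous media separate by >10 combined
   standard errors in the required directions at both wavelengths, and
   the T1 sweep reproduces the published trend directions with every
   successive step resolved above one combined standard error.
5. One published property is reproduced only qualitatively: the
   cancer-thickness (T2) sweep is far less sensitive than the depth (T1)
   sweep, and the T2 = 0.5 and 1.0 mm samples are statistically
   indistinguishable, but the thinnest (T2 = 0.1 mm) sample still
   deviates, leaving the T2/T1 range ratio near 0.4 rather than below
   0.3. Making 0.1 mm of cancer saturate the 850 nm response requires a
   per-millimetre depolarization (or absorption) several times larger
   than the 617 nm mechanism inequality permits for any sphere pair with
   a ~2:1 diameter ratio at phantom-grade index contrasts, so within
   this model family the two requirements cannot be met simultaneously;
   the depth trends were prioritized. See Known limitations.

These are generator defaults, not biological estimates; they define the
synthetic study conditions under which the pipeline is validated.

## Problem sizes

Monte Carlo stages use 1e5 photons per (sample, wavelength) in the
acceptance checks (tens of seconds each, single-threaded), 1e4-3e4 in unit
tests, and a few thousand in workflow tests that only exercise plumbing.
Images in tests are 48-256 superpixels square; real sensor frames are
supported at full resolution.

## Numerical choices

* Quantization: round-half-up, saturate at 2^bit_depth - 1.
* theta sampling bias from the 4096-entry inverse-CDF table is below the
  statistical resolution of 1e5-draw chi-squared tests.
* Zero-denominator pixels in the DOCP estimator are masked invalid (NaN),
  never zero-filled; ROI statistics exclude them.
* Segmentation: Otsu threshold on pseudo-intensity, closing (disk radius
  2 px), largest connected component, hole filling. The ROI delineation in
  the emulated experiment was manual; automatic thresholding was chosen
  for reproducibility, and a manual-mask import path exists.
* Registration between the two wavelength frames defaults to "none"
  (static scene, sequential acquisition); integer-pixel cross-correlation
  is available.
* Monotonicity assessment is a strict sign test on successive differences;
  no smoothing or fitting.
* Degenerate meridian at |uz| -> 1 falls back to the x-z plane reference
  (measure-zero set; S3 unaffected).

## What the generator does and does not emulate

Emulated: the two-wavelength DOCP contrast mechanism and its depth
dependence; oblique elliptical illumination with radial purity falloff;
microgrid sensor readout with shot noise and saturation; tissue-vs-agarose
scene segmentation; the chiral-reflector (left-CPL-only) control target as
a sign check.

Not emulated: real nuclear size dispersity (monodisperse spheres keep the
Mie resonances sharp; real tissue would smooth sigma_c(d) and weaken the
contrast); cytoplasmic/stromal small-particle scattering and fibrous
birefringence; absorption spectra (mu_a is flat); surface roughness;
speckle (illumination is incoherent); lateral structure within a sample
(the scene paints one uniform detected state per tissue region, plus
noise); polarized Fresnel effects at oblique entry/exit. Passing tests
therefore demonstrate the *pipeline* and the *mechanism* under controlled
conditions, not quantitative agreement with any real tissue measurement.

## Known limitations

* Detected-DOCP absolute signs depend on the handedness convention; only
  directions of change are compared against the emulated experiment.
* The resonance-based calibration is deliberately sharp: changing a
  default diameter by a few percent can weaken the wavelength flip. The
  calibration script exists to re-derive defaults if the media model is
  altered.
* The sensitivity contrast between burial depth (T1) and layer volume
  (T2) is reproduced qualitatively (T2 range well below T1 range), but
  its exact magnitude depends on the chosen optical depth scale.
* The stochastic-Fresnel mirror treatment at the top surface ignores
  polarization-dependent reflectance; at the 20-degree acceptance cone
  this is a sub-percent effect.
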