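# Methods

`fiberdrs` studies how the shape of a fiber-optic instrument tip changes what
a diffuse reflectance spectroscopy (DRS) probe "sees" in turbid media such as
cancellous bone.  It couples a voxelized Monte Carlo photon-transport engine
with probe-tip scene builders, probed-volume metrics, and a spectral
processing pipeline for two-layer phantom measurements.  This note documents
the models, the numerical choices, and their limits.

## Photon transport model

Photon packets of unit initial weight are launched from the emitting fiber
and traced through a cubic-voxel grid.  The model is the standard
weighted-packet scheme for turbid media:

- **Free paths.** Between interactions a packet travels an optical depth
  `s = -ln(xi)` (uniform deviate `xi`), consumed voxel by voxel at the local
  total attenuation `mu_t = mu_a + mu_s` so heterogeneous scenes (absorbing
  tip, layered phantom) are handled exactly along the ray.
- **Deposition.** At each interaction a fraction `mu_a / mu_t` of the current
  weight is deposited into the voxel (discrete-albedo scheme); the survivor
  is scattered into a new direction with polar cosine drawn from the
  Henyey-Greenstein inverse CDF and uniform azimuth.
- **Termination.** Russian roulette below weight 1e-4 with survival
  probability 1/10 (unbiased in expectation); escape through any grid face
  (matched refractive index everywhere, hence no Fresnel reflection); a 1e6
  event safety cap, counted and logged.
- **Fibers.** The beam is a top-hat over the 200 um core disc with top-hat
  divergence uniform in solid angle up to `arcsin(NA)`, NA = 0.22.  Detection
  requires exit through the top face within the collector core radius
  (measured in the plane normal to the collector axis) and within
  `arcsin(NA)` of the reversed collector axis.  Tilted fibers launch/collect
  on the flat entry face, with the sampling disc slid along the fiber axis
  onto that face.
- **Randomness.** Every photon owns a counter-based splitmix64 stream derived
  from (run seed, photon index), so results are bit-reproducible and
  independent of batching, buffer sizes, or parallel scheduling.
- **Acceleration.** A per-voxel "safe radius" (Euclidean distance transform
  to the nearest different material or grid face) lets the tracer jump whole
  free paths inside homogeneous regions instead of walking voxel boundaries.
  This changes only the order of floating-point operations along a path, not
  the sampled physics.

Default optical properties are those of cancellous bone at 1211 nm (the NIR
fat-absorption maximum): `mu_a = 1.4220 /cm`, `mu_s' = 19.5129 /cm`,
`g = 0.9`, with `mu_s = mu_s'/(1-g)`.  Coefficients are declared per cm (the
literature convention; a `unit` field allows per-mm) and converted to mm
internally.  The instrument tip is fully absorbing (`mu_a = 1e6 /cm`; at
voxel scale any interpretation of that magnitude is opaque) with the same
scattering as the medium.

## Probe-tip geometries

All scenes use a 6 x 4 x 4 mm grid with the probe face centered on top, z
down.  Fiber separation `df = 1.4 mm`.

- **Blunt:** homogeneous medium, vertical fibers.
- **Cone:** the instrument tip is the cone-shaped end of the probe shaft,
  protruding into the medium between and around the fibers, fully absorbing.
  The base radius defaults to the physical shaft radius (see below); apex
  depth is `R tan(alpha)`.  The fibers reach the tissue through cylindrical
  clearance channels bored through the cone (one voxel of slack), as in the
  physical instrument where the fibers run in channels in the steel tip.
- **Single bevel:** emulated by tilting both fiber axes by `alpha` in the
  fiber plane and widening the face separation to `df' = df / cos(alpha)`;
  the simulated flat face represents the bevel face.  No tip material.

**Probe shaft radius.** The simulated instrument's diameter is not
determined by the fiber separation alone.  The default is the smallest
shaft that spans both fiber channels plus a wall,
`R = df/2 + core_diameter = 0.9 mm`.  `TipConfig.base_radius` overrides it.
Sensitivity (2e7-photon runs): the cone's photon-count attenuation depends
strongly on R (count ratio at 30 degrees: 0.84 / 0.49 / 0.11 / 0.02 for
R = 0.6 / 0.9 / 1.25 / 1.6 mm), while its probing-depth ratio is nearly
R-independent (0.68-0.73) because the surviving detected photons dive just
under the apex wherever it is.

An optional refractive-index mismatch (`Scene.refractive_index`, relative
to the outside) adds unpolarized Fresnel reflection and total internal
reflection at the entry face and Snell-narrowed launch divergence; the
default is matched index (no Fresnel), and all reported results use it.

## Probed volume and optical probing depth

Paths of detected photons are rasterized with exact segment-voxel
intersection lengths weighted by packet weight (a track-length fluence
estimator equal in expectation to deposited energy divided by `mu_a`),
normalized by launched photons and voxel volume, and projected onto the
fiber (x-z) plane.  The probed volume is the highest-density region of this
map holding 68.3% of its mass - the fraction of detected-photon path mass a
one-standard-deviation envelope would contain.  Voxels enter the region in
order of decreasing intensity (ties broken shallower-first), so the achieved
fraction exceeds 68.3% by at most one voxel's mass.

Because the region boundary is a quantile of a sampled density, the raw-map
estimate is noisy and biased deep when only tens to hundreds of photons are
detected.  Projected maps are therefore smoothed with a small Gaussian
(bandwidth 0.08 mm, two voxels at the default 25 bins/mm) before region
extraction.  In reference runs at 2e7 photons the smoothed-map depth agrees
with the converged raw-map value to a few percent while remaining unbiased
down to ~50 detected photons; analytic unit tests bypass smoothing.

The **optical probing depth** is the distance from the probe tip to the
deepest point of the probed volume, measured along the probe axis.  The tip
reference is design-specific: the cone apex, the flat face for the blunt
probe, and for the bevel the collecting fiber's position on the bevel face
(that fiber sits at the instrument tip).  For the tilted bevel frame the
depth of a region point is `(z - z_tip) cos(alpha) + (x - x_tip) sin(alpha)`;
for untilted probes this reduces to `deepest z - apex depth`.  The depth can
be non-positive when light does not pass the tip.

## Tip-angle sweep

`angle_sweep` runs one simulation per (design, alpha) with deterministic
per-cell seeds derived from the base seed, and tabulates detected counts,
probing depths, and their ratios to the blunt (alpha = 0) reference of the
same design.  Cells with fewer than 100 detected photons are flagged
unreliable.  Desk-scale defaults are 25 bins/mm and 1e6-2e7 photons per
cell; the full-scale setting (100 bins/mm, 1e9 photons) is exposed via the
CLI's `--full-scale` for cluster use.

## Phantom spectra pipeline

Measurements are per-distance sets of 10 repeat spectra on a 255-channel
grid spanning 839.65-1724.27 nm, with a white-reference calibration spectrum
and a reference `I_inf(lambda)` acquired on pure cancellous-mimicking
material.  Processing: pointwise division by the white reference (channels
with non-positive white flagged NaN and excluded), pointwise mean of the
repeats, third-order Savitzky-Golay smoothing with an 11-sample frame
(polynomial-fit edge handling, so cubic signals pass through exactly), then
dual normalization

    r(dp, lambda) = [I(dp,lambda) / I_inf(lambda)] / max_lambda [I(0,lambda) / I_inf(lambda)]

so the interface (dp = 0) curve peaks at exactly 1.  The reference spectrum
is calibrated and filtered identically.  The intensity at
`lambda0 = 1211 nm` is read at the nearest grid channel (grid spacing
~3.5 nm makes interpolation immaterial); a non-max-scaled variant
(`I/I_inf` at `lambda0`) supports cross-design comparison.  The per-design
contrast is the absolute swing of that variant between the largest distance
and the interface; the headline comparison is the bevel:cone contrast ratio.
The whole pipeline is invariant under a common rescaling of all raw spectra
and the white reference.

## Synthetic data generator

The generator emulates the statistical structure of the phantom
measurements, not the instrument physics.  Raw spectra follow a two-flux
partial-path model `I = S0 exp(-mua_top L_top - mua_bot L_bot)` with a
smooth source envelope S0, Gaussian absorber templates (fat peak at 1211 nm
dominating the cancellous-mimicking top layer, emulating 18%-fat coconut
milk; a stronger 1450 nm water band and higher baseline in the
cortical-mimicking bottom layer), and layer path lengths
`L_bot = 2 delta s exp(-dp/delta)`, `L_top = 2 delta - L_bot`.  Defaults:
sampling depth `delta = 1 mm` (the order of the ~2 mm detection horizon of
such probes), multiplicative repeat noise `sigma = 0.01`, and a design
sensitivity `s` of 1.0 (bevel) vs 0.5 (cone) expressing the absorbing tip's
shadowing of the deep layer, so bevel-like sets show roughly double the
cancellous-to-cortical dynamic range.  Every channel moves monotonically
with dp when `sigma = 0`, which the end-to-end recovery tests exploit.  What
passing tests show is that the pipeline recovers known monotone trends and
contrast orderings from data with this structure - not that the forward
model reproduces real phantom spectra.  An optional cross-validation hook
(`mc_reference_spectrum`) generates a few-wavelength spectrum by running the
voxel Monte Carlo on the two-layer scene instead.

## Problem sizes and statistics

Simulation-backed tests run 1e4-6e6 photons at 25 bins/mm, chosen so the
full suite completes on a laptop-class single core; at those sizes the
blunt-probe run detects a few hundred photons and depth ratios carry a few
percent of Monte Carlo error, which the quantitative tolerances absorb.  The
acceptance script uses 1.6e7 photons per scene for tighter ratios.  Energy
bookkeeping (deposited + escaped + detected + terminated weight vs launched)
closes to 1e-3 relative, the tolerance covering Russian-roulette variance.

## Known limitations

- No refractive-index mismatch: no Fresnel reflection at the tissue surface
  or internal boundaries, and the NA acceptance is applied in-medium.
- The bevel emulation inherits the tilted-fiber workaround: the probe body
  above the face is not present in the volume, so light may re-enter where
  steel would block it.
- The absorbing tip is an extreme case; a reflective steel tip would raise
  both count and depth for the cone design.
- Desk-scale voxels (0.04 mm) quantize depths; reported depths carry
  one-voxel (0.04 mm) granularity.
- The synthetic phantom model is a labeled stand-in; absolute intensities
  and noise spectra of the real instrument are out of scope.
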