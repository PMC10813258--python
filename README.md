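# fiberdrs

Monte Carlo photon transport and spectral processing for fiber-optic diffuse
reflectance spectroscopy (DRS) probes with shaped instrument tips.

Surgical instruments that pierce bone — such as the pedicle probes used to
prepare screw trajectories in spine surgery — need sharp, cone- or
bevel-shaped tips, but integrating DRS fibers into such a tip changes what
the probe optically "sees": an absorbing tip that protrudes between the
fibers shrinks both the optical probing depth and the collected signal.
`fiberdrs` quantifies this effect.  It provides:

- **`mc_engine`** — a voxelized Monte Carlo photon-packet transport engine
  (MCML-style weight deposition, Henyey–Greenstein scattering with
  anisotropy *g*, Russian roulette, NA-gated fiber detection), JIT-compiled
  and bit-reproducible via counter-based per-photon random streams;
- **`geometry`** — scene builders for a blunt probe, a fully absorbing cone
  tip (angle α, fiber clearance channels), a tilted-fiber single-bevel
  emulation (separation widened to d_f/cos α), and a two-layer phantom;
- **`metrics`** — projected collected-photon fluence maps, the probed
  volume (highest-density region holding 68.3 % of detected-photon path
  mass, the one-standard-deviation envelope fraction), the optical probing
  depth (probe-frame distance from the tip to the deepest probed point),
  and tip-angle sweep tables;
- **`spectra_pipeline`** — the phantom measurement chain: white-reference
  calibration, 10-repeat averaging, third-order Savitzky–Golay filtering
  (11-sample frame), dual normalization r(d_p, λ) = [I/I_∞] / max_λ[I(0)/I_∞],
  intensity at λ₀ = 1211 nm (the NIR fat absorption peak), and
  cancellous→cortical contrast ratios;
- **`synthetic_data`** — a seeded generator of complete measurement sets
  (two-flux partial-path forward model with fat/water absorber templates)
  plus small fixture scenes with closed-form behavior;
- **`cli_experiments`** — a `fiberdrs` command with `fig4` (tip-angle
  sweep), `fig5` (spectra pipeline), and `synth` (data generation) verbs.

The default medium is cancellous bone at 1211 nm: μₐ = 1.4220 cm⁻¹,
μ′ₛ = 19.5129 cm⁻¹, g = 0.9 (μₛ = μ′ₛ/(1−g)); fibers have 200 µm cores,
NA 0.22, separation d_f = 1.4 mm; the tip material is opaque
(μₐ = 10⁶ cm⁻¹) with the medium's scattering.

## Worked example

Probing depth of a 30° single-bevel probe versus a blunt probe:

```python
from fiberdrs import (CANCELLOUS_1211NM, build_scene, run_simulation,
                      project_collected_fluence, probed_volume,
                      optical_probing_depth)
from fiberdrs.metrics import DEFAULT_MAP_SMOOTHING_MM

for design, alpha, seed in (("blunt", 0, 107922), ("bevel", 30, 131679)):
    scene = build_scene(design, alpha, CANCELLOUS_1211NM, resolution=25.0)
    res = run_simulation(scene, n_photons=16_000_000, seed=seed)
    pmap = project_collected_fluence(res)
    pv = probed_volume(pmap, scene.voxel_size,
                       smooth_sigma_mm=DEFAULT_MAP_SMOOTHING_MM)
    depth = optical_probing_depth(pv, scene)
    print(design, alpha, res.n_detected, round(depth, 3))
```

prints (deterministic for the seeds shown, ~3 min each on one core):

```
blunt 0 734 1.12
bevel 30 457 0.797
```

i.e. the blunt probe's probed volume reaches 1.12 mm below the face while
the 30° bevel still reaches 0.797 mm beyond its tip fiber — 71 % of the
blunt probing depth, at roughly ⅔ of the blunt photon count.  The same
comparison for a fully absorbing 30° cone tip gives 0.84 mm from the apex
(75 %) but under half the photon count; sharper cones collapse the signal
entirely.

The equivalent sweep from the shell:

```sh
fiberdrs fig4 --n-photons 1000000 --seed 1 --out fig4_out
fiberdrs synth --design bevel --seed 3 --out sets/bevel
fiberdrs synth --design cone  --seed 3 --out sets/cone
fiberdrs fig5 sets/cone sets/bevel --out fig5_out
```

`fig4` writes `angle_sweep.csv` (counts, probing depths, ratios vs α = 0
per design) and per-cell HDF5 maps; `fig5` writes tidy normalized-spectra
CSVs, λ₀ series, and the bevel:cone contrast ratio (≈ 2 for the default
generator settings: the absorbing cone tip sees about half the
cancellous→cortical intensity swing of the bevel).

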