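"""Synthetic measurement sets and fixture scenes.

The spectrometer measurements of the two-layer phantom are emulated with a
deliberately simple two-flux partial-path forward model, synthetic by design:
its job is to reproduce the statistical structure the processing pipeline
assumes (smooth NIR spectra with a fat absorption peak at 1211 nm and a water
band near 1450 nm, a monotonic spectral transition as the probe approaches
the cortical-mimicking layer, multiplicative repeat noise, a white-reference
calibration spectrum), not the absolute physics of the instrument.

Signal model:  I(dp, lambda) = S0(lambda) * exp(-mua_top * L_top - mua_bot * L_bot)

with partial path lengths that transfer smoothly from the bottom to the top
layer as the probe retreats from the interface:

    L_bot = 2 * delta * s * exp(-dp / delta),      L_top = 2 * delta - L_bot

where delta is the effective sampling depth and s in (0, 1] a tip-design
sensitivity factor (a protruding-fiber bevel sees the deep layer more
strongly than a cone whose absorbing tip shadows it).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mc_engine import Scene
from .optics import CANCELLOUS_1211NM, OpticalProperties
from .spectra_pipeline import WAVELENGTH_GRID, MeasurementSet, Spectrum

__all__ = [
    "PhantomForwardModel",
    "synth_spectrum",
    "synth_measurement_set",
    "mc_reference_spectrum",
    "fixture_scene",
]


def _gauss(wl, center, width):
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass(frozen=True)
class PhantomForwardModel:
    """Parametric stand-in for the two-layer phantom's spectral response.

    Absorber templates are Gaussian peaks (amplitudes per mm); the top layer
    is fat-dominated (18%-fat coconut-milk mimic), the bottom layer
    water-bearing and more attenuating overall (gelatin/barium-sulfate
    cortical mimic).  delta is the effective sampling depth of the probe and
    sigma the per-channel multiplicative repeat-noise level.
    """

    fat_center: float = 1211.0     # nm
    fat_width: float = 35.0
    water_center: float = 1450.0
    water_width: float = 50.0
    top_fat_amp: float = 0.30      # per mm
    top_water_amp: float = 0.10
    top_baseline: float = 0.05
    bot_fat_amp: float = 0.02
    bot_water_amp: float = 0.45
    bot_baseline: float = 0.12
    delta: float = 1.0             # mm, effective sampling depth
    sigma: float = 0.01            # multiplicative Gaussian noise
    source_amp: float = 4.0e4      # detector counts at the envelope peak
    wavelengths: tuple = tuple(WAVELENGTH_GRID)

    def __post_init__(self):
        for name in ("top_fat_amp", "top_water_amp", "top_baseline",
                     "bot_fat_amp", "bot_water_amp", "bot_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.wavelengths)

    def source_envelope(self) -> np.ndarray:
        """Smooth halogen-like source/detector envelope S0(lambda), counts."""
        wl = self.grid
        return self.source_amp * (0.15 + _gauss(wl, 1250.0, 420.0))

    def mu_a_top(self) -> np.ndarray:
        wl = self.grid
        return (self.top_baseline
                + self.top_fat_amp * _gauss(wl, self.fat_center, self.fat_width)
                + self.top_water_amp * _gauss(wl, self.water_center, self.water_width))

    def mu_a_bottom(self) -> np.ndarray:
        wl = self.grid
        return (self.bot_baseline
                + self.bot_fat_amp * _gauss(wl, self.fat_center, self.fat_width)
                + self.bot_water_amp * _gauss(wl, self.water_center, self.water_width))


#: reduced deep-layer sensitivity of the absorbing cone tip vs. the bevel
DESIGN_SENSITIVITY = {"bevel": 1.0, "cone": 0.5}


def synth_spectrum(model: PhantomForwardModel, dp: float,
                   rng: np.random.Generator | None = None,
                   sensitivity: float = 1.0) -> Spectrum:
    """One raw (uncalibrated) spectrum at probe-to-interface distance dp."""
    if dp < 0:
        raise ValueError("dp must be >= 0")
    l_bot = 2.0 * model.delta * sensitivity * math.exp(-dp / model.delta)
    l_top = 2.0 * model.delta - l_bot
    counts = model.source_envelope() * np.exp(
        -model.mu_a_top() * l_top - model.mu_a_bottom() * l_bot)
    if rng is not None and model.sigma > 0:
        counts = counts * (1.0 + model.sigma * rng.standard_normal(counts.shape))
    return Spectrum(model.grid.copy(), counts)


def synth_measurement_set(
    model: PhantomForwardModel,
    design_label: str,
    distances=tuple(np.arange(0, 2.51, 0.25)),
    repeats: int = 10,
    seed: int = 0,
    out_dir=None,
) -> MeasurementSet:
    """Generate a complete measurement set; optionally write it to disk.

    The on-disk layout matches MeasurementSet.from_directory: a manifest.json
    plus one CSV per (distance, repeat), a white-reference calibration
    spectrum (the source envelope with noise) and an I_inf reference recorded
    far from the interface (dp = 10 * delta).
    """
    distances = sorted(float(d) for d in distances)
    if not distances:
        raise ValueError("distances must be nonempty")
    sens = DESIGN_SENSITIVITY.get(design_label)
    if sens is None:
        raise ValueError(f"design_label must be one of {sorted(DESIGN_SENSITIVITY)}")
    rng = np.random.default_rng(seed)

    white = Spectrum(
        model.grid.copy(),
        model.source_envelope() * (1.0 + model.sigma * rng.standard_normal(len(model.grid))),
    )
    reference = synth_spectrum(model, 10.0 * model.delta, rng, sens)
    repeats_map = {
        dp: [synth_spectrum(model, dp, rng, sens) for _ in range(repeats)]
        for dp in distances
    }
    mset = MeasurementSet(
        design_label=design_label,
        repeats=repeats_map,
        calibration=white,
        reference_I_inf=reference,
        expected_repeats=repeats,
        meta={"seed": seed, "delta": model.delta, "sigma": model.sigma},
    )
    if out_dir is not None:
        _write_measurement_set(mset, Path(out_dir))
    return mset


def _write_spectrum_csv(spectrum: Spectrum, path: Path):
    try:
        with open(path, "w") as fh:
            fh.write("wavelength_nm,intensity\n")
            for wl, it in zip(spectrum.wavelengths, spectrum.intensities):
                fh.write(f"{wl:.10g},{it:.10g}\n")
    except OSError as exc:
        raise OSError(f"failed writing spectrum file {path}: {exc}") from exc


def _write_measurement_set(mset: MeasurementSet, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "spectra").mkdir(exist_ok=True)
    _write_spectrum_csv(mset.calibration, out_dir / "calibration.csv")
    _write_spectrum_csv(mset.reference_I_inf, out_dir / "reference_iinf.csv")
    manifest = {
        "design_label": mset.design_label,
        "repeats": mset.expected_repeats,
        "calibration": "calibration.csv",
        "reference": "reference_iinf.csv",
        "distances": mset.distances,
        "spectra": {},
    }
    for dp in mset.distances:
        files = []
        for k, sp in enumerate(mset.repeats[dp]):
            rel = f"spectra/d{dp:.2f}_r{k:02d}.csv"
            _write_spectrum_csv(sp, out_dir / rel)
            files.append(rel)
        manifest["spectra"][f"{dp:.2f}"] = files
    # manifest last, atomically: a complete manifest implies a complete set
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tmp.replace(out_dir / "manifest.json")


def mc_reference_spectrum(model: PhantomForwardModel, dp: float,
                          wavelengths=None, design: str = "blunt",
                          alpha_deg: float = 0.0, n_photons: int = 200_000,
                          seed: int = 0, resolution: float = 10.0):
    """Cross-validation mode: detected-weight spectrum from voxel Monte Carlo.

    Builds a two-layer scene per wavelength, mapping the forward model's
    absorber templates (per mm) onto layer optical properties with fixed
    scattering, and returns (wavelengths, detected weight fraction).  Far
    slower than synth_spectrum; intended to sanity-check the forward model's
    monotone depth transition at a few wavelengths, not to generate data.
    """
    from .geometry import LayeredPhantomConfig, TipConfig, build_two_layer_scene
    from .mc_engine import run_simulation

    if wavelengths is None:
        wavelengths = [1100.0, 1211.0, 1350.0]
    wl_grid = model.grid
    mua_top = np.interp(wavelengths, wl_grid, model.mu_a_top())
    mua_bot = np.interp(wavelengths, wl_grid, model.mu_a_bottom())
    out = []
    for i, wl in enumerate(wavelengths):
        top = OpticalProperties(mu_a=float(mua_top[i]), mu_s_reduced=1.95,
                                g=0.9, unit="mm")
        bot = OpticalProperties(mu_a=float(mua_bot[i]), mu_s_reduced=2.5,
                                g=0.9, unit="mm")
        tip = TipConfig(design, alpha_deg) if design != "blunt" else TipConfig("blunt")
        scene = build_two_layer_scene(LayeredPhantomConfig(dp, top, bot), tip,
                                      resolution=resolution)
        res = run_simulation(scene, n_photons, seed + i, keep_paths="none")
        out.append(res.ledger["detected"] / n_photons)
    return np.asarray(wavelengths, dtype=float), np.asarray(out)


# ---------------------------------------------------------------------------
# small fixture scenes with known closed-form behavior

def fixture_scene(kind: str, resolution: float = 10.0) -> Scene:
    """Small voxel scenes (<= 64^3) for transport unit tests.

    kinds:
      absorbing_slab  - pure absorber (mu_a = 1/mm, mu_s = 0): Beer-Lambert
      scatter_free    - pure absorber, weaker (mu_a = 0.25/mm, mu_s = 0)
      no_absorption   - scattering only (mu_a = 0): zero deposition
      tiny_cancellous - cancellous-bone properties, fibers at df = 1.4 mm
    """
    from .geometry import build_blunt_scene

    if kind == "absorbing_slab":
        props = OpticalProperties(mu_a=1.0, mu_s_reduced=0.0, g=0.0, unit="mm")
    elif kind == "scatter_free":
        props = OpticalProperties(mu_a=0.25, mu_s_reduced=0.0, g=0.0, unit="mm")
    elif kind == "no_absorption":
        props = OpticalProperties(mu_a=0.0, mu_s_reduced=1.95, g=0.9, unit="mm")
    elif kind == "tiny_cancellous":
        props = CANCELLOUS_1211NM
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    grid = (4.0, 4.0, 4.0)
    scene = build_blunt_scene(props, resolution=resolution, grid_mm=grid)
    scene.meta["fixture"] = kind
    return scene
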