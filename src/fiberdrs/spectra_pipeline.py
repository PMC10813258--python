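"""Processing chain for two-layer phantom diffuse reflectance spectra.

A measurement campaign approaches the interface between a cancellous-mimicking
top layer and a cortical-mimicking bottom layer, recording 10 repeat spectra
at each probe-to-interface distance dp, plus a white-reference calibration
spectrum and a reference spectrum I_inf(lambda) on pure cancellous-mimicking
material.  The chain is:

    calibrate (divide by white reference)
    -> average the repeats
    -> third-order Savitzky-Golay smoothing, 11-sample frame
    -> normalize to I_inf(lambda), then to the maximal relative intensity at
       the interface (dp = 0)
    -> extract the intensity at lambda0 = 1211 nm (fat absorption maximum)
       per distance, and the cancellous->cortical contrast per design.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "LAMBDA0_NM",
    "WAVELENGTH_GRID",
    "Spectrum",
    "MeasurementSet",
    "DistanceSeries",
    "calibrate",
    "average_and_filter",
    "normalize_series",
    "intensity_at",
    "contrast",
    "process_measurement_set",
]

#: fat absorption maximum in the NIR, nm
LAMBDA0_NM = 1211.0
#: spectrometer wavelength grid: 255 channels spanning the NIR window
WAVELENGTH_GRID = np.linspace(839.65, 1724.27, 255)

SG_WINDOW = 11
SG_ORDER = 3


@dataclass
class Spectrum:
    """One spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length 1D arrays")
        if np.any(self.wavelengths < 0):
            raise ValueError("negative wavelengths")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self):
        return len(self.wavelengths)

    def same_grid(self, other: "Spectrum") -> bool:
        return (len(self) == len(other)
                and bool(np.allclose(self.wavelengths, other.wavelengths, atol=1e-9)))


@dataclass
class MeasurementSet:
    """Distances -> repeat spectra, plus calibration and I_inf references."""

    design_label: str                       # "cone" | "bevel"
    repeats: dict                           # dp (mm) -> list[Spectrum]
    calibration: Spectrum                   # white-reference spectrum
    reference_I_inf: Spectrum               # pure cancellous-mimicking reference
    expected_repeats: int = 10
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.design_label not in ("cone", "bevel"):
            raise ValueError(f"design_label must be 'cone' or 'bevel', got {self.design_label!r}")
        if not self.repeats:
            raise ValueError("measurement set has no distances")
        for dp, specs in self.repeats.items():
            if len(specs) != self.expected_repeats:
                raise ValueError(
                    f"dp={dp}: expected {self.expected_repeats} repeats, got {len(specs)}")
            for sp in specs:
                if not sp.same_grid(self.calibration):
                    raise ValueError(f"dp={dp}: spectrum grid differs from calibration grid")
        if not self.reference_I_inf.same_grid(self.calibration):
            raise ValueError("reference grid differs from calibration grid")

    @property
    def distances(self):
        return sorted(self.repeats)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_directory(cls, path) -> "MeasurementSet":
        """Read the on-disk layout written by synthetic_data (manifest + CSVs)."""
        path = Path(path)
        manifest_file = path / "manifest.json"
        if not manifest_file.exists():
            raise FileNotFoundError(f"no manifest.json in {path}")
        manifest = json.loads(manifest_file.read_text())

        def read_csv(rel):
            f = path / rel
            try:
                df = pd.read_csv(f)
                return Spectrum(df["wavelength_nm"].to_numpy(),
                                df["intensity"].to_numpy())
            except Exception as exc:
                raise ValueError(f"malformed spectrum file {f}: {exc}") from exc

        calibration = read_csv(manifest["calibration"])
        reference = read_csv(manifest["reference"])
        repeats = {}
        for dp_str, files in manifest["spectra"].items():
            repeats[float(dp_str)] = [read_csv(f) for f in files]
        return cls(
            design_label=manifest["design_label"],
            repeats=repeats,
            calibration=calibration,
            reference_I_inf=reference,
            expected_repeats=int(manifest.get("repeats", 10)),
            meta={"path": str(path)},
        )


@dataclass
class DistanceSeries:
    """Normalized spectra r(dp, lambda) and the lambda0 intensity series."""

    design_label: str
    dp: np.ndarray                      # sorted distances, mm
    wavelengths: np.ndarray
    r: np.ndarray                       # (n_dp, n_lambda) doubly normalized
    relative: np.ndarray                # (n_dp, n_lambda) I(dp)/I_inf, before max-scaling
    intensity_at_lambda0: np.ndarray    # per dp, from r
    intensity_at_lambda0_relative: np.ndarray  # per dp, from I(dp)/I_inf (non-max-scaled)
    lambda0: float = LAMBDA0_NM

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.dp):
            for j, wl in enumerate(self.wavelengths):
                rows.append((self.design_label, d, wl, self.r[i, j]))
        return pd.DataFrame(rows, columns=["design", "dp_mm", "lambda_nm", "r"])

    def lambda0_summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "design": self.design_label,
            "dp_mm": self.dp,
            "r_lambda0": self.intensity_at_lambda0,
            "relative_lambda0": self.intensity_at_lambda0_relative,
        })


# ---------------------------------------------------------------------------
# operations

def calibrate(raw: Spectrum, white: Spectrum) -> Spectrum:
    """Correct wavelength-dependent system sensitivity: pointwise raw / white.

    Channels where the white reference is not strictly positive are flagged
    NaN and excluded downstream.
    """
    if not raw.same_grid(white):
        raise ValueError("raw and white spectra must share a wavelength grid")
    out = np.full_like(raw.intensities, np.nan)
    ok = white.intensities > 0
    out[ok] = raw.intensities[ok] / white.intensities[ok]
    return Spectrum(raw.wavelengths.copy(), out)


def average_and_filter(repeats) -> Spectrum:
    """Pointwise mean of repeat spectra, then Savitzky-Golay smoothing
    (order 3, 11-sample frame; polynomial-fit edge handling)."""
    repeats = list(repeats)
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeat spectra to average")
    first = repeats[0]
    for sp in repeats[1:]:
        if not sp.same_grid(first):
            raise ValueError("repeat spectra must share a wavelength grid")
    if len(first) < SG_WINDOW:
        raise ValueError(f"spectrum shorter than the {SG_WINDOW}-sample filter frame")
    mean = np.mean([sp.intensities for sp in repeats], axis=0)
    smooth = savgol_filter(mean, SG_WINDOW, SG_ORDER, mode="interp")
    return Spectrum(first.wavelengths.copy(), smooth)


def normalize_series(mset: MeasurementSet) -> DistanceSeries:
    """Dual normalization of the processed distance series.

    r(dp, lambda) = [I(dp, lambda) / I_inf(lambda)] / max_lambda [I(0, lambda) / I_inf(lambda)]

    so the dp = 0 (interface) curve peaks at exactly 1.  I(dp, .) and I_inf
    are both calibrated, repeat-averaged (measurements only) and SG-filtered.
    """
    dps = mset.distances
    if 0.0 not in [float(d) for d in dps]:
        raise ValueError("dp = 0 measurement required as the normalization reference")
    ref_cal = calibrate(mset.reference_I_inf, mset.calibration)
    ref = Spectrum(ref_cal.wavelengths,
                   savgol_filter(ref_cal.intensities, SG_WINDOW, SG_ORDER, mode="interp"))
    if np.any(~(ref.intensities > 0)):
        raise ValueError("reference I_inf must be positive at every channel")
    processed = {}
    for dp in dps:
        processed[dp] = average_and_filter(
            [calibrate(sp, mset.calibration) for sp in mset.repeats[dp]])
    wl = mset.calibration.wavelengths
    relative = np.vstack([processed[dp].intensities / ref.intensities for dp in dps])
    norm_const = np.nanmax(relative[[float(d) for d in dps].index(0.0)])
    if not norm_const > 0:
        raise ValueError("normalization constant at dp = 0 is not positive")
    r = relative / norm_const
    j0 = _nearest_channel(wl, LAMBDA0_NM)
    return DistanceSeries(
        design_label=mset.design_label,
        dp=np.asarray(dps, dtype=float),
        wavelengths=wl.copy(),
        r=r,
        relative=relative,
        intensity_at_lambda0=r[:, j0],
        intensity_at_lambda0_relative=relative[:, j0],
    )


def _nearest_channel(wavelengths: np.ndarray, lambda0: float) -> int:
    if not wavelengths[0] <= lambda0 <= wavelengths[-1]:
        raise ValueError(f"lambda0 = {lambda0} nm outside grid span "
                         f"[{wavelengths[0]:.2f}, {wavelengths[-1]:.2f}] nm")
    return int(np.argmin(np.abs(wavelengths - lambda0)))


def intensity_at(series: DistanceSeries, lambda0: float = LAMBDA0_NM,
                 normalized: bool = True) -> np.ndarray:
    """Per-distance intensity at the channel nearest lambda0.

    normalized=True uses the doubly normalized r; False the I(dp)/I_inf ratio.
    """
    j = _nearest_channel(series.wavelengths, lambda0)
    return (series.r if normalized else series.relative)[:, j]


def contrast(series_a: DistanceSeries, series_b: DistanceSeries,
             lambda0: float = LAMBDA0_NM) -> float:
    """Ratio of cancellous->cortical intensity swings at lambda0: b over a.

    The per-design contrast is |value(dp_max) - value(dp=0)| of the
    non-max-scaled lambda0 series (comparable across designs).
    """
    def swing(series):
        v = intensity_at(series, lambda0, normalized=False)
        i0 = int(np.argmin(series.dp))
        imax = int(np.argmax(series.dp))
        if not math.isclose(float(series.dp[i0]), 0.0, abs_tol=1e-9):
            raise ValueError("series must include dp = 0")
        return abs(float(v[imax] - v[i0]))

    ca, cb = swing(series_a), swing(series_b)
    if ca == 0:
        raise ZeroDivisionError("zero contrast in the denominator series")
    return cb / ca


def process_measurement_set(mset: MeasurementSet) -> DistanceSeries:
    """Full chain: calibrate -> average+filter -> dual normalization -> series."""
    return normalize_series(mset)
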