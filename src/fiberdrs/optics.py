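"""Optical material properties for voxelized photon transport.

Absorption and scattering coefficients are conventionally tabulated per cm in
the tissue-optics literature; all internal geometry here is in mm, so scene
construction converts.  The ``unit`` field makes the convention explicit and
testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced scattering / anisotropy of one material.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (``unit``⁻¹), >= 0.
    mu_s_reduced : float
        Reduced scattering coefficient mu_s' = mu_s (1 - g) (``unit``⁻¹), >= 0.
    g : float
        Henyey-Greenstein anisotropy factor, |g| < 1.
    unit : str
        Length unit of the coefficients, "cm" (default) or "mm".
    """

    mu_a: float
    mu_s_reduced: float
    g: float
    unit: str = field(default="cm")

    def __post_init__(self):
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_reduced < 0:
            raise ValueError(f"mu_s_reduced must be >= 0, got {self.mu_s_reduced}")
        if not abs(self.g) < 1:
            raise ValueError(f"|g| must be < 1, got {self.g}")
        if self.unit not in ("cm", "mm"):
            raise ValueError(f"unit must be 'cm' or 'mm', got {self.unit!r}")
        if not math.isfinite(self.mu_s):
            raise ValueError("mu_s = mu_s'/(1-g) must be finite")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient recovered from the reduced coefficient."""
        return self.mu_s_reduced / (1.0 - self.g)

    @property
    def _to_mm(self) -> float:
        return 0.1 if self.unit == "cm" else 1.0

    @property
    def mu_a_mm(self) -> float:
        return self.mu_a * self._to_mm

    @property
    def mu_s_mm(self) -> float:
        return self.mu_s * self._to_mm

    @property
    def mu_t_mm(self) -> float:
        """Total attenuation coefficient per mm."""
        return self.mu_a_mm + self.mu_s_mm


#: Cancellous-bone optical properties at 1211 nm (fat absorption maximum).
CANCELLOUS_1211NM = OpticalProperties(mu_a=1.4220, mu_s_reduced=19.5129, g=0.9)

#: Fully absorbing probe-tip material: opaque absorber, scattering as cancellous bone.
TIP_1211NM = OpticalProperties(mu_a=1e6, mu_s_reduced=19.5129, g=0.9)
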