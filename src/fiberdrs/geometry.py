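"""Probe-tip scene builders: blunt, absorbing cone tip, tilted-fiber single bevel.

Coordinate convention: z increases downward into the medium; the fiber plane
is x-z; the probe axis pierces the center of the top face.  Voxels are cubic,
0-based, with centers at (i + 1/2) * voxel_size.

Three tip designs are modelled:

* ``blunt``   - flat instrument face, both fibers vertical, separation df.
* ``cone``    - a fully absorbing cone protrudes into the medium between the
  vertical fibers (an extended instrument tip); the cone base sits on the top
  face and its apex reaches base_radius * tan(alpha) deep.
* ``bevel``   - a slanted tip face emulated by tilting both fibers by alpha
  and widening their surface separation to df' = df / cos(alpha); the
  simulated volume keeps a flat top face (fibers cannot be embedded in the
  voxel grid) and contains no tip material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mc_engine import FiberSpec, Scene
from .optics import TIP_1211NM, OpticalProperties

__all__ = [
    "TipConfig",
    "LayeredPhantomConfig",
    "build_blunt_scene",
    "build_cone_scene",
    "build_bevel_scene",
    "build_two_layer_scene",
    "build_scene",
]

#: material labels
MEDIUM = 0
TIP = 1
BOTTOM_LAYER = 2

DEFAULT_GRID_MM = (6.0, 4.0, 4.0)


@dataclass(frozen=True)
class TipConfig:
    """Probe-tip design parameters."""

    design: str                      # "blunt" | "cone" | "bevel"
    alpha_deg: float = 0.0           # tip angle between tip face and the flat face
    df: float = 1.4                  # emitter-collector distance, mm
    core_diameter: float = 0.2       # mm
    numerical_aperture: float = 0.22
    base_radius: float | None = None  # cone base radius; None -> default rule

    def __post_init__(self):
        if self.design not in ("blunt", "cone", "bevel"):
            raise ValueError(f"unknown tip design {self.design!r}")
        if not 0 <= self.alpha_deg < 90:
            raise ValueError("alpha must satisfy 0 <= alpha < 90 degrees")
        if self.design == "blunt" and self.alpha_deg != 0:
            raise ValueError("a blunt tip has alpha = 0")
        if self.df <= 0:
            raise ValueError("df must be > 0")

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha_deg)

    @property
    def df_prime(self) -> float:
        """Adjusted fiber separation for the tilted-fiber bevel workaround."""
        return self.df / math.cos(self.alpha_rad)


@dataclass(frozen=True)
class LayeredPhantomConfig:
    """Two-layer phantom: a top (cancellous-mimicking) layer of thickness dp
    above a cortical-mimicking half-space."""

    dp: float                          # probe-to-interface distance, mm
    top_props: OpticalProperties = field(default=None)
    bottom_props: OpticalProperties = field(default=None)

    def __post_init__(self):
        if self.dp < 0:
            raise ValueError("dp must be >= 0")


def _grid(resolution: float, grid_mm):
    if resolution <= 0:
        raise ValueError("resolution (bins/mm) must be > 0")
    shape = tuple(max(1, round(L * resolution)) for L in grid_mm)
    return shape, 1.0 / resolution


def _fibers(tip: TipConfig, grid_mm):
    """Emitter/collector placed symmetrically about the probe axis on the top face."""
    cx, cy = grid_mm[0] / 2.0, grid_mm[1] / 2.0
    if tip.design == "bevel":
        sep = tip.df_prime
        a = tip.alpha_rad
        axis = (math.sin(a), 0.0, math.cos(a))
    else:
        sep = tip.df
        axis = (0.0, 0.0, 1.0)
    emitter = FiberSpec(
        center=(cx - sep / 2.0, cy, 0.0), axis=axis,
        core_diameter=tip.core_diameter,
        numerical_aperture=tip.numerical_aperture, role="emitter",
    )
    collector = FiberSpec(
        center=(cx + sep / 2.0, cy, 0.0), axis=axis,
        core_diameter=tip.core_diameter,
        numerical_aperture=tip.numerical_aperture, role="collector",
    )
    return emitter, collector


def probe_radius(tip: TipConfig) -> float:
    """Default probe shaft radius: the tip spans both fiber cores plus a wall.

    The instrument tip is the shaped end of the probe shaft, so its radius
    covers the fiber separation, the cores, and a minimal wall outside the
    fiber channels: df/2 + core_diameter.  Used as the cone base radius and
    as the bevel-face extent; override via TipConfig.base_radius.
    """
    if tip.base_radius is not None:
        return tip.base_radius
    return tip.df / 2.0 + tip.core_diameter


#: retained name for the cone design
cone_base_radius = probe_radius


def build_blunt_scene(
    props: OpticalProperties,
    resolution: float = 25.0,
    grid_mm=DEFAULT_GRID_MM,
    tip: TipConfig | None = None,
) -> Scene:
    """Homogeneous medium, flat face, vertical fibers at separation df."""
    tip = tip or TipConfig("blunt")
    shape, vs = _grid(resolution, grid_mm)
    labels = np.zeros(shape, dtype=np.uint8)
    emitter, collector = _fibers(TipConfig("blunt", 0.0, tip.df,
                                           tip.core_diameter, tip.numerical_aperture),
                                 grid_mm)
    return Scene(
        voxel_labels=labels,
        material_table={MEDIUM: props},
        voxel_size=vs,
        emitter=emitter,
        collector=collector,
        tip_apex_depth=0.0,
        probe_tilt_deg=0.0,
        tip_reference=(grid_mm[0] / 2.0, 0.0),
        meta={"design": "blunt", "alpha_deg": 0.0, "df": tip.df, "grid_mm": tuple(grid_mm)},
    )


def build_cone_scene(
    tip: TipConfig,
    props: OpticalProperties,
    resolution: float = 25.0,
    grid_mm=DEFAULT_GRID_MM,
    tip_props: OpticalProperties = TIP_1211NM,
    fiber_channels: bool = True,
) -> Scene:
    """Absorbing-cone-tip scene (alpha = 0 degenerates to the blunt scene).

    The cone apex points downward; its depth is base_radius * tan(alpha).
    Voxels whose centers fall inside the cone get the fully absorbing tip
    material (same scattering and anisotropy as the medium).  With
    fiber_channels (default) the cone is bored through under each fiber so
    the beam enters the tissue, as in the physical probe.
    """
    if tip.design not in ("cone", "blunt"):
        raise ValueError("build_cone_scene requires a cone (or blunt) TipConfig")
    shape, vs = _grid(resolution, grid_mm)
    labels = np.zeros(shape, dtype=np.uint8)
    R = probe_radius(tip)
    apex = R * math.tan(tip.alpha_rad)
    if apex >= grid_mm[2]:
        raise ValueError(f"cone apex depth {apex:.2f} mm exceeds grid depth {grid_mm[2]} mm")
    if apex > 0:
        cx, cy = grid_mm[0] / 2.0, grid_mm[1] / 2.0
        nx, ny, nz = shape
        x = (np.arange(nx) + 0.5) * vs - cx
        y = (np.arange(ny) + 0.5) * vs - cy
        z = (np.arange(nz) + 0.5) * vs
        r_xy = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
        # cone radius shrinks linearly from R at the face to 0 at the apex
        cone_r = R * (1.0 - z / apex)
        inside = (z[None, None, :] < apex) & (r_xy[:, :, None] <= cone_r[None, None, :])
        if fiber_channels:
            # the fibers reach the tissue through cylindrical clearance
            # channels bored through the absorbing tip (one voxel of slack
            # so the discretized channel never occludes the core)
            chan_r = tip.core_diameter / 2.0 + vs
            for fx in (-tip.df / 2.0, tip.df / 2.0):
                chan = (x[:, None] - fx) ** 2 + y[None, :] ** 2 <= chan_r**2
                inside &= ~chan[:, :, None]
        labels[inside] = TIP
    emitter, collector = _fibers(tip, grid_mm)
    return Scene(
        voxel_labels=labels,
        material_table={MEDIUM: props, TIP: tip_props},
        voxel_size=vs,
        emitter=emitter,
        collector=collector,
        tip_apex_depth=apex,
        probe_tilt_deg=0.0,
        tip_reference=(grid_mm[0] / 2.0, apex),
        meta={"design": "cone", "alpha_deg": tip.alpha_deg, "df": tip.df,
              "base_radius": R, "grid_mm": tuple(grid_mm)},
    )


def build_bevel_scene(
    tip: TipConfig,
    props: OpticalProperties,
    resolution: float = 25.0,
    grid_mm=DEFAULT_GRID_MM,
) -> Scene:
    """Tilted-fiber single-bevel scene: flat face, no tip voxels.

    Both fiber axes tilt by alpha in the fiber (x-z) plane and the surface
    separation widens to df' = df / cos(alpha).  The simulated flat face
    represents the bevel face of the probe; the probe axis is tilted by
    alpha, and the probe's deepest structural point (the bevel heel, the rim
    of the elliptical face on the tilt side) is recorded as the probing-depth
    reference for the probe-frame depth transform.
    """
    if tip.design != "bevel":
        raise ValueError("build_bevel_scene requires a bevel TipConfig")
    shape, vs = _grid(resolution, grid_mm)
    labels = np.zeros(shape, dtype=np.uint8)
    emitter, collector = _fibers(tip, grid_mm)
    # the probing-depth reference is the collecting fiber's face position: in
    # the physical single-bevel probe that fiber sits at the instrument tip
    tip_x = collector.center[0]
    return Scene(
        voxel_labels=labels,
        material_table={MEDIUM: props},
        voxel_size=vs,
        emitter=emitter,
        collector=collector,
        tip_apex_depth=0.0,
        probe_tilt_deg=tip.alpha_deg,
        tip_reference=(tip_x, 0.0),
        meta={"design": "bevel", "alpha_deg": tip.alpha_deg, "df": tip.df,
              "df_prime": tip.df_prime, "grid_mm": tuple(grid_mm)},
    )


def build_two_layer_scene(
    cfg: LayeredPhantomConfig,
    tip: TipConfig,
    resolution: float = 25.0,
    grid_mm=DEFAULT_GRID_MM,
    tip_props: OpticalProperties = TIP_1211NM,
) -> Scene:
    """Two-layer phantom scene: top layer of thickness dp above a half-space.

    The probe (any tip design) sits on the top face; voxels below z = dp that
    are not tip material get the bottom-layer label.
    """
    if cfg.top_props is None or cfg.bottom_props is None:
        raise ValueError("LayeredPhantomConfig needs top_props and bottom_props")
    if cfg.dp > grid_mm[2]:
        raise ValueError(f"dp = {cfg.dp} mm exceeds grid depth {grid_mm[2]} mm")
    if tip.design == "bevel":
        scene = build_bevel_scene(tip, cfg.top_props, resolution, grid_mm)
    else:
        scene = build_cone_scene(tip, cfg.top_props, resolution, grid_mm,
                                 tip_props=tip_props)
    nz = scene.shape[2]
    vs = scene.voxel_size
    z_centers = (np.arange(nz) + 0.5) * vs
    below = z_centers >= cfg.dp
    mask = (scene.voxel_labels == MEDIUM) & below[None, None, :]
    scene.voxel_labels[mask] = BOTTOM_LAYER
    scene.material_table[BOTTOM_LAYER] = cfg.bottom_props
    scene.meta.update({"dp": cfg.dp, "layered": True})
    return scene


def build_scene(design: str, alpha_deg: float, props: OpticalProperties,
                resolution: float = 25.0, grid_mm=DEFAULT_GRID_MM,
                df: float = 1.4, **kw) -> Scene:
    """Convenience dispatcher used by sweeps and the CLI."""
    if design == "blunt" or (design == "cone" and alpha_deg == 0):
        return build_blunt_scene(props, resolution, grid_mm, TipConfig("blunt", 0.0, df))
    if design == "cone":
        return build_cone_scene(TipConfig("cone", alpha_deg, df, **kw), props,
                                resolution, grid_mm)
    if design == "bevel":
        return build_bevel_scene(TipConfig("bevel", alpha_deg, df, **kw), props,
                                 resolution, grid_mm)
    raise ValueError(f"unknown design {design!r}")
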