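"""Voxelized Monte Carlo photon-packet transport with fiber source/detector.

The engine launches weighted photon packets from an emitting fiber (top-hat
beam profile, top-hat divergence up to the NA cone), propagates them through a
voxel grid with per-voxel optical properties (discrete-albedo weight
deposition, Henyey-Greenstein scattering, Russian roulette), and detects
packets escaping the top face within the collecting fiber's core and
acceptance cone.

All geometry is in mm; the grid origin is the top-face corner, with z
increasing downward into the medium.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .optics import OpticalProperties

log = logging.getLogger(__name__)

__all__ = [
    "FiberSpec",
    "Scene",
    "PhotonRecord",
    "SimulationResult",
    "sample_step_length",
    "sample_hg_cosine",
    "launch_beam",
    "detect_photon",
    "propagate_photon",
    "run_simulation",
    "normalize_fluence",
]

#: Russian-roulette weight threshold and survivor probability (MCML convention).
WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVE_P = 0.1
#: Safety cap on interaction events per photon.
MAX_EVENTS = 1_000_000


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector cannot be normalized")
    return v / n


def _orthonormal_basis(axis: np.ndarray):
    """Two unit vectors spanning the plane normal to `axis`."""
    a = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, helper))
    e2 = np.cross(a, e1)
    return e1, e2


@dataclass(frozen=True)
class FiberSpec:
    """One optical fiber: position, orientation, core size, numerical aperture."""

    center: tuple          # (x, y, z) mm
    axis: tuple            # unit vector, points into the medium for both roles
    core_diameter: float = 0.2   # mm
    numerical_aperture: float = 0.22
    role: str = "emitter"        # "emitter" | "collector"

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        if not math.isclose(float(np.linalg.norm(ax)), 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError("fiber axis must be a unit vector")
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("numerical aperture must be in (0, 1)")
        if self.core_diameter <= 0:
            raise ValueError("core diameter must be > 0")
        if self.role not in ("emitter", "collector"):
            raise ValueError(f"unknown fiber role {self.role!r}")

    @property
    def core_radius(self) -> float:
        return self.core_diameter / 2.0

    @property
    def half_angle(self) -> float:
        """Emission/acceptance half-angle arcsin(NA), radians."""
        return math.asin(self.numerical_aperture)


@dataclass
class Scene:
    """Voxel label grid + material table + fiber pair + tip reference depth."""

    voxel_labels: np.ndarray                 # (nx, ny, nz) uint8
    material_table: dict                     # label -> OpticalProperties
    voxel_size: float                        # mm
    emitter: FiberSpec
    collector: FiberSpec
    tip_apex_depth: float = 0.0              # mm below the fiber plane; 0 for blunt
    probe_tilt_deg: float = 0.0              # probe-axis tilt vs the face normal
    tip_reference: tuple | None = None       # (x, z) mm of the probe's deepest point
    refractive_index: float = 1.0            # relative to outside; 1 = matched (no Fresnel)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxel_labels = np.ascontiguousarray(self.voxel_labels, dtype=np.uint8)
        if self.voxel_labels.ndim != 3 or min(self.voxel_labels.shape) < 1:
            raise ValueError("voxel_labels must be a non-empty 3D grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        present = set(np.unique(self.voxel_labels).tolist())
        missing = present - set(self.material_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from material_table")

    @property
    def shape(self):
        return self.voxel_labels.shape

    @property
    def extent_mm(self):
        return tuple(n * self.voxel_size for n in self.shape)

    def coefficient_tables(self):
        """Per-label (mu_a, mu_t, g) arrays in mm^-1 for the transport kernel."""
        n = max(self.material_table) + 1
        mua = np.zeros(n)
        mut = np.zeros(n)
        g = np.zeros(n)
        for lbl, props in self.material_table.items():
            mua[lbl] = props.mu_a_mm
            mut[lbl] = props.mu_t_mm
            g[lbl] = props.g
        return mua, mut, g


@dataclass
class PhotonRecord:
    """Full event path of one photon packet (positions in mm) plus exit state."""

    path: np.ndarray           # (n_points, 3)
    weights: np.ndarray        # (n_points,) packet weight on leaving each point
    exit_direction: np.ndarray
    weight_at_exit: float
    detected: bool

    def __post_init__(self):
        if self.path.shape[0] < 2:
            raise ValueError("a photon path needs at least launch and exit points")
        if not 0 < self.weight_at_exit <= 10.0:
            # roulette-boosted survivors may exceed 1; plain packets stay in (0, 1]
            raise ValueError(f"implausible exit weight {self.weight_at_exit}")


@dataclass
class SimulationResult:
    """Raw output of one transport run."""

    fluence: np.ndarray            # deposited weight per voxel (not yet normalized)
    n_launched: int
    n_detected: int
    seed: int
    ledger: dict                   # weight bookkeeping, see run_simulation
    paths: np.ndarray              # (n_points_total, 4): x, y, z, weight
    path_offsets: np.ndarray       # (n_stored + 1,)
    record_info: np.ndarray        # (n_stored, 8): exit pos, exit dir, weight, detected
    scene: Scene

    @property
    def n_stored(self) -> int:
        return len(self.path_offsets) - 1

    def detected_records(self):
        """Materialize PhotonRecord objects for stored detected photons."""
        out = []
        for k in range(self.n_stored):
            if self.record_info[k, 7] < 0.5:
                continue
            lo, hi = self.path_offsets[k], self.path_offsets[k + 1]
            out.append(
                PhotonRecord(
                    path=self.paths[lo:hi, :3],
                    weights=self.paths[lo:hi, 3],
                    exit_direction=self.record_info[k, 3:6].copy(),
                    weight_at_exit=float(self.record_info[k, 6]),
                    detected=True,
                )
            )
        return out


# ---------------------------------------------------------------------------
# elementary sampling operations (exposed for testing; the kernel inlines them)

def sample_step_length(xi: float, mu_t: float) -> float:
    """Exponential free-path sample -ln(xi)/mu_t (mm, mu_t per mm)."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0 for a finite free path")
    if not 0 < xi < 1:
        raise ValueError("xi must lie in (0, 1)")
    return -math.log(xi) / mu_t


def sample_hg_cosine(xi, g: float):
    """Henyey-Greenstein scattering-cosine inverse CDF; vectorized over xi."""
    if not abs(g) < 1:
        raise ValueError("|g| must be < 1")
    xi = np.asarray(xi, dtype=float)
    if np.any((xi <= 0) | (xi >= 1)):
        raise ValueError("xi must lie in (0, 1)")
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return np.clip((1.0 + g * g - t * t) / (2.0 * g), -1.0, 1.0)


def launch_beam(emitter: FiberSpec, rng: np.random.Generator, n: int = 1):
    """Sample launch positions and directions of the top-hat fiber beam.

    Positions are uniform on the fiber-core disc (in the plane normal to the
    fiber axis, slid along the axis onto the z=0 entry face); directions are
    uniform in solid angle within the half-angle arcsin(NA) about the axis.
    Returns (positions (n,3), directions (n,3)).
    """
    ax = np.asarray(emitter.axis, dtype=float)
    e1, e2 = _orthonormal_basis(ax)
    u1 = rng.random(n)
    u2 = rng.random(n)
    r = emitter.core_radius * np.sqrt(u1)
    ang = 2 * np.pi * u2
    pos = (np.asarray(emitter.center, dtype=float)[None, :]
           + r[:, None] * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2))
    if abs(ax[2]) > 1e-12:
        t = -pos[:, 2] / ax[2]
        pos = pos + t[:, None] * ax
    cos_max = math.cos(emitter.half_angle)
    ct = 1.0 - rng.random(n) * (1.0 - cos_max)
    st = np.sqrt(np.clip(1 - ct**2, 0, None))
    psi = 2 * np.pi * rng.random(n)
    dirs = (ct[:, None] * ax
            + st[:, None] * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2))
    return pos, dirs


def detect_photon(record: PhotonRecord, collector: FiberSpec) -> bool:
    """NA-gated fiber detection of an escaped photon.

    True iff the exit point lies within the core radius of the collector
    center measured in the plane normal to the collector axis, and the exit
    direction is within arcsin(NA) of the reversed collector axis.
    """
    exit_point = np.asarray(record.path[-1], dtype=float)
    delta = exit_point - np.asarray(collector.center, dtype=float)
    ax = np.asarray(collector.axis, dtype=float)
    dot = float(delta @ ax)
    dperp = math.sqrt(max(0.0, float(delta @ delta) - dot * dot))
    if dperp > collector.core_radius:
        return False
    cos_angle = float(-np.asarray(record.exit_direction, dtype=float) @ ax)
    return cos_angle >= math.cos(collector.half_angle)


# ---------------------------------------------------------------------------
# full simulation driver

def _safe_distance(scene: Scene) -> np.ndarray:
    """Per-voxel radius of the largest sphere guaranteed to contain only the
    voxel's own material and to stay inside the grid (jump acceleration)."""
    from scipy.ndimage import distance_transform_edt

    labels = scene.voxel_labels
    vs = scene.voxel_size
    nx, ny, nz = labels.shape
    out = np.zeros(labels.shape)
    for lbl in np.unique(labels):
        mask = labels == lbl
        if mask.all():
            out[:] = 1e30
            break
        d = distance_transform_edt(mask, sampling=vs)
        out[mask] = d[mask]
    # distance from the voxel center to the nearest grid face
    fx = np.minimum(np.arange(nx) + 0.5, nx - 0.5 - np.arange(nx)) * vs
    fy = np.minimum(np.arange(ny) + 0.5, ny - 0.5 - np.arange(ny)) * vs
    fz = np.minimum(np.arange(nz) + 0.5, nz - 0.5 - np.arange(nz)) * vs
    face = np.minimum(np.minimum(fx[:, None, None], fy[None, :, None]), fz[None, None, :])
    out = np.minimum(out, face)
    # photon may sit anywhere in its voxel; obstacles fill theirs: one diagonal margin
    out -= math.sqrt(3.0) * vs
    return np.ascontiguousarray(np.clip(out, 0.0, None), dtype=np.float32)


def _kernel_args(scene: Scene):
    mua, mut, g = scene.coefficient_tables()
    em, col = scene.emitter, scene.collector
    em_ax = _unit(em.axis)
    e1, e2 = _orthonormal_basis(em_ax)
    safe = scene.meta.get("_safe_dist")
    if safe is None or safe.shape != scene.shape:
        safe = _safe_distance(scene)
        scene.meta["_safe_dist"] = safe
    n_rel = float(scene.refractive_index)
    em_cos = math.cos(em.half_angle)
    if n_rel > 1.0:
        # in-medium divergence narrows by Snell's law at the fiber-tissue face
        em_cos = math.cos(math.asin(em.numerical_aperture / n_rel))
    return dict(
        labels=scene.voxel_labels,
        safe=safe,
        n_rel=n_rel,
        mua=mua, mut=mut, g_tab=g, vs=float(scene.voxel_size),
        em_pos=np.asarray(em.center, dtype=float), em_ax=em_ax,
        em_e1=e1, em_e2=e2, em_r=em.core_radius,
        cos_em_max=em_cos,
        col_pos=np.asarray(col.center, dtype=float), col_ax=_unit(col.axis),
        col_r=col.core_radius, cos_col_max=math.cos(col.half_angle),
    )


def run_simulation(
    scene: Scene,
    n_photons: int,
    seed: int,
    keep_paths: str = "detected",
    weight_threshold: float = WEIGHT_THRESHOLD,
    roulette_survive_p: float = ROULETTE_SURVIVE_P,
    max_events: int = MAX_EVENTS,
) -> SimulationResult:
    """Run the voxel Monte Carlo and return fluence, detections, and ledger.

    Reproducible: identical (scene, n_photons, seed) give bit-identical
    results, independent of path-buffer sizing, because every photon owns a
    counter-based random stream.

    keep_paths: "detected" (default), "all" (debug, small n only), or "none".
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    store_mode = {"none": 0, "detected": 1, "all": 2}[keep_paths]
    args = _kernel_args(scene)

    scratch = np.empty((min(max_events, 2_000_000) + 2, 4))
    cap_pts = 2_000_000 if store_mode else 2
    cap_rec = min(200_000, max(1024, n_photons)) if store_mode else 1

    while True:
        fluence = np.zeros(scene.shape)
        path_buf = np.empty((cap_pts, 4))
        path_off = np.zeros(cap_rec + 1, dtype=np.int64)
        rec_info = np.empty((cap_rec, 8))
        (n_det, n_stored, pts_used, pts_needed, overflow,
         dep, esc, detw, lost_roulette, lost_cap, n_capped) = _kernel.run_transport(
            args["labels"], args["mua"], args["mut"], args["g_tab"], args["vs"],
            args["safe"],
            args["em_pos"], args["em_ax"], args["em_e1"], args["em_e2"],
            args["em_r"], args["cos_em_max"],
            args["col_pos"], args["col_ax"], args["col_r"], args["cos_col_max"],
            args["n_rel"],
            n_photons, seed, weight_threshold, roulette_survive_p, max_events,
            store_mode, fluence, scratch, path_buf, path_off, rec_info,
        )
        if not overflow:
            break
        # deterministic rerun with buffers sized from the measured requirement
        cap_pts = max(cap_pts, int(pts_needed * 1.05) + 1024)
        cap_rec = max(cap_rec, n_det + (0 if store_mode == 1 else n_photons - n_det) + 16)

    if n_capped:
        log.warning("%d photons hit the %d-event safety cap and were excluded "
                    "from detection", n_capped, max_events)
    log.info("run_simulation: launched=%d detected=%d deposited=%.4g escaped=%.4g",
             n_photons, n_det, dep, esc)
    ledger = {
        "launched": float(n_photons),
        "deposited": dep,
        "escaped_undetected": esc,
        "detected": detw,
        "roulette_lost": lost_roulette,
        "event_cap_lost": lost_cap,
        "n_event_capped": int(n_capped),
    }
    return SimulationResult(
        fluence=fluence,
        n_launched=n_photons,
        n_detected=int(n_det),
        seed=int(seed),
        ledger=ledger,
        paths=path_buf[:pts_used].copy(),
        path_offsets=path_off[: n_stored + 1].copy(),
        record_info=rec_info[:n_stored].copy(),
        scene=scene,
    )


def propagate_photon(scene: Scene, seed: int, photon_index: int = 0) -> PhotonRecord:
    """Trace a single photon packet and return its full event path (debug aid).

    Equivalent to photon `photon_index` of a run_simulation call with the same
    seed.
    """
    res = run_simulation(scene, photon_index + 1, seed, keep_paths="all")
    k = photon_index
    lo, hi = res.path_offsets[k], res.path_offsets[k + 1]
    info = res.record_info[k]
    return PhotonRecord(
        path=res.paths[lo:hi, :3],
        weights=res.paths[lo:hi, 3],
        exit_direction=info[3:6].copy(),
        weight_at_exit=float(max(info[6], 1e-300)),
        detected=bool(info[7] > 0.5),
    )


def normalize_fluence(result: SimulationResult, scene: Scene | None = None) -> np.ndarray:
    """Normalized fluence rate: deposited weight / (input power x voxel volume x mu_a).

    Voxels of zero absorption map to 0 by convention.
    """
    scene = scene or result.scene
    mua, _, _ = scene.coefficient_tables()
    mua_grid = mua[scene.voxel_labels]
    v = scene.voxel_size**3
    out = np.zeros_like(result.fluence)
    nz = mua_grid > 0
    out[nz] = result.fluence[nz] / (result.n_launched * v * mua_grid[nz])
    return out
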