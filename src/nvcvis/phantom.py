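"""Synthetic paired CISS-like / TOF-like volumes with ground truth.

The phantom emulates the anatomy and the three artifact classes needed to
exercise every downstream stage without clinical data:

* a brainstem-like elliptical cylinder surrounded by a bright CSF shell
  (CISS contrast: hyperintense CSF, hypointense nerves/vessels/brainstem);
* a large vessel trunk running through the cistern (vertebral/basilar
  analogue) and a brainstem-hugging arterial loop (PICA analogue);
* a short nerve tube leaving the brainstem radially (root-entry-zone
  analogue);
* flow-void arcs that attenuate CISS vessel signal toward the brainstem
  mean, CSF pulsation speckle near the trunk, and a rigid offset applied to
  the TOF acquisition.

All geometry is defined by continuous membership functions so the displaced
TOF grid can be rasterized exactly, and all randomness flows through one
seeded generator (same seed => bytewise identical volumes).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree

from .registration import RigidTransform
from .volumes_io import Modality, Volume

__all__ = ["PhantomSpec", "GroundTruth", "generate", "contact_phantom"]

_CLASSES = ("background", "csf", "brainstem", "nerve", "vessel")


@dataclass
class PhantomSpec:
    """Geometry, contrast, artifact and noise parameters of one phantom."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 0.4  # mm, isotropic

    # class intensity means per modality
    ciss_means: dict[str, float] = field(
        default_factory=lambda: {
            "background": 100.0,
            "csf": 1000.0,
            "brainstem": 520.0,
            "nerve": 330.0,
            "vessel": 300.0,
        }
    )
    tof_means: dict[str, float] = field(
        default_factory=lambda: {
            "background": 80.0,
            "csf": 150.0,
            "brainstem": 200.0,
            "nerve": 200.0,
            "vessel": 1000.0,
        }
    )
    ciss_sigma: float = 12.0
    tof_sigma: float = 12.0
    rician: bool = False

    # anatomy (fractions of grid extent unless noted)
    brainstem_center: tuple[float, float] = (0.45, 0.60)
    brainstem_radii: tuple[float, float] = (0.16, 0.18)
    # ventral bend of the brainstem axis (fractions of grid extent); breaks
    # the rotational near-symmetry a straight cylinder would have
    brainstem_bend: tuple[float, float] = (0.05, -0.03)
    csf_outer: float = 1.75  # outer CSF boundary, multiples of brainstem radii
    # azimuthal modulation of the outer CSF boundary (amplitude, phase rad);
    # phase keeps the cistern widest around the trunk
    csf_outer_mod: tuple[float, float] = (0.12, -1.92)

    trunk_radius: float = 0.045  # fraction of axis-0 extent
    loop_radius: float = 0.026
    nerve_radius: float = 0.022
    trunk_angle_deg: float = -110.0
    nerve_angle_deg: float = -60.0
    nerve_z: float = 0.45  # fraction of axis-2 extent
    loop_radial: float = 1.15  # elliptical radius of the loop arc
    loop_dz: float | None = None  # voxels above the nerve plane; None => +6

    # explicit centerline control points (voxel coords) override the defaults
    trunk_points: np.ndarray | None = None
    loop_points: np.ndarray | None = None
    nerve_points: np.ndarray | None = None

    # artifacts
    flow_void: tuple[tuple[str, float, float, float], ...] = (
        ("trunk", 0.35, 0.75, 1.0),
    )  # (vessel name, arc start, arc end in [0,1], attenuation factor)
    pulsation: dict | None = field(
        default_factory=lambda: {
            "box_lo": (0.20, 0.10, 0.55),
            "box_hi": (0.70, 0.55, 0.90),
            "density": 0.03,
            "amplitude": 680.0,
        }
    )

    # rigid offset of the TOF acquisition (moving -> fixed world transform)
    tof_rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tof_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        cm, tm = self.ciss_means, self.tof_means
        others = [cm["nerve"], cm["vessel"], cm["brainstem"], cm["background"]]
        if not all(cm["csf"] > m for m in others):
            raise ValueError("CISS contrast requires CSF mean above all other classes")
        if not all(tm["vessel"] > m for k, m in tm.items() if k != "vessel"):
            raise ValueError("TOF contrast requires vessel mean above all other classes")
        for name in ("trunk_radius", "loop_radius", "nerve_radius"):
            r = getattr(self, name) * self.shape[0]
            if r >= min(self.shape) / 2:
                raise ValueError(f"{name} must be below half the grid extent")
        for pts_name in ("trunk_points", "loop_points", "nerve_points"):
            pts = getattr(self, pts_name)
            if pts is not None and len(np.atleast_2d(pts)) < 2:
                raise ValueError(f"degenerate centerline: {pts_name} needs >= 2 points")

    # radii in voxels (clamped so tubes stay rasterizable on small grids)
    def radius_vox(self, name: str) -> float:
        frac = {"trunk": self.trunk_radius, "loop": self.loop_radius,
                "nerve": self.nerve_radius}[name]
        return max(frac * self.shape[0], 1.4)

    def true_rigid(self) -> RigidTransform:
        center_vox = (np.asarray(self.shape, float) - 1) / 2
        center_mm = center_vox * self.spacing
        return RigidTransform.from_params(
            np.asarray(self.tof_rot_deg), np.asarray(self.tof_shift_mm), center_mm
        )


@dataclass
class GroundTruth:
    """Oracle data accompanying one generated phantom pair."""

    masks: dict[str, np.ndarray]  # per-class + per-vessel boolean masks
    centerlines: dict[str, np.ndarray]  # ordered integer voxel paths
    true_rigid: RigidTransform
    contact: bool
    contact_voxels: np.ndarray  # (K, 3) vessel-side voxels at the interface
    flow_void_masks: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _axis_center(spec: PhantomSpec, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Brainstem axis position at height z (bent ventrally along z)."""
    nx, ny, nz = spec.shape
    phase = np.sin(np.pi * np.asarray(z, float) / (nz - 1))
    cx = spec.brainstem_center[0] * nx + spec.brainstem_bend[0] * nx * phase
    cy = spec.brainstem_center[1] * ny + spec.brainstem_bend[1] * ny * phase
    return cx, cy


def _ellipse_point(spec: PhantomSpec, r: np.ndarray, theta: np.ndarray,
                   z: np.ndarray) -> np.ndarray:
    nx, ny, _ = spec.shape
    cx, cy = _axis_center(spec, z)
    a, b = spec.brainstem_radii[0] * nx, spec.brainstem_radii[1] * ny
    return np.stack([cx + a * r * np.cos(theta), cy + b * r * np.sin(theta), z], axis=-1)


def _spline_through(points: np.ndarray, n: int = 600) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) < 2:
        raise ValueError("degenerate centerline: need >= 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0:
        raise ValueError("degenerate centerline: coincident points")
    t /= t[-1]
    k = min(3, len(pts) - 1)
    spl = make_interp_spline(t, pts, k=k)
    return spl(np.linspace(0.0, 1.0, n))


def _centerlines(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Dense centerline polylines in voxel coordinates of the fixed grid."""
    nz = spec.shape[2]
    n = 600
    s = np.linspace(0.0, 1.0, n)

    if spec.trunk_points is not None:
        trunk = _spline_through(spec.trunk_points, n)
    else:
        z = (0.06 + 0.88 * s) * (nz - 1)
        theta = np.deg2rad(spec.trunk_angle_deg + 14.0 * np.sin(2 * np.pi * s))
        r = 1.40 + 0.05 * np.sin(4 * np.pi * s)
        trunk = _ellipse_point(spec, r, theta, z)

    loop_dz = 6.0 if spec.loop_dz is None else float(spec.loop_dz)
    if spec.loop_points is not None:
        loop = _spline_through(spec.loop_points, n)
    else:
        theta = np.deg2rad(spec.nerve_angle_deg + np.linspace(-70.0, 70.0, n))
        z = np.full(n, spec.nerve_z * (nz - 1) + loop_dz)
        r = np.full(n, spec.loop_radial)
        loop = _ellipse_point(spec, r, theta, z)

    if spec.nerve_points is not None:
        nerve = _spline_through(spec.nerve_points, n)
    else:
        r = 0.85 + 0.75 * s
        theta = np.full(n, np.deg2rad(spec.nerve_angle_deg))
        z = np.full(n, spec.nerve_z * (nz - 1))
        nerve = _ellipse_point(spec, r, theta, z)

    return {"trunk": trunk, "loop": loop, "nerve": nerve}


class _Geometry:
    """Continuous class-membership evaluator over voxel coordinates."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.centerlines = _centerlines(spec)
        self.trees = {k: cKDTree(v) for k, v in self.centerlines.items()}

    def tube_fields(self, pts: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per tube: (inside mask, nearest-centerline parameter in [0,1])."""
        out = {}
        for name in ("trunk", "loop", "nerve"):
            dist, idx = self.trees[name].query(pts, workers=-1)
            inside = dist <= self.spec.radius_vox(name)
            out[name] = (inside, idx / (len(self.centerlines[name]) - 1))
        return out

    def elliptical_coords(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Elliptical radius and azimuth relative to the (bent) brainstem axis."""
        nx, ny, _ = self.spec.shape
        cx, cy = _axis_center(self.spec, pts[:, 2])
        a, b = self.spec.brainstem_radii[0] * nx, self.spec.brainstem_radii[1] * ny
        u = (pts[:, 0] - cx) / a
        w = (pts[:, 1] - cy) / b
        return np.sqrt(u * u + w * w), np.arctan2(w, u)

    def classify(self, pts: np.ndarray) -> tuple[np.ndarray, dict]:
        """Class index per point (priority vessel > nerve > brainstem > CSF)."""
        tubes = self.tube_fields(pts)
        r_e, theta = self.elliptical_coords(pts)
        amp, phase = self.spec.csf_outer_mod
        outer = self.spec.csf_outer * (1.0 + amp * np.cos(theta - phase))
        cls = np.zeros(len(pts), dtype=np.uint8)  # background
        cls[r_e <= outer] = _CLASSES.index("csf")
        cls[r_e <= 1.0] = _CLASSES.index("brainstem")
        cls[tubes["nerve"][0]] = _CLASSES.index("nerve")
        vessel = tubes["trunk"][0] | tubes["loop"][0]
        cls[vessel] = _CLASSES.index("vessel")
        return cls, tubes


def _grid_points(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)


def _centerline_voxels(poly: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    vox = np.round(poly).astype(int)
    ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
    vox = vox[ok]
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(np.diff(vox, axis=0) != 0, axis=1)
    return vox[keep]


def _add_noise(rng: np.random.Generator, data: np.ndarray, sigma: float,
               rician: bool) -> np.ndarray:
    if sigma <= 0:
        return data
    if rician:
        n1 = rng.normal(0.0, sigma, data.shape)
        n2 = rng.normal(0.0, sigma, data.shape)
        return np.sqrt((data + n1) ** 2 + n2**2)
    return data + rng.normal(0.0, sigma, data.shape)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(spec: PhantomSpec) -> tuple[Volume, Volume, GroundTruth]:
    """Generate (ciss, tof, truth) for ``spec``; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    geo = _Geometry(spec)
    shape = spec.shape
    pts = _grid_points(shape)

    # ---- fixed (CISS) grid classification + truth masks ----
    cls, tubes = geo.classify(pts)
    cls_grid = cls.reshape(shape)
    masks = {name: cls_grid == i for i, name in enumerate(_CLASSES)}
    for name in ("trunk", "loop"):
        inside, _ = tubes[name]
        masks[name] = inside.reshape(shape) & masks["vessel"]

    ciss_means = np.array([spec.ciss_means[c] for c in _CLASSES])
    ciss = ciss_means[cls].reshape(shape).astype(float)

    # ---- flow void: pull CISS vessel signal toward the brainstem mean ----
    flow_void_masks: dict[str, np.ndarray] = {}
    bs_mean = spec.ciss_means["brainstem"]
    v_mean = spec.ciss_means["vessel"]
    for name, t0, t1, factor in spec.flow_void:
        inside, t_par = tubes[name]
        affected = (inside & (t_par >= t0) & (t_par <= t1)).reshape(shape)
        affected &= masks[name]
        ciss[affected] = (1.0 - factor) * v_mean + factor * bs_mean
        flow_void_masks[name] = flow_void_masks.get(name, np.zeros(shape, bool)) | affected

    # ---- pulsation speckle in CSF near the trunk ----
    if spec.pulsation:
        p = spec.pulsation
        lo = np.floor(np.asarray(p["box_lo"]) * np.asarray(shape)).astype(int)
        hi = np.ceil(np.asarray(p["box_hi"]) * np.asarray(shape)).astype(int)
        box = np.zeros(shape, bool)
        box[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]] = True
        candidates = np.flatnonzero((box & masks["csf"]).ravel())
        k = int(len(candidates) * float(p["density"]))
        if k > 0:
            chosen = rng.choice(candidates, size=k, replace=False)
            flat = ciss.ravel()
            flat[chosen] = spec.ciss_means["csf"] - float(p["amplitude"])
            ciss = flat.reshape(shape)

    ciss = _add_noise(rng, ciss, spec.ciss_sigma, spec.rician)

    # ---- TOF on a rigidly displaced grid ----
    T = spec.true_rigid()
    affine = np.diag([spec.spacing] * 3 + [1.0])
    world = pts * spec.spacing
    fixed_world = T.apply(world)  # TOF voxel -> its anatomy location
    fixed_vox = fixed_world / spec.spacing
    tof_cls, _ = geo.classify(fixed_vox)
    tof_means = np.array([spec.tof_means[c] for c in _CLASSES])
    tof = tof_means[tof_cls].reshape(shape).astype(float)
    tof = _add_noise(rng, tof, spec.tof_sigma, spec.rician)

    # ---- centerlines + contact ----
    centerlines = {
        name: _centerline_voxels(poly, shape) for name, poly in geo.centerlines.items()
    }
    contact_voxels = _contact_voxels(masks["vessel"], masks["nerve"])

    truth = GroundTruth(
        masks=masks,
        centerlines=centerlines,
        true_rigid=T,
        contact=len(contact_voxels) > 0,
        contact_voxels=contact_voxels,
        flow_void_masks=flow_void_masks,
    )
    ciss_vol = Volume(ciss, (spec.spacing,) * 3, affine.copy(), Modality.CISS)
    tof_vol = Volume(tof, (spec.spacing,) * 3, affine.copy(), Modality.TOF)
    return ciss_vol, tof_vol, truth


def _contact_voxels(vessel: np.ndarray, nerve: np.ndarray) -> np.ndarray:
    struct = np.ones((3, 3, 3), bool)
    interface = vessel & ndimage.binary_dilation(nerve, structure=struct)
    return np.argwhere(interface)


def contact_phantom(
    spec: PhantomSpec, touching: bool
) -> tuple[Volume, Volume, GroundTruth]:
    """Phantom variant controlling vessel-nerve contact at the REZ.

    ``touching=True`` routes the loop so its tube shares a 26-neighborhood
    interface with the nerve tube (no CSF in between); ``touching=False``
    leaves a CSF layer of at least 2 voxels.
    """
    r_sum = spec.radius_vox("loop") + spec.radius_vox("nerve")
    dz = r_sum - 1.0 if touching else r_sum + 4.0
    return generate(replace(spec, loop_dz=dz, loop_points=None))
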