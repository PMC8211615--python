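"""Rigid CISS<->TOF alignment.

Landmark initialization (closed-form SVD fit), mutual-information refinement
over a Gaussian resolution pyramid with a derivative-free optimizer, and
trilinear reformatting of the moving volume onto the fixed grid.

Transform convention: a :class:`RigidTransform` maps **moving-world** points
into **fixed-world** coordinates, ``p_fixed = R @ p_moving + t``.  Resampling
the moving volume on the fixed grid therefore pulls intensities through the
inverse transform.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .volumes_io import Volume

__all__ = [
    "RigidTransform",
    "MIOptions",
    "RegistrationResult",
    "landmark_rigid",
    "mutual_information",
    "register",
    "reformat",
    "gaussian_pyramid",
]


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rotation + translation acting on world-mm coordinates."""

    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # 3, mm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(
        cls,
        rotvec_deg: np.ndarray,
        shift_mm: np.ndarray,
        center: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Build from an axis-angle rotation (degrees) about ``center``."""
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        c = np.zeros(3) if center is None else np.asarray(center, float)
        t = c + np.asarray(shift_mm, float) - R @ c
        return cls(R, t)

    def params(self, center: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`from_params` for the same ``center``."""
        c = np.zeros(3) if center is None else np.asarray(center, float)
        rotvec = Rotation.from_matrix(self.rotation).as_rotvec(degrees=True)
        shift = self.translation + self.rotation @ c - c
        return rotvec, shift

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, float)
        return cls(m[:3, :3], m[:3, 3])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        return float(
            np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec(degrees=True))
        )


@dataclass
class MIOptions:
    """Knobs for mutual-information estimation and optimization."""

    bins: int = 64
    pyramid_levels: int = 3
    sampling: float = 0.25  # fraction of fixed voxels sampled at finest level
    max_iter: int = 100
    xtol: float = 1e-3
    ftol: float = 1e-5
    seed: int = 0
    normalized: bool = False
    dense_threshold: int = 40_000  # sample everything below this voxel count
    max_samples: int = 200_000
    # Capture range: the coarsest level scans a rotation grid of
    # +/- grid_span_deg (step grid_step_deg) per axis around the init before
    # the local search, to avoid spurious coarse-scale MI maxima.
    grid_span_deg: float = 8.0
    grid_step_deg: float = 4.0

    def __post_init__(self) -> None:
        if self.bins < 8:
            raise ValueError("bins must be >= 8")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if not 0 < self.sampling <= 1:
            raise ValueError("sampling must be in (0, 1]")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    mi: float
    mi_init: float
    converged: bool
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# Landmark initialization
# ---------------------------------------------------------------------------


def landmark_rigid(fixed_pts: np.ndarray, moving_pts: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping moving points onto fixed points.

    Closed form via the SVD of the cross-covariance (Kabsch/Umeyama without
    scaling); the rotation determinant is constrained to +1.
    """
    f = np.atleast_2d(np.asarray(fixed_pts, float))
    m = np.atleast_2d(np.asarray(moving_pts, float))
    if f.shape != m.shape or f.shape[1] != 3:
        raise ValueError("landmark sets must be matching (N, 3) arrays")
    if len(f) < 3:
        raise ValueError("at least 3 landmark pairs required")
    fc, mc = f.mean(axis=0), m.mean(axis=0)
    fm, mm = f - fc, m - mc
    # Non-collinearity: the centered moving set must span a plane.
    sv = np.linalg.svd(mm, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate landmark set (collinear points)")
    H = mm.T @ fm
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = fc - R @ mc
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _joint_mi_bits(
    f_vals: np.ndarray,
    m_vals: np.ndarray,
    bins: int,
    f_range: tuple[float, float],
    m_range: tuple[float, float],
    normalized: bool = False,
) -> float:
    fi = _digitize(f_vals, f_range, bins)
    mi_ = _digitize(m_vals, m_range, bins)
    joint = np.bincount(fi * bins + mi_, minlength=bins * bins).astype(float)
    joint /= joint.sum()
    joint = joint.reshape(bins, bins)
    hf = _entropy_bits(joint.sum(axis=1))
    hm = _entropy_bits(joint.sum(axis=0))
    hj = _entropy_bits(joint.ravel())
    if normalized:
        return (hf + hm) / hj if hj > 0 else 2.0
    return hf + hm - hj


def _parzen_mi_bits(
    f_vals: np.ndarray,
    m_vals: np.ndarray,
    bins: int,
    f_range: tuple[float, float],
    m_range: tuple[float, float],
) -> float:
    """MI from a linearly Parzen-smoothed joint histogram.

    Each sample spreads bilinear weight over the four neighboring bin pairs,
    which makes the estimate differentiable in the sample values and keeps
    derivative-free optimizers from stalling on bin-crossing ripples.  Used
    as the internal optimization objective only; the public
    :func:`mutual_information` keeps the exact hard-binned histogram.
    """

    def soft(vals: np.ndarray, rng: tuple[float, float]):
        lo, hi = rng
        u = np.zeros_like(vals) if hi <= lo else (vals - lo) / (hi - lo) * bins - 0.5
        u = np.clip(u, 0.0, bins - 1.0)
        i0 = np.floor(u).astype(np.intp)
        i0 = np.minimum(i0, bins - 2)
        w1 = u - i0
        return i0, 1.0 - w1, w1

    fi, fw0, fw1 = soft(f_vals, f_range)
    mi_, mw0, mw1 = soft(m_vals, m_range)
    joint = np.zeros(bins * bins)
    for di, fw in ((0, fw0), (1, fw1)):
        for dj, mw in ((0, mw0), (1, mw1)):
            joint += np.bincount(
                (fi + di) * bins + (mi_ + dj), weights=fw * mw, minlength=bins * bins
            )
    joint /= joint.sum()
    joint = joint.reshape(bins, bins)
    return (
        _entropy_bits(joint.sum(axis=1))
        + _entropy_bits(joint.sum(axis=0))
        - _entropy_bits(joint.ravel())
    )


def _digitize(vals: np.ndarray, rng: tuple[float, float], bins: int) -> np.ndarray:
    lo, hi = rng
    if hi <= lo:
        return np.zeros(len(vals), dtype=np.intp)
    idx = ((vals - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def _sample_indices(
    shape: tuple[int, int, int], opt: MIOptions, level_scale: int = 1
) -> np.ndarray:
    """Deterministic voxel-index sample of the fixed grid (N, 3)."""
    n = int(np.prod(shape))
    target = n if n <= opt.dense_threshold else int(n * opt.sampling)
    target = min(max(target, min(n, opt.dense_threshold)), opt.max_samples, n)
    rng = np.random.default_rng(opt.seed + 7919 * level_scale)
    if target >= n:
        flat = np.arange(n)
    else:
        flat = rng.choice(n, size=target, replace=False)
    return np.stack(np.unravel_index(flat, shape), axis=1)


def _resample_at(
    moving: Volume, world_pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear moving intensities at world points; returns (values, valid)."""
    vox = moving.to_voxel(world_pts)
    shape = np.asarray(moving.shape)
    valid = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    vals = np.zeros(len(vox))
    if valid.any():
        vals[valid] = ndimage.map_coordinates(
            moving.data.astype(float), vox[valid].T, order=1, mode="nearest"
        )
    return vals, valid


def mutual_information(
    fixed: Volume,
    moving: Volume,
    T: RigidTransform,
    opt: MIOptions | None = None,
    sample_idx: np.ndarray | None = None,
) -> float:
    """Mutual information (bits) between fixed and transformed moving volume.

    Fixed voxel centers (optionally subsampled) are mapped through ``T^-1``
    into the moving volume and sampled trilinearly; samples falling outside
    the moving field of view are excluded from the joint histogram.
    """
    opt = opt or MIOptions()
    if sample_idx is None:
        sample_idx = _sample_indices(fixed.shape, opt)
    f_vals = fixed.data[tuple(sample_idx.T)].astype(float)
    world = fixed.world(sample_idx)
    m_world = T.inverse().apply(world)
    m_vals, valid = _resample_at(moving, m_world)
    if not valid.any():
        raise ValueError("empty overlap between fixed and moving volumes")
    f_range = (float(fixed.data.min()), float(fixed.data.max()))
    m_range = (float(moving.data.min()), float(moving.data.max()))
    return _joint_mi_bits(
        f_vals[valid], m_vals[valid], opt.bins, f_range, m_range, opt.normalized
    )


# ---------------------------------------------------------------------------
# Pyramid + optimization
# ---------------------------------------------------------------------------


def _downsample(v: Volume) -> Volume:
    smoothed = ndimage.gaussian_filter(v.data.astype(float), sigma=1.0)
    data = smoothed[::2, ::2, ::2]
    scale = np.diag([2.0, 2.0, 2.0, 1.0])
    affine = v.affine @ scale
    spacing = tuple(2 * s for s in v.spacing)
    return Volume(data, spacing, affine, v.modality)


def gaussian_pyramid(v: Volume, levels: int) -> list[Volume]:
    """Fine-to-coarse list; level 0 is the input volume."""
    out = [v]
    for _ in range(levels - 1):
        if min(out[-1].shape) < 8:
            break
        out.append(_downsample(out[-1]))
    return out


def register(
    fixed: Volume,
    moving: Volume,
    init: RigidTransform | None = None,
    opt: MIOptions | None = None,
) -> RegistrationResult:
    """Maximize MI coarse-to-fine with a Powell search over 6 parameters.

    Monotone acceptance: if the optimized transform does not improve MI over
    ``init`` (measured at the finest level), ``init`` is returned with
    ``converged=False``.
    """
    opt = opt or MIOptions()
    init = init or RigidTransform.identity()
    center = fixed.world_center()

    fixed_pyr = gaussian_pyramid(fixed, opt.pyramid_levels)
    moving_pyr = gaussian_pyramid(moving, opt.pyramid_levels)

    rotvec, shift = init.params(center)
    x = np.concatenate([rotvec, shift])
    n_eval = 0
    converged = True

    coarsest = len(fixed_pyr) - 1
    for level in range(coarsest, -1, -1):
        f_lv, m_lv = fixed_pyr[level], moving_pyr[min(level, len(moving_pyr) - 1)]
        sample_idx = _sample_indices(f_lv.shape, opt, level_scale=level + 1)
        # fewer histogram bins at coarse levels: few samples per cell make
        # the MI landscape noisy and prone to spurious maxima
        level_opt = replace(opt, bins=max(16, opt.bins // (2**level)))

        f_samp = f_lv.data[tuple(sample_idx.T)].astype(float)
        f_world = f_lv.world(sample_idx)
        f_range = (float(f_lv.data.min()), float(f_lv.data.max()))
        m_range = (float(m_lv.data.min()), float(m_lv.data.max()))
        m_data = m_lv.data.astype(float)

        def neg_mi(p: np.ndarray) -> float:
            # Parzen-smoothed MI with edge-extended sampling: a fixed sample
            # set avoids rewarding transforms that shrink the overlap.
            T = RigidTransform.from_params(p[:3], p[3:], center)
            vox = m_lv.to_voxel(T.inverse().apply(f_world))
            m_samp = ndimage.map_coordinates(m_data, vox.T, order=1, mode="nearest")
            return -_parzen_mi_bits(
                f_samp, m_samp, level_opt.bins, f_range, m_range
            )

        if level == coarsest and opt.grid_span_deg > 0:
            offs = np.arange(
                -opt.grid_span_deg, opt.grid_span_deg + 1e-9, opt.grid_step_deg
            )
            best_val, best_x = neg_mi(x), x.copy()
            n_eval += 1
            for dx in offs:
                for dy in offs:
                    for dz in offs:
                        cand = x + np.array([dx, dy, dz, 0, 0, 0])
                        val = neg_mi(cand)
                        n_eval += 1
                        if val < best_val:
                            best_val, best_x = val, cand
            x = best_x

        res = minimize(
            neg_mi,
            x,
            method="Powell",
            options={
                "maxiter": opt.max_iter,
                "xtol": opt.xtol,
                "ftol": opt.ftol,
            },
        )
        n_eval += int(res.nfev)
        converged = converged and bool(res.success)
        x = np.asarray(res.x)

    best = RigidTransform.from_params(x[:3], x[3:], center)
    final_idx = _sample_indices(fixed.shape, opt, level_scale=1)
    mi_final = mutual_information(fixed, moving, best, opt, final_idx)
    mi_init = mutual_information(fixed, moving, init, opt, final_idx)
    if mi_final < mi_init:
        return RegistrationResult(init, mi_init, mi_init, False, n_eval)
    return RegistrationResult(best, mi_final, mi_init, converged, n_eval)


def reformat(moving: Volume, fixed_grid: Volume, T: RigidTransform) -> Volume:
    """Resample ``moving`` onto the grid of ``fixed_grid`` under ``T``.

    Trilinear interpolation at voxel centers; out-of-field values are 0.  The
    output shares dims, spacing and affine with ``fixed_grid``.
    """
    shape = fixed_grid.shape
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = fixed_grid.world(idx)
    m_world = T.inverse().apply(world)
    vox = moving.to_voxel(m_world)
    vals = ndimage.map_coordinates(
        moving.data.astype(float), vox.T, order=1, mode="constant", cval=0.0
    )
    return Volume(
        vals.reshape(shape), fixed_grid.spacing, fixed_grid.affine.copy(), moving.modality
    )
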