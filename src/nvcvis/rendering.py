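"""Direct volume rendering with per-label look-up tables.

Implicit segmentation: every explicit label carries its own intensity ->
(color, opacity) look-up table, so detail inside the coarse sub-volumes is
resolved at render time.  Orthographic front-to-back ray casting, label
sampled nearest-neighbor, intensity trilinear, opacity corrected for step
length, early ray termination at accumulated alpha 0.99.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .volumes_io import (
    BRAINSTEM,
    CSF_VESSEL,
    NERVE,
    REST,
    VESSEL,
    LabelVolume,
    Volume,
)

__all__ = ["LabelTF", "TransferFunction", "Camera", "render", "default_tf",
           "save_png", "VIEW_PRESETS"]


@dataclass
class LabelTF:
    """Fixed RGB color plus a piecewise-linear intensity -> opacity curve.

    Opacity is interpolated between control points and extended as a
    constant beyond the outermost points; values are clamped to [0, 1].
    """

    color: tuple[float, float, float]
    control: tuple[tuple[float, float], ...]  # (intensity, opacity) pairs

    def __post_init__(self) -> None:
        pts = sorted((float(x), float(a)) for x, a in self.control)
        if not pts:
            raise ValueError("transfer function needs at least one control point")
        self.control = tuple(pts)
        self.color = tuple(float(np.clip(c, 0.0, 1.0)) for c in self.color)

    def opacity(self, intensity: np.ndarray) -> np.ndarray:
        xs = np.array([p[0] for p in self.control])
        ys = np.array([p[1] for p in self.control])
        return np.clip(np.interp(intensity, xs, ys), 0.0, 1.0)


@dataclass
class TransferFunction:
    """Per-label look-up tables; labels without an entry are transparent."""

    table: dict[int, LabelTF] = field(default_factory=dict)

    def opacity(self, label_id: int, intensity: np.ndarray) -> np.ndarray:
        tf = self.table.get(int(label_id))
        if tf is None:
            return np.zeros_like(np.asarray(intensity, float))
        return tf.opacity(intensity)

    def color(self, label_id: int) -> np.ndarray:
        tf = self.table.get(int(label_id))
        return np.zeros(3) if tf is None else np.asarray(tf.color)


def default_tf(
    vessel_window: tuple[float, float] = (240.0, 360.0),
    csf_mean: float = 1000.0,
    edge: float = 40.0,
) -> TransferFunction:
    """Atlas-style defaults: vessels red, nerves yellow, brainstem light grey.

    The CSF_VESSEL table renders hypointense vessel-range content red while
    hyperintense CSF (and anything at or above ``csf_mean``) stays fully
    transparent; REST is completely transparent.
    """
    v_lo, v_hi = vessel_window
    red = (0.8, 0.1, 0.1)
    return TransferFunction(
        {
            REST: LabelTF((0.0, 0.0, 0.0), ((0.0, 0.0),)),
            CSF_VESSEL: LabelTF(
                red,
                (
                    (v_lo - edge, 0.0),
                    (v_lo, 0.9),
                    (v_hi, 0.9),
                    (v_hi + edge, 0.0),
                    (csf_mean, 0.0),
                ),
            ),
            BRAINSTEM: LabelTF((0.8, 0.8, 0.8), ((0.0, 0.25),)),
            NERVE: LabelTF((0.9, 0.85, 0.1), ((0.0, 0.9),)),
            VESSEL: LabelTF(red, ((0.0, 0.95),)),
        }
    )


@dataclass
class Camera:
    """Orthographic camera; rays march along ``direction`` through the volume."""

    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    width_mm: float | None = None  # None: fit the volume bounding sphere
    image_size: tuple[int, int] = (512, 512)
    step_mm: float | None = None  # None: half the smallest voxel spacing

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        d = np.asarray(self.direction, float)
        if np.linalg.norm(d) < 1e-12:
            raise ValueError("degenerate camera: zero view direction")
        d = d / np.linalg.norm(d)
        u = np.asarray(self.up, float)
        u = u - (u @ d) * d
        if np.linalg.norm(u) < 1e-9:
            raise ValueError("degenerate camera: up parallel to view direction")
        u /= np.linalg.norm(u)
        r = np.cross(d, u)
        return d, u, r


VIEW_PRESETS = {
    "ap": ((0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
    "pa": ((0.0, -1.0, 0.0), (0.0, 0.0, 1.0)),
    "left": ((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
    "right": ((-1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
    "superior": ((0.0, 0.0, -1.0), (0.0, 1.0, 0.0)),
}


def render(
    v: Volume,
    labels: LabelVolume,
    tf: TransferFunction,
    cam: Camera,
) -> np.ndarray:
    """Ray-cast ``v`` under ``labels``/``tf``; returns (H, W, 3) floats in [0,1].

    Front-to-back compositing: ``C += (1 - A) * alpha * color`` and
    ``A += (1 - A) * alpha`` with the per-sample opacity corrected for step
    length, ``alpha = 1 - (1 - a)^(step / ref_step)``.
    """
    if v.shape != labels.shape or not np.allclose(v.affine, labels.affine, atol=1e-6):
        raise ValueError("volume and labels must share one grid")
    d, u, r = cam.basis()
    w, h = cam.image_size
    center = v.world_center()
    corners_idx = np.array(
        [[i, j, k] for i in (0, v.shape[0] - 1)
         for j in (0, v.shape[1] - 1) for k in (0, v.shape[2] - 1)],
        dtype=float,
    )
    corners = v.world(corners_idx)
    half_extent = float(np.max(np.linalg.norm(corners - center, axis=1)))
    width = cam.width_mm or 2.0 * half_extent
    height = width * h / w
    step = cam.step_mm or 0.5 * min(v.spacing)
    if step <= 0:
        raise ValueError("degenerate camera: step must be positive")
    ref_step = min(v.spacing)

    xs = (np.arange(w) + 0.5) / w * width - width / 2.0
    ys = height / 2.0 - (np.arange(h) + 0.5) / h * height
    px, py = np.meshgrid(xs, ys)  # (h, w)
    origins = (
        center
        + px[..., None] * r
        + py[..., None] * u
        - half_extent * d
    ).reshape(-1, 3)

    inv = np.linalg.inv(v.affine)
    data = v.data.astype(float)
    lab = labels.labels

    n_pix = origins.shape[0]
    color = np.zeros((n_pix, 3))
    alpha = np.zeros(n_pix)
    active = np.ones(n_pix, dtype=bool)
    n_steps = int(np.ceil(2.0 * half_extent / step)) + 1
    shape_arr = np.asarray(v.shape, float)

    for s in range(n_steps):
        if not active.any():
            break
        pts = origins[active] + (s * step) * d
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        inb = np.all((vox >= 0) & (vox <= shape_arr - 1), axis=1)
        if not inb.any():
            continue
        act_idx = np.flatnonzero(active)[inb]
        coords = vox[inb].T
        intens = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
        lab_s = lab[tuple(np.round(coords).astype(int))]
        a = np.zeros(len(act_idx))
        for lid in np.unique(lab_s):
            sel = lab_s == lid
            a[sel] = tf.opacity(int(lid), intens[sel])
        a = 1.0 - np.power(1.0 - np.clip(a, 0.0, 1.0 - 1e-12), step / ref_step)
        weight = (1.0 - alpha[act_idx]) * a
        cols = np.zeros((len(act_idx), 3))
        for lid in np.unique(lab_s):
            cols[lab_s == lid] = tf.color(int(lid))
        color[act_idx] += weight[:, None] * cols
        alpha[act_idx] += weight
        active[act_idx[alpha[act_idx] >= 0.99]] = False

    img = np.clip(color.reshape(h, w, 3), 0.0, 1.0)
    return img


def save_png(img: np.ndarray, path) -> None:
    """Write an (H, W, 3) float image in [0,1] as 8-bit RGB PNG."""
    arr = (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(str(path))
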