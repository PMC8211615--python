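"""Explicit coarse segmentation into the four sub-volumes.

Volume growing (seeded connected thresholding) separates the bright CSF
body; the brainstem is grown next with the CSF mask acting as a barrier; the
nerves are imported as manual (or phantom-truth) annotations.  The label
assembly resolves overlaps by the fixed priority NERVE > CSF_VESSEL >
BRAINSTEM > REST.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes_io import (
    BRAINSTEM,
    CSF_VESSEL,
    DEFAULT_LEGEND,
    NERVE,
    BoundingBox,
    LabelVolume,
    Volume,
    read_labels,
)

__all__ = [
    "GrowParams",
    "volume_grow",
    "assemble_labels",
    "segment_brainstem",
    "import_nerve_labels",
    "window_around_seed",
    "bright_peak_window",
]


@dataclass
class GrowParams:
    """Seeds, intensity window and spatial restriction for volume growing."""

    seeds: list[tuple[int, int, int]]
    lower: float
    upper: float
    bbox: BoundingBox | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower threshold must not exceed upper threshold")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        self.seeds = [tuple(int(c) for c in s) for s in self.seeds]


def _as_array(v: Volume | np.ndarray) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v)


def volume_grow(
    v: Volume | np.ndarray,
    p: GrowParams,
    barrier: np.ndarray | None = None,
) -> np.ndarray:
    """Maximal connected in-window region containing the seeds.

    A voxel belongs to the result iff its intensity lies in
    ``[p.lower, p.upper]``, it is inside ``p.bbox`` (when given), it is not
    blocked by ``barrier``, and it is connected (6- or 26-connectivity) to a
    seed through such voxels.
    """
    data = _as_array(v)
    if not p.seeds:
        raise ValueError("empty seed list")
    window = (data >= p.lower) & (data <= p.upper)
    if p.bbox is not None:
        window &= p.bbox.mask(data.shape)
    if barrier is not None:
        if barrier.shape != data.shape:
            raise ValueError("barrier mask grid mismatch")
        window &= ~barrier
    for s in p.seeds:
        if any(c < 0 or c >= n for c, n in zip(s, data.shape)):
            raise ValueError(f"seed {s} outside grid {data.shape}")
        if p.bbox is not None and not p.bbox.contains(s):
            raise ValueError(f"seed {s} outside bounding box")
        if not window[s]:
            raise ValueError(
                f"seed {s} outside intensity window "
                f"[{p.lower}, {p.upper}] (value {data[s]})"
            )
    structure = ndimage.generate_binary_structure(3, 1 if p.connectivity == 6 else 3)
    comp, _ = ndimage.label(window, structure=structure)
    ids = np.unique([comp[s] for s in p.seeds])
    return np.isin(comp, ids[ids > 0])


def segment_brainstem(
    v: Volume | np.ndarray,
    csf_mask: np.ndarray,
    p: GrowParams,
) -> np.ndarray:
    """Volume growing with the previously segmented CSF acting as a barrier."""
    data = _as_array(v)
    if csf_mask.shape != data.shape:
        raise ValueError("csf mask grid mismatch")
    return volume_grow(data, p, barrier=csf_mask)


def assemble_labels(
    csf_mask: np.ndarray,
    brainstem_mask: np.ndarray,
    nerve_mask: np.ndarray,
    like: Volume,
) -> LabelVolume:
    """Merge the three masks into one partition with fixed priority.

    NERVE wins over CSF_VESSEL wins over BRAINSTEM; unclaimed voxels are
    REST.  The result never depends on argument evaluation order.
    """
    shape = like.shape
    for m in (csf_mask, brainstem_mask, nerve_mask):
        if m.shape != shape:
            raise ValueError("masks must share the target grid")
    labels = np.zeros(shape, dtype=np.int16)
    labels[brainstem_mask] = BRAINSTEM
    labels[csf_mask] = CSF_VESSEL
    labels[nerve_mask] = NERVE
    return LabelVolume(labels, dict(DEFAULT_LEGEND), like.spacing, like.affine.copy())


def import_nerve_labels(path, like: Volume) -> np.ndarray:
    """Read a hand-drawn (or phantom-truth) nerve mask; no automation."""
    lv = read_labels(path)
    if lv.shape != like.shape or not np.allclose(lv.affine, like.affine, atol=1e-6):
        raise ValueError("nerve label grid mismatch with target volume")
    mask = lv.labels != 0
    if not mask.any():
        warnings.warn("imported nerve mask is empty", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# Threshold helpers ("selected close to the signal intensity" of the target)
# ---------------------------------------------------------------------------


def window_around_seed(
    v: Volume | np.ndarray,
    seed: tuple[int, int, int],
    nsigma: float = 4.0,
    patch: int = 3,
) -> tuple[float, float]:
    """Intensity window mean +/- nsigma*std of a cubic patch around the seed."""
    data = _as_array(v)
    sl = tuple(
        slice(max(c - patch, 0), min(c + patch + 1, n))
        for c, n in zip(seed, data.shape)
    )
    region = data[sl].astype(float)
    mu, sd = float(region.mean()), float(region.std())
    sd = max(sd, 1e-6)
    return mu - nsigma * sd, mu + nsigma * sd


def bright_peak_window(
    v: Volume | np.ndarray, nsigma: float = 2.0, bins: int = 128
) -> tuple[float, float]:
    """CSF-style window: mode of the bright histogram peak +/- nsigma*sigma.

    The bright population is taken above the Otsu threshold; the peak is the
    dominant histogram bin of that population and sigma is estimated from
    voxels within 15% of the peak.
    """
    from skimage.filters import threshold_otsu

    data = _as_array(v).astype(float)
    thr = threshold_otsu(data)
    bright = data[data >= thr]
    if bright.size == 0:
        raise ValueError("no bright voxels above Otsu threshold")
    hist, edges = np.histogram(bright, bins=bins)
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    near = data[np.abs(data - mode) <= 0.15 * max(abs(mode), 1.0)]
    sigma = float(near.std()) if near.size else float(bright.std())
    sigma = max(sigma, 1e-6)
    return mode - nsigma * sigma, mode + nsigma * sigma
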