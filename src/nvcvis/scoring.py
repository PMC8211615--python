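"""Vessel-nerve contact detection and the 0-5 vessel-quality ranking score.

The ordinal quality scale is operationalized through centerline coverage:
the fraction of ground-truth centerline voxels reproduced inside the vessel
display window.  Clinical use accepts expert-entered scores instead; the
automatic mode exists so phantoms can be scored reproducibly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import CSF_VESSEL, LabelVolume, Volume

__all__ = [
    "VesselScore",
    "NVCFinding",
    "detect_contact",
    "coverage",
    "score_from_coverage",
    "score_vessel",
    "display_window_mask",
]


@dataclass
class VesselScore:
    vessel: str
    score: int
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= int(self.score) <= 5:
            raise ValueError("score must lie in 0..5")
        self.score = int(self.score)


@dataclass
class NVCFinding:
    side: str  # left | right | bilateral | none
    contact_voxels: np.ndarray  # (K, 3) vessel-side interface voxels
    loop_type: str | None = None  # manual annotation pass-through (I/II/III)

    def __post_init__(self) -> None:
        self.contact_voxels = np.asarray(self.contact_voxels).reshape(-1, 3)
        if (self.side == "none") != (len(self.contact_voxels) == 0):
            raise ValueError("side 'none' iff contact set empty")

    @property
    def positive(self) -> bool:
        return len(self.contact_voxels) > 0


def _shifted(mask: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Boolean array whose value at v equals mask[v + d] (False outside)."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, off in enumerate(d):
        if off > 0:
            src[ax], dst[ax] = slice(off, None), slice(None, -off)
        elif off < 0:
            src[ax], dst[ax] = slice(None, off), slice(-off, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def detect_contact(
    vessel_mask: np.ndarray,
    rez_mask: np.ndarray,
    csf_labels: LabelVolume | np.ndarray,
    loop_type: str | None = None,
) -> NVCFinding:
    """Vessel voxels 26-adjacent to nerve voxels with no CSF layer between.

    Face-adjacent pairs have no voxel in between and always count.  For a
    diagonal pair the single-axis intermediate voxels are inspected; the
    pair is discounted only if every intermediate is CSF-labeled (a visible
    CSF layer separates the structures).  ``side`` is derived from the
    axis-0 position of the contact voxels relative to the grid midline.
    """
    if isinstance(csf_labels, LabelVolume):
        csf = csf_labels.labels == CSF_VESSEL
    else:
        csf = np.asarray(csf_labels).astype(bool)
    if not (vessel_mask.shape == rez_mask.shape == csf.shape):
        raise ValueError("masks must share one grid")

    contact = np.zeros_like(vessel_mask, dtype=bool)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for d in offsets:
        pair = vessel_mask & _shifted(rez_mask, d)
        if not pair.any():
            continue
        order = sum(abs(c) for c in d)
        if order == 1:
            contact |= pair
            continue
        blocked = np.ones_like(pair)
        for ax in range(3):
            if d[ax] != 0:
                e = [0, 0, 0]
                e[ax] = d[ax]
                blocked &= _shifted(csf, tuple(e))
        contact |= pair & ~blocked

    voxels = np.argwhere(contact)
    if len(voxels) == 0:
        return NVCFinding("none", voxels, loop_type)
    mid = (vessel_mask.shape[0] - 1) / 2.0
    left = (voxels[:, 0] < mid).any()
    right = (voxels[:, 0] > mid).any()
    side = "bilateral" if (left and right) else ("left" if left else "right")
    return NVCFinding(side, voxels, loop_type)


# ---------------------------------------------------------------------------
# Ranking score
# ---------------------------------------------------------------------------


def display_window_mask(v: Volume, window: tuple[float, float]) -> np.ndarray:
    """Voxels whose intensity falls inside the vessel display window."""
    lo, hi = window
    return (v.data >= lo) & (v.data <= hi)


def coverage(visible_mask: np.ndarray, centerline: np.ndarray) -> float:
    """Fraction of ordered centerline voxels marked visible."""
    cl = np.asarray(centerline, int).reshape(-1, 3)
    if len(cl) == 0:
        raise ValueError("empty centerline")
    return float(visible_mask[tuple(cl.T)].mean())


def score_from_coverage(c: float, proximal_c: float, distal_c: float) -> int:
    """Map coverage fractions onto the 0-5 ordinal quality scale.

    0: nothing reproduced; 1: c < 0.25; 2: c < 0.5; 3: proximal half
    well covered (>= 0.8) while the distal half is mostly missing (< 0.5);
    4: c < 0.95; 5: c >= 0.95.
    """
    if c == 0:
        return 0
    if c >= 0.95:
        return 5
    if proximal_c >= 0.8 and distal_c < 0.5:
        return 3
    if c < 0.25:
        return 1
    if c < 0.5:
        return 2
    return 4


def score_vessel(
    visible_mask: np.ndarray, centerline: np.ndarray, name: str = "vessel"
) -> VesselScore:
    """Automatic ranking score from centerline coverage in the display window."""
    cl = np.asarray(centerline, int).reshape(-1, 3)
    if len(cl) == 0:
        raise ValueError("empty centerline")
    half = len(cl) // 2
    c = coverage(visible_mask, cl)
    prox = coverage(visible_mask, cl[: max(half, 1)])
    dist = coverage(visible_mask, cl[half:]) if half < len(cl) else prox
    return VesselScore(name, score_from_coverage(c, prox, dist), c)
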