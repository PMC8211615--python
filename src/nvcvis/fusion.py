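"""Vessel transplantation from reformatted TOF into the CISS volume.

Hyperintense TOF vessels are extracted by volume growing, their intensities
are mapped by a strictly decreasing linear ramp onto the hypointense CISS
vessel display range, and the mapped values replace the CISS voxels.  The
affected voxels are additionally stamped with the dedicated VESSEL label so
rendering can color them independently of the CSF look-up table.
"""
from __future__ import annotations

import numpy as np

from .segmentation import GrowParams, volume_grow
from .volumes_io import VESSEL, LabelVolume, Modality, Volume

__all__ = ["extract_tof_vessels", "invert_map", "fuse", "stamp_vessel_labels"]

DEFAULT_CISS_VESSEL_RANGE = (240.0, 360.0)


def extract_tof_vessels(tof_ref: Volume, p: GrowParams) -> np.ndarray:
    """Volume growing on the reformatted TOF with a high-intensity window."""
    return volume_grow(tof_ref, p)


def invert_map(
    values: np.ndarray | float,
    t_range: tuple[float, float],
    c_range: tuple[float, float],
) -> np.ndarray | float:
    """Linear decreasing remap of [t_lo, t_hi] onto [c_lo, c_hi].

    ``t_lo -> c_hi`` and ``t_hi -> c_lo``; applying the map twice with the
    ranges swapped is the identity.
    """
    t_lo, t_hi = float(t_range[0]), float(t_range[1])
    c_lo, c_hi = float(c_range[0]), float(c_range[1])
    if t_hi == t_lo:
        raise ValueError("degenerate TOF intensity range (t_hi == t_lo)")
    return c_hi - (np.asarray(values, float) - t_lo) * (c_hi - c_lo) / (t_hi - t_lo)


def fuse(
    ciss: Volume,
    tof_ref: Volume,
    vessel_mask: np.ndarray,
    t_range: tuple[float, float] | None = None,
    c_range: tuple[float, float] = DEFAULT_CISS_VESSEL_RANGE,
) -> tuple[Volume, np.ndarray]:
    """Replace CISS values inside ``vessel_mask`` with inverted TOF values.

    Returns the fused volume and ``labels_delta`` (the voxel set to be
    stamped VESSEL).  Outside the mask the CISS data is untouched bit-exact.
    ``t_range`` defaults to the 1st-99th intensity percentiles of the TOF
    values inside the mask.
    """
    if not ciss.same_grid(tof_ref):
        raise ValueError("ciss and reformatted tof must share one grid")
    if vessel_mask.shape != ciss.shape:
        raise ValueError("vessel mask grid mismatch")
    fused = ciss.data.astype(float).copy()
    if vessel_mask.any():
        tof_vals = tof_ref.data[vessel_mask].astype(float)
        if t_range is None:
            t_range = (
                float(np.percentile(tof_vals, 1)),
                float(np.percentile(tof_vals, 99)),
            )
        lo, hi = min(c_range), max(c_range)
        # clamp so values outside the percentile window stay displayable
        fused[vessel_mask] = np.clip(invert_map(tof_vals, t_range, c_range), lo, hi)
    out = Volume(fused, ciss.spacing, ciss.affine.copy(), Modality.FUSED)
    return out, vessel_mask.copy()


def stamp_vessel_labels(labels: LabelVolume, labels_delta: np.ndarray) -> LabelVolume:
    """Return a copy of ``labels`` with the fused vessel voxels set to VESSEL."""
    if labels_delta.shape != labels.shape:
        raise ValueError("labels_delta grid mismatch")
    stamped = labels.labels.copy()
    stamped[labels_delta] = VESSEL
    legend = dict(labels.legend)
    legend.setdefault(VESSEL, "VESSEL")
    return LabelVolume(stamped, legend, labels.spacing, labels.affine.copy())
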