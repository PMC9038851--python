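"""Automated anatomy segmentation for the sharpness metric.

The metric must score genuine soft-tissue structure, not the overwhelming
object-to-air and tissue-to-bone edges, so the analysis region of interest
(ROI) is built fully automatically: Otsu threshold on the whole volume ->
body = largest 3-D connected component with slice-wise hole filling;
second-stage Otsu inside the body -> bone; ROI = body eroded at the air
boundary, minus the bone dilated by a physical safety margin.  Vessel-wall
calcifications are deliberately *not* excluded — they are vascular
features, and blurring of the calcification-lumen edge is precisely what
the metric should see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, GridGeometry

__all__ = [
    "MaskSet",
    "SegmentationError",
    "DegenerateInputError",
    "otsu_threshold",
    "body_mask",
    "bone_mask",
    "analysis_roi",
    "bone_removal_quality",
    "build_masks",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Segmentation produced an empty or invalid result."""


class DegenerateInputError(ValueError):
    """Input carries no contrast to threshold (e.g. constant values)."""


@dataclass
class MaskSet:
    """Aligned boolean masks sharing one grid.

    ``analysis_roi`` is the region the sharpness metric is evaluated on:
    inside the body, clear of the (dilated) bones and of the body/air
    boundary.
    """

    body: np.ndarray
    bone: np.ndarray
    analysis_roi: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        shp = self.geometry.shape
        for name in ("body", "bone", "analysis_roi"):
            m = getattr(self, name)
            if m.shape != shp or m.dtype != bool:
                raise ValueError(f"mask {name!r} must be a boolean array of shape {shp}")
        if np.any(self.analysis_roi & ~self.body):
            raise ValueError("analysis_roi must be a subset of body")


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Otsu's threshold: maximise between-class variance w0*w1*(mu0-mu1)^2.

    ``values`` is either a sample of scalars, or a precomputed histogram
    ``(counts, bin_centers)``.  Candidate thresholds are the boundaries
    between adjacent bins; the returned threshold separates the classes as
    ``x < t`` versus ``x >= t``.  Ties — splits whose between-class
    variance is within 1e-10 relative of the maximum, e.g. splits
    separated only by empty bins — are broken toward the lowest
    threshold.
    """
    if isinstance(values, tuple):
        counts, centers = values
        counts = np.asarray(counts, dtype=np.float64)
        centers = np.asarray(centers, dtype=np.float64)
    else:
        sample = np.asarray(values, dtype=np.float64).ravel()
        if sample.size == 0 or np.ptp(sample) == 0:
            raise DegenerateInputError("need >= 2 distinct values for Otsu")
        counts, edges = np.histogram(sample, bins=n_bins)
        counts = counts.astype(np.float64)
        centers = (edges[:-1] + edges[1:]) / 2.0
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError("histogram has fewer than 2 occupied bins")

    total = counts.sum()
    w0 = np.cumsum(counts)
    m0 = np.cumsum(counts * centers)
    mu_total = m0[-1] / total
    # split after bin i: lower class = bins[0..i], upper class = bins[i+1..]
    w0_ = w0[:-1] / total
    w1_ = 1.0 - w0_
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0[:-1] > 0, m0[:-1] / w0[:-1], 0.0)
        mu1 = np.where(
            w0[:-1] < total, (m0[-1] - m0[:-1]) / (total - w0[:-1]), 0.0
        )
    sigma_b = w0_ * w1_ * (mu0 - mu1) ** 2
    sigma_b[(w0_ == 0) | (w1_ == 0)] = -np.inf
    best = sigma_b.max()
    # lowest split within the tie band of the maximum
    i = int(np.argmax(sigma_b >= best - abs(best) * 1e-10))
    return float((centers[i] + centers[i + 1]) / 2.0)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        raise SegmentationError("no foreground voxels")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def body_mask(vol: CTVolume) -> np.ndarray:
    """Segment the patient body: Otsu on the whole volume, keep the largest
    3-D 26-connected component, fill enclosed holes slice by slice."""
    t = otsu_threshold(vol.values)
    fg = vol.values >= t
    if not fg.any():
        raise SegmentationError("no voxels above the Otsu threshold")
    body = _largest_component(fg)
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return body


def bone_mask(
    vol: CTVolume,
    body: np.ndarray,
    min_voxels: int = 50,
    fixed_hu: float | None = None,
) -> np.ndarray:
    """Segment bone within the body.

    Default: second-stage Otsu on in-body HU values (the upper class is
    bone).  ``fixed_hu`` switches to a fixed HU cutoff — an escape hatch
    for volumes where contrast-filled vessels contaminate the upper Otsu
    class.  Components smaller than ``min_voxels`` (26-connected) are
    dropped as speckle.
    """
    inside = vol.values[body]
    if inside.size == 0:
        raise SegmentationError("empty body mask")
    if fixed_hu is not None:
        t = float(fixed_hu)
    else:
        t = otsu_threshold(inside)
    bone = body & (vol.values >= t)
    if not bone.any():
        return bone
    labels, n = ndimage.label(bone, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    return np.isin(labels, keep)


def analysis_roi(
    body: np.ndarray,
    bone: np.ndarray,
    geometry: GridGeometry,
    dilation_radius_mm: float = 2.0,
) -> np.ndarray:
    """ROI = body, eroded at the air boundary and cleared of dilated bone.

    Both operations use true physical distance (anisotropic-spacing-aware
    Euclidean distance transform), so a 2 mm margin means 2 mm regardless
    of the grid.
    """
    if dilation_radius_mm < 0:
        raise ValueError("dilation radius must be >= 0")
    if body.shape != bone.shape:
        raise ValueError("body and bone masks must share one grid")
    if dilation_radius_mm == 0:
        return body & ~bone
    spacing = geometry.spacing
    # distance of each in-body voxel to the nearest air voxel
    d_air = ndimage.distance_transform_edt(body, sampling=spacing)
    eroded = d_air > dilation_radius_mm
    if bone.any():
        d_bone = ndimage.distance_transform_edt(~bone, sampling=spacing)
        dilated_bone = d_bone <= dilation_radius_mm
    else:
        dilated_bone = bone
    return eroded & ~dilated_bone


def bone_removal_quality(
    bone: np.ndarray,
    vol: CTVolume,
    body: np.ndarray,
    hu_cutoff: float = 700.0,
    vessel_component_voxels: int = 200,
    eligibility_cutoff: float = 0.98,
) -> tuple[float, bool]:
    """Automated proxy for visual bone-removal quality control.

    Considers in-body voxels above ``hu_cutoff`` HU that belong to large
    (> ``vessel_component_voxels``) connected components — bone-calibre
    objects, excluding small calcifications and contrast-filled lumina —
    and returns the fraction captured by the bone mask plus an eligibility
    flag (fraction >= ``eligibility_cutoff``).  Datasets failing the flag
    should be excluded from the objective comparison.
    """
    high = body & (vol.values >= hu_cutoff)
    if not high.any():
        return 1.0, True
    labels, n = ndimage.label(high, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    big = np.flatnonzero(sizes > vessel_component_voxels) + 1
    target = np.isin(labels, big)
    if not target.any():
        return 1.0, True
    score = float(np.count_nonzero(target & bone) / np.count_nonzero(target))
    return score, score >= eligibility_cutoff


def build_masks(
    vol: CTVolume,
    dilation_radius_mm: float = 2.0,
    min_bone_voxels: int = 50,
    fixed_bone_hu: float | None = None,
) -> MaskSet:
    """Run the full segmentation chain on one volume."""
    body = body_mask(vol)
    bone = bone_mask(vol, body, min_voxels=min_bone_voxels, fixed_hu=fixed_bone_hu)
    roi = analysis_roi(body, bone, vol.geometry, dilation_radius_mm)
    if not roi.any():
        warnings.warn("analysis ROI is empty", stacklevel=2)
    return MaskSet(body=body, bone=bone, analysis_roi=roi, geometry=vol.geometry)
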