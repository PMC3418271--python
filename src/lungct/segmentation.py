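"""Automated aerated-lung segmentation.

The algorithm isolates the air-filled lung spaces of a mouse from a
calibrated HU volume with no operator interaction:

1. threshold the whole field of view at an air density (HU ≤ threshold);
2. despeckle per axial slice: keep only 2D air components touching the
   slice border — that is exactly the air *outside* the animal, since
   lungs are enclosed pores in every axial thorax slice;
3. the complement of that external air is a body region of interest
   (the animal plus its internal air and the bed);
4. erode the ROI border by 10 pixels per slice to sharpen its shape and
   peel off partial-volume skin voxels;
5. re-threshold for air inside the eroded ROI;
6. sweep: keep only the largest 26-connected 3D object, which is the
   lung (left + right lungs connect through the trachea and main
   bronchi); this removes low-density pockets outside the lung such as
   gas in subcutaneous fat.

Two thresholds are in use: −580 HU for euthanized animals (the full air
histogram of a reference air tube sits below −580 HU) and −383 HU in
vivo, where residual respiratory motion blurs lung borders and a higher
cut is needed to capture inflation. Threshold semantics are uniform:
voxels with HU ≤ threshold count as air.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume_io import CTVolume, HUHistogram, stack_histogram

__all__ = [
    "Mode",
    "SegmentationParams",
    "SegmentationResult",
    "threshold_air",
    "external_air_mask",
    "body_roi",
    "erode_roi",
    "largest_component_3d",
    "segment_aerated_lung",
    "THRESHOLD_EUTHANIZED_HU",
    "THRESHOLD_IN_VIVO_HU",
    "EROSION_RADIUS_PX",
]

THRESHOLD_EUTHANIZED_HU = -580.0
THRESHOLD_IN_VIVO_HU = -383.0
EROSION_RADIUS_PX = 10


class Mode(str, Enum):
    EUTHANIZED = "euthanized"
    IN_VIVO = "in_vivo"


_MODE_THRESHOLDS = {
    Mode.EUTHANIZED: THRESHOLD_EUTHANIZED_HU,
    Mode.IN_VIVO: THRESHOLD_IN_VIVO_HU,
}


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation algorithm.

    ``air_threshold_hu`` defaults from the mode (−580 euthanized, −383 in
    vivo); the two modes differ in nothing else.
    """

    mode: Mode = Mode.EUTHANIZED
    air_threshold_hu: float | None = None
    erosion_radius_px: int = EROSION_RADIUS_PX

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        if self.air_threshold_hu is None:
            self.air_threshold_hu = _MODE_THRESHOLDS[self.mode]
        if not (-1000.0 < self.air_threshold_hu < 0.0):
            raise ValueError(
                f"air threshold must lie in (−1000, 0) HU, got {self.air_threshold_hu}"
            )
        if self.erosion_radius_px < 0:
            raise ValueError("erosion radius must be non-negative")


@dataclass
class SegmentationResult:
    """Final lung-air mask with volume bookkeeping.

    ``volume_mm3 == voxel_count * (voxel_size_mm)**3`` exactly; the
    attached histogram is the full-stack HU histogram of the body ROI.
    """

    lung_mask: np.ndarray
    voxel_count: int
    volume_mm3: float
    histogram: HUHistogram
    params: SegmentationParams

    def to_dict(self) -> dict:
        return {
            "voxel_count": self.voxel_count,
            "volume_mm3": self.volume_mm3,
            "mode": self.params.mode.value,
            "air_threshold_hu": self.params.air_threshold_hu,
            "erosion_radius_px": self.params.erosion_radius_px,
        }


def threshold_air(volume: CTVolume, threshold_hu: float) -> np.ndarray:
    """Binary air mask: true exactly where HU ≤ threshold."""
    if not volume.calibrated:
        raise ValueError("threshold_air requires a calibrated (HU) volume")
    return volume.voxels <= threshold_hu


def external_air_mask(air_mask: np.ndarray) -> np.ndarray:
    """Keep, per axial slice, only 2D air components touching the border.

    Enclosed 2D air components ("pores" — the lungs, gas pockets) are
    removed, leaving the air surrounding the animal. 8-connectivity in
    plane.
    """
    air_mask = np.asarray(air_mask, dtype=bool)
    out = np.zeros_like(air_mask)
    for z in range(air_mask.shape[0]):
        sl = air_mask[z]
        labels = measure.label(sl, connectivity=2)
        border = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        border = border[border != 0]
        if border.size:
            out[z] = np.isin(labels, border)
    return out


def body_roi(volume_shape: tuple[int, int, int], external_air: np.ndarray) -> np.ndarray:
    """Body ROI = complement of the external air.

    Contains the animal with all its internal air plus the bed; the later
    sweep isolates the lung from it.
    """
    external_air = np.asarray(external_air, dtype=bool)
    if tuple(volume_shape) != external_air.shape:
        raise ValueError(
            f"shape mismatch: volume {tuple(volume_shape)} vs external air {external_air.shape}"
        )
    roi = ~external_air
    if not roi.any():
        raise ValueError("no subject in field of view: ROI is empty")
    return roi


def erode_roi(roi: np.ndarray, radius_px: int = EROSION_RADIUS_PX) -> np.ndarray:
    """Erode the ROI border by ``radius_px`` pixels per axial slice.

    The structuring element is a square of side 2r+1 (Chebyshev ball);
    pixels outside the image count as background, so the ROI also recedes
    from the image edge. Equivalent to keeping pixels whose 2D Chebyshev
    distance to background exceeds r.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("cannot erode an empty ROI")
    if radius_px == 0:
        return roi.copy()
    side = 2 * radius_px + 1
    eroded = ndimage.minimum_filter(
        roi.astype(np.uint8), size=(1, side, side), mode="constant", cval=0
    ).astype(bool)
    if not eroded.any():
        raise ValueError("ROI vanished under erosion")
    return eroded


def largest_component_3d(mask: np.ndarray) -> np.ndarray:
    """Sweep: retain only the largest 26-connected 3D component.

    Ties are broken deterministically in favour of the component whose
    smallest (z, y, x) voxel is lexicographically first (labels are
    assigned in raster-scan order, so the lowest-numbered of the largest
    labels wins).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty segmentation")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 1:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))  # first maximal label = lexicographic tie-break
    return labels == keep


def segment_aerated_lung(
    volume: CTVolume, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Run the full automated aerated-lung segmentation pipeline.

    Returns the lung-air mask together with its voxel count, volume in
    mm³ and the full-stack HU histogram of the body ROI. Raises
    ``ValueError("empty segmentation")`` when the subject holds no
    sub-threshold air (e.g. a solid-tissue phantom).
    """
    if params is None:
        params = SegmentationParams()
    air = threshold_air(volume, params.air_threshold_hu)
    external = external_air_mask(air)
    roi = body_roi(volume.shape, external)
    roi_hist = stack_histogram(volume, roi)
    eroded = erode_roi(roi, params.erosion_radius_px)
    internal_air = air & eroded
    lung = largest_component_3d(internal_air)
    voxel_count = int(np.count_nonzero(lung))
    return SegmentationResult(
        lung_mask=lung,
        voxel_count=voxel_count,
        volume_mm3=voxel_count * volume.voxel_volume_mm3,
        histogram=roi_hist,
        params=params,
    )
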