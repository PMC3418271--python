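"""Volume I/O and Hounsfield-unit calibration.

Reconstructed micro-CT tomograms arrive as a stack of axial grayscale
slices (TIFF or PNG, one file per slice). This module assembles them into a
:class:`CTVolume`, applies the two-point water/air HU calibration, and
computes full-stack HU histograms over a region of interest.

Axis convention: ``voxels[z, y, x]`` with z = slice file order (natural
sort), y = image row, x = image column; all indices 0-based. Grayscale
values are the file's stored integers (8- or 16-bit) without rescaling,
because the calibration is defined on stored grayscale indices.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CTVolume",
    "CalibrationModel",
    "HUHistogram",
    "read_slice_stack",
    "write_slice_stack",
    "read_volume",
    "write_volume",
    "calibrate_to_hu",
    "stack_histogram",
]

#: default isotropic voxel edge length (µm) of the reconstructed tomograms
DEFAULT_VOXEL_SIZE_UM = 35.0

HIST_MIN_HU = -1000
HIST_MAX_HU = 1000


@dataclass
class CTVolume:
    """A 3D voxel grid of grayscale or HU values with isotropic voxels.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Raw grayscale indices before calibration, HU after.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    calibrated : bool
        True once the grayscale → HU map has been applied.
    """

    voxels: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(
                f"volume must be 3D with all dimensions >= 1, got shape {self.voxels.shape}"
            )
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if self.calibrated and not np.all(np.isfinite(self.voxels)):
            raise ValueError("calibrated volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm³."""
        return (self.voxel_size_um / 1000.0) ** 3


@dataclass
class CalibrationModel:
    """Two-point linear grayscale → HU map anchored at water and air.

    The mean grayscale of a pure-water region maps to 0 HU and of a
    pure-air region to −1000 HU:

        HU(g) = 1000 * (g − water_gray) / (water_gray − air_gray)
    """

    water_gray: float
    air_gray: float

    def __post_init__(self) -> None:
        if not self.water_gray > self.air_gray:
            raise ValueError(
                f"water grayscale ({self.water_gray}) must exceed air grayscale "
                f"({self.air_gray}); the calibration map is ill-defined otherwise"
            )

    def to_hu(self, gray):
        """Apply the linear map elementwise; anchors map exactly."""
        g = np.asarray(gray, dtype=np.float64)
        # divide before scaling so both anchors map exactly (x/x == 1.0)
        return 1000.0 * ((g - self.water_gray) / (self.water_gray - self.air_gray))


@dataclass
class HUHistogram:
    """Full-stack histogram over 1-HU-wide bins spanning [−1000, +1000].

    Bins are half-open [h, h+1) with the last bin closed. Voxels outside
    the plotted range are tallied in ``underflow`` / ``overflow`` rather
    than dropped, so counts are conserved:
    ``counts.sum() + underflow + overflow == roi_voxel_count``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    roi_voxel_count: int
    underflow: int = 0
    overflow: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hu_bin": self.bin_edges[:-1].astype(int), "count": self.counts}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def read_slice_stack(
    directory, pattern: str = "*.tif*", voxel_size_um: float | None = None
) -> CTVolume:
    """Assemble a directory of grayscale slice images into a raw volume.

    Files are stacked in natural-sort order of their names (``s2`` before
    ``s10``), matching scanner export conventions. Voxel size is taken from
    a ``volume.json`` sidecar if present, else the ``voxel_size_um``
    argument, else 35 µm.
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern), key=lambda p: _natural_key(p.name))
    if not files:
        raise FileNotFoundError(f"no slice files matching {pattern!r} in {directory}")

    slices = []
    for i, f in enumerate(files):
        img = iio.imread(f)
        if img.ndim == 3:  # collapse RGB written by some viewers
            img = img[..., 0]
        if img.ndim != 2:
            raise ValueError(f"slice {f.name} is not a 2D grayscale image")
        if slices and img.shape != slices[0].shape:
            raise ValueError(
                f"slice {f.name} (index {i}) has dimensions {img.shape}, "
                f"expected {slices[0].shape} from {files[0].name}"
            )
        slices.append(img)

    sidecar = directory / "volume.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if voxel_size_um is None:
        voxel_size_um = meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM)

    return CTVolume(
        np.stack(slices),
        voxel_size_um=voxel_size_um,
        calibrated=meta.get("calibrated", False),
    )


def write_slice_stack(volume: CTVolume | np.ndarray, directory, prefix: str = "slice") -> list[Path]:
    """Write a volume (or boolean mask) as a TIFF stack, one file per slice.

    Boolean arrays are written as 8-bit 0/255 masks; integer arrays keep
    their dtype so ``read_slice_stack`` round-trips bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vox = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    if vox.dtype == bool:
        vox = vox.astype(np.uint8) * 255
    elif vox.dtype == np.float64:
        vox = vox.astype(np.float32)  # HU precision; halves stack size on disk
    paths = []
    width = max(4, len(str(vox.shape[0])))
    for z in range(vox.shape[0]):
        p = directory / f"{prefix}_{z:0{width}d}.tif"
        tifffile.imwrite(p, vox[z])
        paths.append(p)
    if isinstance(volume, CTVolume):
        (directory / "volume.json").write_text(
            json.dumps(
                {
                    "voxel_size_um": volume.voxel_size_um,
                    "axis_order": "zyx",
                    "calibrated": volume.calibrated,
                }
            )
        )
    return paths


def write_volume(volume: CTVolume, path) -> None:
    """Write a single-file multi-page TIFF volume plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.voxels)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "voxel_size_um": volume.voxel_size_um,
                "axis_order": "zyx",
                "calibrated": volume.calibrated,
            }
        )
    )


def read_volume(path) -> CTVolume:
    """Read a single-file volume written by :func:`write_volume`."""
    path = Path(path)
    vox = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return CTVolume(
        vox,
        voxel_size_um=meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM),
        calibrated=meta.get("calibrated", False),
    )


def calibrate_to_hu(volume: CTVolume, model: CalibrationModel) -> CTVolume:
    """Apply the two-point grayscale → HU calibration voxelwise.

    The water anchor maps exactly to 0 HU and the air anchor exactly to
    −1000 HU; the map is affine and strictly increasing.
    """
    if volume.calibrated:
        raise ValueError("volume is already calibrated to HU")
    return CTVolume(
        model.to_hu(volume.voxels),
        voxel_size_um=volume.voxel_size_um,
        calibrated=True,
    )


def stack_histogram(volume: CTVolume, roi: np.ndarray) -> HUHistogram:
    """Histogram ROI voxels into 1-HU bins over [−1000, +1000].

    Out-of-range voxels go to the underflow/overflow counters so the total
    tally always equals the ROI voxel count.
    """
    if not volume.calibrated:
        raise ValueError("stack_histogram requires a calibrated (HU) volume")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != volume.shape:
        raise ValueError(
            f"ROI shape {roi.shape} does not match volume shape {volume.shape}"
        )
    values = volume.voxels[roi]
    edges = np.arange(HIST_MIN_HU, HIST_MAX_HU + 1, dtype=np.float64)
    counts, _ = np.histogram(values, bins=edges)
    underflow = int(np.count_nonzero(values < HIST_MIN_HU))
    overflow = int(np.count_nonzero(values > HIST_MAX_HU))
    return HUHistogram(
        bin_edges=edges,
        counts=counts,
        roi_voxel_count=int(values.size),
        underflow=underflow,
        overflow=overflow,
    )
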