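"""Seeded synthetic phantoms: calibration tube, digital mouse thorax, breathing trace.

Three generators stand in for the scanner:

* a water/air calibration phantom — an air-filled tube inside a
  water-filled tube — with region masks for the pure-water and pure-air
  voxels, from which calibration anchors are measured;
* a 4-phase digital mouse thorax: an ellipsoidal soft-tissue body
  surrounded by external air, resting on a bed, containing two air-filled
  lung lobes joined by a tracheal channel. The lungs deflate from phase 0
  (end-inspiration) to phase 3 (end-expiration). Disease transforms:
  ``fibrosis_fraction`` replaces a patchy fraction of the lung air with
  consolidation-density tissue (restriction); ``emphysema_factor`` scales
  the aerated compartment volume (dose-dependent airspace increase).
  Sub-threshold speckle pockets (gas at ≈ −600 HU in subcutaneous
  tissue) exercise the final largest-component sweep. Ground truth is
  recorded on the noiseless geometry before Gaussian HU noise is added;
* a pseudo-sinusoidal breathing trace sampled at 100 Hz.

All outputs are bit-reproducible for a fixed seed. The phantom has no
beam-hardening or ring artifacts: reconstruction is upstream of this
toolkit, and its artifacts are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gating import BreathingTrace
from .volume_io import CTVolume

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "make_calibration_phantom",
    "make_thorax_phantom",
    "make_breathing_trace",
    "uniform_projection_timestamps",
]

HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_BED = 100.0
HU_SPECKLE = -600.0
HU_FIBROSIS = -200.0

TRACE_SAMPLE_RATE_HZ = 100.0


@dataclass
class PhantomSpec:
    """Geometry and acquisition parameters of the digital thorax.

    Defaults mimic the reconstruction targeted by the analysis: isotropic
    35 µm voxels, 4 respiratory phases, Gaussian HU noise of SD 20. The
    default 200³ grid keeps a full phantom cheap to generate and segment;
    geometry is specified in grid fractions so larger grids (up to the
    scanner's 1000×1000×N) reproduce the same scene.
    """

    shape: tuple[int, int, int] = (200, 200, 200)
    voxel_size_um: float = 35.0
    noise_sd_hu: float = 20.0
    fibrosis_fraction: float = 0.0
    emphysema_factor: float = 1.0
    n_phases: int = 4
    #: per-phase lung volume relative to phase 0 (EIV); non-increasing,
    #: ending at end-expiration (EEV)
    inflation_profile: tuple[float, ...] = (1.00, 0.93, 0.87, 0.82)
    speckles: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 32:
            raise ValueError("phantom grid must be 3D with every dimension >= 32")
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValueError("fibrosis_fraction must lie in [0, 1]")
        if self.emphysema_factor < 1.0:
            raise ValueError("emphysema_factor must be >= 1")
        if self.n_phases < 1:
            raise ValueError("need at least one phase")
        profile = self.inflation_profile[: self.n_phases]
        if len(profile) < self.n_phases:
            raise ValueError("inflation_profile shorter than n_phases")
        if any(b > a for a, b in zip(profile, profile[1:])):
            raise ValueError("inflation profile must be non-increasing (EIV first)")


@dataclass
class PhantomGroundTruth:
    """Noiseless truth for every generated phase (the test oracle)."""

    lung_masks: dict[int, np.ndarray] = field(default_factory=dict)
    lung_voxels: dict[int, int] = field(default_factory=dict)
    lung_mm3: dict[int, float] = field(default_factory=dict)
    body_mask: np.ndarray | None = None
    speckle_mask: np.ndarray | None = None


def _ellipsoid(zz, yy, xx, center, semi):
    cz, cy, cx = center
    az, ay, ax = semi
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_calibration_phantom(
    water_gray: float = 81.32,
    air_gray: float = 0.0,
    shape: tuple[int, int, int] = (64, 128, 128),
    noise_sd_gray: float = 0.0,
    seed: int = 0,
):
    """Concentric air-in-water tube phantom in raw grayscale.

    Returns ``(volume, masks)`` where ``masks['water']`` / ``masks['air']``
    select interior voxels of each material, margin-eroded so region means
    estimate the anchors cleanly.
    """
    nz, ny, nx = shape
    water_r = 0.40 * min(ny, nx)
    air_r = 0.15 * min(ny, nx)
    if air_r >= water_r:
        raise ValueError("air region must be smaller than the water region")
    yy, xx = np.ogrid[:ny, :nx]
    r2 = (yy - ny / 2.0) ** 2 + (xx - nx / 2.0) ** 2
    water_2d = (r2 <= water_r**2) & (r2 > air_r**2)
    air_inner_2d = r2 <= air_r**2

    gray = np.full(shape, air_gray, dtype=np.float64)
    gray[:, water_2d] = water_gray
    rng = np.random.default_rng(seed)
    if noise_sd_gray > 0:
        gray += rng.normal(0.0, noise_sd_gray, size=shape)

    margin = 3  # keep region means away from the material interface
    water_core = (r2 <= (water_r - margin) ** 2) & (r2 > (air_r + margin) ** 2)
    air_core = r2 <= (air_r - margin) ** 2
    masks = {
        "water": np.broadcast_to(water_2d & water_core, shape).copy(),
        "air": np.broadcast_to(air_inner_2d & air_core, shape).copy(),
    }
    return CTVolume(gray, calibrated=False), masks


def _thorax_geometry(spec: PhantomSpec):
    """Shared scene constants, in voxels, derived from grid fractions."""
    nz, ny, nx = spec.shape
    c = (nz / 2.0, ny / 2.0, nx / 2.0)
    body_semi = (0.44 * nz, 0.31 * ny, 0.38 * nx)
    lung_semi = (0.28 * nz, 0.14 * ny, 0.12 * nx)
    lung_dy = -0.02 * ny
    lung_dx = 0.17 * nx
    trachea_r = 0.03 * min(ny, nx)
    return c, body_semi, lung_semi, lung_dy, lung_dx, trachea_r


def _lung_mask(spec: PhantomSpec, scale: float) -> np.ndarray:
    """Noiseless aerated compartment at a given volumetric scale factor."""
    nz, ny, nx = spec.shape
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    c, _, lung_semi, lung_dy, lung_dx, trachea_r = _thorax_geometry(spec)
    s = scale ** (1.0 / 3.0)
    semi = tuple(a * s for a in lung_semi)
    left = _ellipsoid(zz, yy, xx, (c[0], c[1] + lung_dy, c[2] - lung_dx), semi)
    right = _ellipsoid(zz, yy, xx, (c[0], c[1] + lung_dy, c[2] + lung_dx), semi)
    # tracheal channel along x joining the lobes
    tr = trachea_r * s
    trachea = (
        ((zz - c[0]) ** 2 + (yy - (c[1] + lung_dy)) ** 2 <= tr**2)
        & (xx >= c[2] - lung_dx)
        & (xx <= c[2] + lung_dx)
    )
    return left | right | trachea


def _fibrosis_patches(
    spec: PhantomSpec, lung: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Patchy consolidation: seeded spheres inside the lung until the
    requested fraction of lung air is replaced (within one patch)."""
    target = spec.fibrosis_fraction * np.count_nonzero(lung)
    if target <= 0:
        return np.zeros_like(lung)
    nz, ny, nx = spec.shape
    patch_r = max(3, int(round(0.035 * nx)))
    coords = np.argwhere(lung)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    fibrosis = np.zeros_like(lung)
    while np.count_nonzero(fibrosis) < target:
        cz, cy, cx = coords[rng.integers(len(coords))]
        sphere = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= patch_r**2
        fibrosis |= sphere & lung
    return fibrosis


def make_thorax_phantom(
    spec: PhantomSpec, seed: int | None = None, phases: list[int] | None = None
):
    """Generate per-phase HU volumes plus noiseless ground truth.

    Parameters
    ----------
    phases : list of int, optional
        Subset of phase indices to rasterise (default: all ``n_phases``);
        ground truth is recorded for the generated phases.

    Returns
    -------
    (volumes, truth) : (dict[int, CTVolume], PhantomGroundTruth)
    """
    if seed is None:
        seed = spec.seed
    if phases is None:
        phases = list(range(spec.n_phases))
    nz, ny, nx = spec.shape
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    c, body_semi, *_ = _thorax_geometry(spec)

    body = _ellipsoid(zz, yy, xx, c, body_semi)

    # bed: a tissue slab under the animal, clear of the image border
    bed = np.zeros(spec.shape, dtype=bool)
    y0 = int(c[1] + 0.33 * ny)
    bed[nz // 10 : nz - nz // 10, y0 : y0 + max(4, ny // 40), nx // 5 : nx - nx // 5] = True
    bed &= ~body

    speckle = np.zeros(spec.shape, dtype=bool)
    if spec.speckles:
        r = max(2, nx // 70)
        for dy, dx in ((0.15 * ny, -0.15 * nx), (0.15 * ny, 0.15 * nx), (0.18 * ny, 0.0)):
            cz, cy, cx = c[0], c[1] + dy, c[2] + dx
            speckle |= (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        speckle &= body

    rng_fib = np.random.default_rng((seed, 77))
    truth = PhantomGroundTruth(body_mask=body, speckle_mask=speckle)
    volumes: dict[int, CTVolume] = {}
    voxel_mm3 = (spec.voxel_size_um / 1000.0) ** 3

    fibrosis_ref: np.ndarray | None = None
    for p in phases:
        scale = spec.inflation_profile[p] * spec.emphysema_factor
        lung = _lung_mask(spec, scale)
        if np.any(lung & ~body):
            raise ValueError("lung compartment exceeds the body; shrink the lungs")
        if speckle.any() and np.any(lung & speckle):
            raise ValueError("speckle pockets overlap the lung compartment")

        if spec.fibrosis_fraction > 0:
            # patches are placed once, on the most-inflated generated
            # phase, then intersected with each phase's lung: consolidation
            # is anatomy, not a per-phase event
            if fibrosis_ref is None:
                fibrosis_ref = _fibrosis_patches(spec, _lung_mask(spec, max(
                    spec.inflation_profile[q] * spec.emphysema_factor for q in phases
                )), rng_fib)
            fibrosis = fibrosis_ref & lung
        else:
            fibrosis = np.zeros_like(lung)

        aerated = lung & ~fibrosis
        hu = np.full(spec.shape, HU_AIR, dtype=np.float64)
        hu[body] = HU_SOFT_TISSUE
        hu[bed] = HU_BED
        hu[speckle] = HU_SPECKLE
        hu[fibrosis] = HU_FIBROSIS
        hu[aerated] = HU_AIR

        truth.lung_masks[p] = aerated
        truth.lung_voxels[p] = int(np.count_nonzero(aerated))
        truth.lung_mm3[p] = truth.lung_voxels[p] * voxel_mm3

        if spec.noise_sd_hu > 0:
            rng_noise = np.random.default_rng((seed, 1000 + p))
            hu = hu + rng_noise.normal(0.0, spec.noise_sd_hu, size=spec.shape)
        volumes[p] = CTVolume(hu, voxel_size_um=spec.voxel_size_um, calibrated=True)

    return volumes, truth


def make_breathing_trace(
    rate_hz: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
) -> BreathingTrace:
    """Pseudo-sinusoidal thorax-marker displacement sampled at 100 Hz."""
    if rate_hz <= 0:
        raise ValueError("breathing rate must be positive")
    if duration_s <= 2.0 / rate_hz:
        raise ValueError("duration too short to contain a full breathing cycle")
    t = np.arange(0.0, duration_s, 1.0 / TRACE_SAMPLE_RATE_HZ)
    y = amplitude * np.sin(2.0 * np.pi * rate_hz * t)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return BreathingTrace(t, y)


def uniform_projection_timestamps(duration_s: float, n_projections: int) -> np.ndarray:
    """Evenly spaced projection acquisition times over [0, duration)."""
    if n_projections < 1:
        raise ValueError("need at least one projection")
    return np.arange(n_projections) * (duration_s / n_projections)
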