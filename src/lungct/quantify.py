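"""Pressure-volume curves from post-sacrifice scans.

After euthanasia, decreasing airway pressures (30 → 3 cmH₂O) are applied
through a tracheal cannula and the aerated lung volume is segmented at
each pressure. The resulting PV curve is summarised by its trapezoidal
area under the curve over the measured pressure range; restrictive
(fibrotic) lungs give curves that are shifted downward and flattened,
hence a smaller AUC. No extrapolation below the lowest measured pressure
is performed. Volumes may be mm³ or raw voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PVCurve", "build_pv_curve", "pv_auc"]


@dataclass
class PVCurve:
    """Paired (pressure, volume) points, stored in ascending pressure."""

    pressures: np.ndarray  # cmH2O, strictly increasing
    volumes: np.ndarray  # mm3 or voxel counts, paired

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=np.float64)
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if self.pressures.size < 2:
            raise ValueError("a PV curve needs at least 2 points")
        if self.pressures.shape != self.volumes.shape:
            raise ValueError("pressures and volumes must have equal length")
        if not np.all(np.diff(self.pressures) > 0):
            raise ValueError("pressures must be strictly increasing with no duplicates")

    @classmethod
    def from_csv(cls, path) -> "PVCurve":
        df = pd.read_csv(path)
        return build_pv_curve(
            df["pressure_cmH2O"].to_numpy(), df["volume_mm3"].to_numpy()
        )


def build_pv_curve(pressures, volumes) -> PVCurve:
    """Build a PV curve, normalizing descending acquisition order.

    The scan protocol acquires from 30 down to 3 cmH₂O; points are
    re-sorted ascending. Duplicate pressures are an error.
    """
    p = np.asarray(pressures, dtype=np.float64)
    v = np.asarray(volumes, dtype=np.float64)
    if p.shape != v.shape:
        raise ValueError("pressures and volumes must have equal length")
    if p.size < 2:
        raise ValueError("a PV curve needs at least 2 points")
    if np.unique(p).size != p.size:
        raise ValueError("duplicate pressures in PV curve")
    order = np.argsort(p)
    return PVCurve(p[order], v[order])


def pv_auc(curve: PVCurve) -> float:
    """Trapezoidal area under the PV curve over the measured range.

    Units: volume unit × cmH₂O (mm³·cmH₂O for mm³ input).
    """
    return float(np.trapezoid(curve.volumes, curve.pressures))
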