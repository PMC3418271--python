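"""Retrospective respiratory gating.

During free-breathing acquisition the up/down movement of a thorax marker
is recorded as a pseudo-sinusoidal displacement trace. Projections are
acquired continuously through the breathing cycle; gating sorts them
post-hoc into 4 equal-length phase bins per cycle (bin 0 = earliest
inspiration .. bin 3 = end-expiration), so that each bin can be
reconstructed and segmented as a motion-frozen volume.

A cycle runs from the initiation of inspiration (a displacement trough,
i.e. end-expiration of the previous breath) to the next trough. Bin 0
therefore holds the end-inspiratory volume (EIV) and bin 3 the
end-expiratory volume (EEV, the functional residual volume). The marker's
sign convention is not fixed by the hardware; pass ``invert=True`` if the
recorded signal decreases during inspiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BreathingTrace",
    "RespiratoryCycle",
    "PhaseBinning",
    "RespiratoryVolumes",
    "detect_breath_cycles",
    "assign_phase_bins",
    "respiratory_volumes",
]

N_BINS_DEFAULT = 4
MIN_PROJECTIONS_PER_BIN = 2


@dataclass
class BreathingTrace:
    """1-D thorax-marker displacement sampled over time.

    timestamps are seconds and must be strictly increasing; displacement
    units are arbitrary (only extrema matter).
    """

    timestamps: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise ValueError("breathing trace needs at least 2 samples")
        if self.timestamps.shape != self.displacement.shape:
            raise ValueError("timestamps and displacement must have equal length")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "BreathingTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["displacement"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.timestamps, "displacement": self.displacement}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class RespiratoryCycle:
    """One breath: initiation of inspiration to end-expiration."""

    onset_time: float
    duration: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("cycle duration must be positive")

    @property
    def end_time(self) -> float:
        return self.onset_time + self.duration

    def phase_fraction(self, t: float) -> float:
        """Phase φ ∈ [0, 1) of time t within this cycle."""
        return (t - self.onset_time) / self.duration


@dataclass
class PhaseBinning:
    """Assignment of projection timestamps to respiratory phase bins.

    ``assignments[i]`` is the bin of projection i, or −1 if the projection
    fell outside every detected cycle (flagged, never silently dropped).
    ``valid`` is the QC verdict: every bin holds at least 2 projections.
    """

    n_bins: int
    assignments: np.ndarray
    occupancy: np.ndarray
    outside_cycles: np.ndarray
    valid: bool
    underfilled_bins: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"proj_index": np.arange(len(self.assignments)), "bin": self.assignments}
        )

    def qc_report(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "occupancy": self.occupancy.tolist(),
            "n_outside_cycles": int(self.outside_cycles.size),
            "outside_projection_indices": self.outside_cycles.tolist(),
            "underfilled_bins": self.underfilled_bins,
            "valid": self.valid,
        }


@dataclass
class RespiratoryVolumes:
    """Aerated volume per phase bin with EIV/EEV bookkeeping.

    EIV (end-inspiratory volume) is the bin-0 volume; EEV (end-expiratory
    volume, = functional residual volume) is the bin-3 volume. EEV is the
    preferred endpoint for group comparisons since it measures air trapping
    and is insensitive to anesthesia-induced gasping. ``consistent`` is
    False when EIV < EEV, which should not happen physiologically.
    """

    per_bin_voxels: np.ndarray
    per_bin_mm3: np.ndarray
    eiv_mm3: float
    eev_mm3: float
    eiv_voxels: int
    eev_voxels: int
    consistent: bool


def _dominant_period(trace: BreathingTrace) -> float:
    """Dominant breathing period (s) from the displacement periodogram."""
    y = trace.displacement - trace.displacement.mean()
    dt = float(np.median(np.diff(trace.timestamps)))
    freqs = np.fft.rfftfreq(y.size, d=dt)
    power = np.abs(np.fft.rfft(y)) ** 2
    power[0] = 0.0
    if not np.any(power > 0):
        raise ValueError("no respiratory cycles detected: flat displacement trace")
    return 1.0 / freqs[np.argmax(power)]


def detect_breath_cycles(
    trace: BreathingTrace,
    smoothing_window: float | None = None,
    invert: bool = False,
) -> list[RespiratoryCycle]:
    """Detect breathing cycles as trough-to-trough spans of the trace.

    The displacement is smoothed by a centered moving average (default
    window: 25% of the dominant period) and cycle onsets are its local
    minima — end-expiration, i.e. the initiation of the next inspiration.
    Partial cycles before the first and after the last trough are
    discarded because phase fraction is undefined there.

    Parameters
    ----------
    smoothing_window : float, optional
        Moving-average window in seconds. Defaults to a quarter of the
        dominant period estimated from the periodogram.
    invert : bool
        Flip the signal first, for markers that move downward during
        inspiration.
    """
    y = trace.displacement.copy()
    if invert:
        y = -y
    if np.ptp(y) == 0:
        raise ValueError("no respiratory cycles detected: constant displacement")

    dt = float(np.median(np.diff(trace.timestamps)))
    period = _dominant_period(trace)
    if smoothing_window is None:
        smoothing_window = 0.25 * period
    win = max(1, int(round(smoothing_window / dt)))
    if win % 2 == 0:
        win += 1
    if win > 1:
        kernel = np.ones(win) / win
        # reflect-pad so edge troughs are not pulled by zero padding
        ypad = np.pad(y, win // 2, mode="reflect")
        y = np.convolve(ypad, kernel, mode="valid")

    min_dist = max(1, int(round(0.5 * period / dt)))
    troughs, _ = signal.find_peaks(-y, distance=min_dist)
    if troughs.size < 2:
        raise ValueError("no respiratory cycles detected")

    times = trace.timestamps[troughs]
    return [
        RespiratoryCycle(onset_time=t0, duration=t1 - t0)
        for t0, t1 in zip(times[:-1], times[1:])
    ]


def assign_phase_bins(
    cycles: list[RespiratoryCycle],
    projection_timestamps: np.ndarray,
    n_bins: int = N_BINS_DEFAULT,
) -> PhaseBinning:
    """Assign each projection to one of ``n_bins`` equal phase bins.

    A projection at phase fraction φ within its cycle goes to bin
    ``floor(n_bins * φ)``; the bins partition each cycle into equal
    lengths. Projections outside every cycle are flagged with bin −1 and
    listed in the QC report. The binning is valid only if every bin ends
    up with at least 2 projections.
    """
    if not cycles:
        raise ValueError("no respiratory cycles supplied")
    ts = np.asarray(projection_timestamps, dtype=np.float64)
    assignments = np.full(ts.shape, -1, dtype=np.int64)

    onsets = np.array([c.onset_time for c in cycles])
    ends = np.array([c.end_time for c in cycles])
    for i, t in enumerate(ts):
        idx = np.searchsorted(onsets, t, side="right") - 1
        if idx >= 0 and t < ends[idx]:
            phi = cycles[idx].phase_fraction(t)
            assignments[i] = min(int(n_bins * phi), n_bins - 1)

    outside = np.flatnonzero(assignments < 0)
    occupancy = np.bincount(assignments[assignments >= 0], minlength=n_bins)
    underfilled = [b for b in range(n_bins) if occupancy[b] < MIN_PROJECTIONS_PER_BIN]
    return PhaseBinning(
        n_bins=n_bins,
        assignments=assignments,
        occupancy=occupancy,
        outside_cycles=outside,
        valid=not underfilled,
        underfilled_bins=underfilled,
    )


def respiratory_volumes(per_bin_results, n_bins: int = N_BINS_DEFAULT) -> RespiratoryVolumes:
    """Map per-bin segmentation results to EIV (bin 0) and EEV (bin 3).

    ``per_bin_results`` must contain exactly ``n_bins`` segmentation
    results in bin order. A consistency flag is lowered when EIV < EEV.
    """
    results = list(per_bin_results)
    if len(results) != n_bins:
        raise ValueError(f"expected {n_bins} per-bin results, got {len(results)}")
    voxels = np.array([r.voxel_count for r in results], dtype=np.int64)
    mm3 = np.array([r.volume_mm3 for r in results], dtype=np.float64)
    eiv, eev = mm3[0], mm3[-1]
    return RespiratoryVolumes(
        per_bin_voxels=voxels,
        per_bin_mm3=mm3,
        eiv_mm3=float(eiv),
        eev_mm3=float(eev),
        eiv_voxels=int(voxels[0]),
        eev_voxels=int(voxels[-1]),
        consistent=bool(eiv >= eev),
    )
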