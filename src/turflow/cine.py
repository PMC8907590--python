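"""Cine loops of vector frames and cardiac-cycle averaging of Tur series.

A cine loop is an ordered stack of vector frames acquired at a fixed frame
rate, together with the heart rate recorded during acquisition and the
vessel geometry.  Because the cardiac phase of the first frame is unknown,
the cycle statistic is simply the mean of the per-frame Tur over the first
N = floor(60 * FR / HR) frames of the loop — one heartbeat from the start of
the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .turbulence import (
    DEFAULT_MAGNITUDE_FLOOR,
    EmptyRoiError,
    RoiSpec,
    VectorFrame,
)

__all__ = ["CineLoop", "TurSeries", "frames_per_cycle", "cycle_mean_tur", "tur_series"]


@dataclass
class CineLoop:
    """An ordered sequence of 2D vector frames with acquisition metadata.

    Velocities are stored as dense arrays of shape ``(n_frames, ny, nx)`` in
    cm/s on the grid ``x`` (axial, mm) x ``y`` (depth, mm).  ``geometry``
    echoes the generator configuration (or scanner annotation): vessel
    diameter, lumen centreline depth and stenosis position, all in mm.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray  # (n_frames, ny, nx)
    vy: np.ndarray
    frame_rate: float  # Hz
    heart_rate: float  # beats/min
    vessel_diameter: float  # mm
    lumen_center_y: float  # mm
    stenosis_position: float | None = None  # mm, None for an unstenosed vessel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.heart_rate <= 0:
            raise ValueError("frame_rate and heart_rate must be positive")
        if self.vx.ndim != 3 or self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy must be (n_frames, ny, nx) arrays of equal shape")
        if self.vx.shape[1:] != (self.y.size, self.x.size):
            raise ValueError(
                f"frame shape {self.vx.shape[1:]} does not match grid "
                f"({self.y.size}, {self.x.size})"
            )

    @property
    def n_frames(self) -> int:
        return self.vx.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def frame(self, i: int) -> VectorFrame:
        """Materialise frame ``i`` as a standalone :class:`VectorFrame`."""
        return VectorFrame(
            x=self.x, y=self.y, vx=self.vx[i], vy=self.vy[i],
            frame_index=i, time=i / self.frame_rate,
        )

    def lumen_roi(self, center_x: float, width: float = 2.0) -> RoiSpec:
        """ROI at axial position ``center_x`` spanning the lumen depth."""
        half = self.vessel_diameter / 2.0
        return RoiSpec(
            center_x=center_x,
            top_y=self.lumen_center_y - half,
            bottom_y=self.lumen_center_y + half,
            width=width,
        )


@dataclass(frozen=True)
class TurSeries:
    """Per-frame Tur percentages for one fixed ROI of a cine loop."""

    values: np.ndarray  # percent, one per frame
    roi: RoiSpec
    frame_rate: float
    heart_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())

    def __len__(self) -> int:
        return self.values.size


def frames_per_cycle(frame_rate: float, heart_rate: float) -> int:
    """Number of frames in one cardiac cycle, N = floor(60 * FR / HR).

    The quotient is floored to a whole frame (never average a fractional
    frame) and clipped below at 1.
    """
    if frame_rate <= 0 or heart_rate <= 0:
        raise ValueError("frame_rate and heart_rate must be positive")
    n = math.floor(60.0 * frame_rate / heart_rate + 1e-9)
    return max(n, 1)


def cycle_mean_tur(series: TurSeries | Sequence[float], n_frames: int) -> float:
    """Mean of the first ``n_frames`` Tur values — one heartbeat from the
    start of the loop."""
    values = series.values if isinstance(series, TurSeries) else np.asarray(series, float)
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    if n_frames > values.size:
        raise ValueError(
            f"cycle of {n_frames} frames exceeds the {values.size}-frame series"
        )
    return float(np.mean(values[:n_frames]))


def tur_series(
    loop: CineLoop,
    roi: RoiSpec,
    magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR,
) -> TurSeries:
    """Per-frame Tur of ``roi`` across the whole loop.

    Vectorised over frames; numerically identical to applying
    :func:`turflow.turbulence.tur_of_frame` frame by frame.
    """
    in_x = (loop.x >= roi.x_min) & (loop.x < roi.x_max)
    in_y = (loop.y >= roi.top_y) & (loop.y < roi.bottom_y)
    if not in_x.any() or not in_y.any():
        raise EmptyRoiError(
            f"ROI x=[{roi.x_min:g},{roi.x_max:g}) y=[{roi.top_y:g},{roi.bottom_y:g}) "
            "does not overlap the grid"
        )
    vx = loop.vx[:, in_y, :][:, :, in_x].reshape(loop.n_frames, -1)
    vy = loop.vy[:, in_y, :][:, :, in_x].reshape(loop.n_frames, -1)
    speed = np.hypot(vx, vy)
    keep = speed > magnitude_floor
    n = keep.sum(axis=1)
    if np.any(n == 0):
        bad = int(np.argmax(n == 0))
        raise EmptyRoiError(
            f"ROI centred at x={roi.center_x:g} mm retains no point in frame {bad}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        angles = np.arctan2(vy, vx)
    c = np.where(keep, np.cos(angles), 0.0).sum(axis=1)
    s = np.where(keep, np.sin(angles), 0.0).sum(axis=1)
    resultant = np.minimum(np.hypot(c, s) / n, 1.0)
    values = (1.0 - resultant) * 100.0
    return TurSeries(values=values, roi=roi,
                     frame_rate=loop.frame_rate, heart_rate=loop.heart_rate)
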