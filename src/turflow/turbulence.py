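"""Direction-based turbulence index (Tur) over a rectangular ROI.

The Tur index is the circular variance of the flow-direction angles in a
region of interest, expressed as a percentage:

    Tur = (1 - sqrt(C^2 + S^2) / N) * 100,   C = sum cos(theta_i),
                                             S = sum sin(theta_i),

where ``theta_i`` is the velocity angle at the i-th measuring point and N is
the number of points retained in the ROI.  Tur is 0% when all vectors point
the same way (pure laminar flow) and approaches 100% as directions disperse;
it depends only on directions, never on speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmptyRoiError",
    "VectorFrame",
    "RoiSpec",
    "AngleSample",
    "TurValue",
    "extract_angles",
    "compute_tur",
    "tur_of_frame",
]

#: Speeds at or below this floor (cm/s) have no meaningful direction and are
#: dropped before angles are formed; atan2(0, 0) would otherwise inject an
#: arbitrary angle.
DEFAULT_MAGNITUDE_FLOOR = 1e-6


class EmptyRoiError(ValueError):
    """Raised when an ROI retains no velocity measuring point."""


@dataclass(frozen=True)
class VectorFrame:
    """One time point of a 2D velocity field on a regular grid.

    Parameters
    ----------
    x, y
        Grid coordinates in mm (axial / depth), strictly increasing and
        uniformly spaced.
    vx, vy
        Velocity components in cm/s, shape ``(len(y), len(x))``.
    frame_index
        Ordinal position of the frame in its cine loop.
    time
        Acquisition time of the frame in seconds.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    frame_index: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.vx.shape != (self.y.size, self.x.size) or self.vy.shape != self.vx.shape:
            raise ValueError(
                f"velocity grids must have shape (len(y), len(x)) = "
                f"({self.y.size}, {self.x.size}); got vx {self.vx.shape}, vy {self.vy.shape}"
            )
        if not (np.all(np.isfinite(self.vx)) and np.all(np.isfinite(self.vy))):
            raise ValueError("velocity components must be finite")


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular measurement box: 2 mm wide axially, spanning the lumen.

    ``center_x`` is the axial position of the ROI centre in mm (for
    post-stenotic profiles this is the stenosis position plus the distance
    distal to it).  ``top_y``/``bottom_y`` bound the lumen so that
    ``bottom_y - top_y`` equals the internal vessel diameter.  Both axes use
    a half-open convention ``[min, max)`` so adjacent ROIs tile the vessel
    without double-counting grid points.
    """

    center_x: float
    top_y: float
    bottom_y: float
    width: float = 2.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"ROI width must be positive, got {self.width}")
        if self.bottom_y <= self.top_y:
            raise ValueError("bottom_y must exceed top_y")

    @property
    def x_min(self) -> float:
        return self.center_x - self.width / 2.0

    @property
    def x_max(self) -> float:
        return self.center_x + self.width / 2.0


@dataclass(frozen=True)
class AngleSample:
    """Flow-direction angles (radians, in (-pi, pi]) retained from an ROI."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float).ravel())

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class TurValue:
    """A Tur index with its circular-statistics ingredients."""

    tur: float
    n_points: int
    C: float
    S: float


def extract_angles(
    frame: VectorFrame,
    roi: RoiSpec,
    magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR,
) -> AngleSample:
    """Collect flow angles from every grid point inside an ROI.

    A point contributes ``atan2(vy, vx)`` iff it lies in the half-open ROI
    rectangle and its speed exceeds ``magnitude_floor``.

    Raises
    ------
    EmptyRoiError
        If no point is retained (the Tur index is then undefined).
    """
    if magnitude_floor < 0:
        raise ValueError("magnitude_floor must be non-negative")
    in_x = (frame.x >= roi.x_min) & (frame.x < roi.x_max)
    in_y = (frame.y >= roi.top_y) & (frame.y < roi.bottom_y)
    if not in_x.any() or not in_y.any():
        raise EmptyRoiError(
            f"ROI x=[{roi.x_min:g},{roi.x_max:g}) y=[{roi.top_y:g},{roi.bottom_y:g}) "
            "does not overlap the grid"
        )
    vx = frame.vx[np.ix_(in_y, in_x)]
    vy = frame.vy[np.ix_(in_y, in_x)]
    speed = np.hypot(vx, vy)
    keep = speed > magnitude_floor
    if not keep.any():
        raise EmptyRoiError(
            f"ROI centred at x={roi.center_x:g} mm retains no point above the "
            f"magnitude floor {magnitude_floor:g} cm/s"
        )
    return AngleSample(np.arctan2(vy[keep], vx[keep]))


def compute_tur(sample: AngleSample) -> TurValue:
    """Tur index of an angle sample: ``(1 - R) * 100`` with R the mean
    resultant length ``sqrt(C^2 + S^2)/N``."""
    n = sample.n
    if n < 1:
        raise EmptyRoiError("Tur is undefined for an empty angle sample")
    c = float(np.sum(np.cos(sample.angles)))
    s = float(np.sum(np.sin(sample.angles)))
    resultant = np.hypot(c, s) / n
    # guard the 1-ulp overshoot of hypot for perfectly aligned angles
    tur = (1.0 - min(resultant, 1.0)) * 100.0
    return TurValue(tur=tur, n_points=n, C=c, S=s)


def tur_of_frame(
    frame: VectorFrame,
    roi: RoiSpec,
    magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR,
) -> float:
    """Convenience composition: extract angles then compute Tur."""
    return compute_tur(extract_angles(frame, roi, magnitude_floor)).tur
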