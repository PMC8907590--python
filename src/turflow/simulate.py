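"""Synthetic pulsatile stenotic-flow generator.

Emulates what a high-frame-rate vector flow scanner would record from a
longitudinal view of a small straight artery (default: a 3 mm vessel in a
2.4 cm x 1.5 cm image, 1.5 s loops at 380 Hz, i.e. 570 frames):

* a parabolic (Poiseuille) axial profile modulated by a raised-cosine
  pulsatile waveform — the laminar baseline;
* an optional stenosis: the lumen radius narrows by ``stenosis_severity``
  over a short cosine taper ending at ``stenosis_position`` and the local
  centreline velocity rises by conservation of flux;
* downstream of the stenosis, a train of counter-rotating Gaussian vortices
  superposed on the base flow under the envelope

      A(x) = vortex_strength * severity * (x/p) * exp(1 - x/p),

  which rises from zero at the stenosis, peaks at ``x = peak_distance`` and
  decays — the qualitative signature of post-stenotic turbulence;
* independent von Mises angular jitter (concentration ``kappa``) rotating
  every in-lumen vector, so even laminar flow has a small, analytically
  known turbulence index.

The vortex train is advected by exactly one pattern wavelength per cardiac
cycle, so averages over a full cycle are invariant to axial translation of
the pattern and the measured Tur-versus-distance profile tracks the envelope
A(x) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .cine import CineLoop, frames_per_cycle
from .turbulence import AngleSample

__all__ = [
    "ConfigurationError",
    "FlowConfig",
    "CardiacWaveform",
    "generate_laminar",
    "generate_stenotic",
    "generate_noise_field",
]


class ConfigurationError(ValueError):
    """Raised for a geometrically or physically invalid flow configuration."""


@dataclass(frozen=True)
class FlowConfig:
    """Geometry, acquisition and disturbance parameters of a synthetic loop.

    Lengths in mm, velocities in cm/s, frame_rate in Hz, heart_rate in
    beats/min, duration in s.  ``stenosis_severity`` is the fractional
    diameter reduction in [0, 1); ``peak_distance`` and ``decay_length``
    shape the downstream disturbance envelope; ``kappa`` is the von Mises
    concentration of the angular jitter (larger = straighter flow).
    """

    vessel_diameter: float = 3.0
    image_width: float = 24.0
    image_depth: float = 15.0
    grid_spacing: float = 0.1
    frame_rate: float = 380.0
    heart_rate: float = 120.0
    duration: float = 1.5
    stenosis_position: float = 4.0
    stenosis_severity: float = 0.0
    peak_distance: float = 7.0
    decay_length: float = 5.0
    vortex_strength: float = 120.0
    kappa: float = 5000.0
    peak_velocity: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        if self.vessel_diameter <= 0:
            raise ConfigurationError("vessel_diameter must be positive")
        if self.vessel_diameter > self.image_depth:
            raise ConfigurationError(
                f"lumen (diameter {self.vessel_diameter} mm) does not fit inside "
                f"the image depth ({self.image_depth} mm)"
            )
        if not (0 <= self.stenosis_position <= self.image_width):
            raise ConfigurationError(
                f"stenosis_position {self.stenosis_position} mm lies outside the "
                f"image width ({self.image_width} mm)"
            )
        if not (0 <= self.stenosis_severity < 1):
            raise ConfigurationError("stenosis_severity must be in [0, 1)")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be non-negative")
        if self.frame_rate <= 0 or self.heart_rate <= 0 or self.duration <= 0:
            raise ConfigurationError("frame_rate, heart_rate and duration must be positive")
        if self.peak_distance <= 0 or self.decay_length <= 0:
            raise ConfigurationError("peak_distance and decay_length must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))

    @property
    def lumen_center_y(self) -> float:
        return self.image_depth / 2.0

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Axial and depth coordinate vectors (mm)."""
        nx = int(round(self.image_width / self.grid_spacing)) + 1
        ny = int(round(self.image_depth / self.grid_spacing)) + 1
        return (np.arange(nx) * self.grid_spacing, np.arange(ny) * self.grid_spacing)


@dataclass(frozen=True)
class CardiacWaveform:
    """Periodic velocity modulation over the cardiac cycle.

    ``raised_cosine_pulse``: a smooth systolic pulse occupying
    ``systolic_fraction`` of the cycle, rising from ``diastolic_floor`` of
    the peak velocity to 1 and back, with flat diastole at the floor.
    ``constant`` holds the waveform at 1 (steady flow).
    """

    shape: Literal["raised_cosine_pulse", "constant"] = "raised_cosine_pulse"
    systolic_fraction: float = 0.3
    diastolic_floor: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.systolic_fraction <= 1):
            raise ConfigurationError("systolic_fraction must be in (0, 1]")
        if not (0 <= self.diastolic_floor <= 1):
            raise ConfigurationError("diastolic_floor must be in [0, 1]")

    def __call__(self, t: np.ndarray | float, heart_rate: float) -> np.ndarray:
        """Waveform value(s) in [diastolic_floor, 1] at time(s) ``t`` (s)."""
        if self.shape == "constant":
            return np.ones_like(np.asarray(t, dtype=float))
        phase = np.mod(np.asarray(t, dtype=float) * heart_rate / 60.0, 1.0)
        w = np.full_like(phase, self.diastolic_floor)
        sys = phase < self.systolic_fraction
        pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[sys] / self.systolic_fraction))
        w[sys] = self.diastolic_floor + (1.0 - self.diastolic_floor) * pulse
        return w


# ---------------------------------------------------------------------------
# lumen geometry

def _lumen_radius(x: np.ndarray, config: FlowConfig) -> np.ndarray:
    """Local lumen radius R(x) in mm.

    The stenotic segment is a raised-cosine constriction of axial extent one
    vessel diameter whose downstream edge sits at ``stenosis_position``, so
    post-stenotic distances are measured from the point where the lumen has
    fully recovered.
    """
    r0 = config.vessel_diameter / 2.0
    r = np.full_like(x, r0, dtype=float)
    s = config.stenosis_severity
    if s > 0:
        half = config.vessel_diameter / 2.0  # taper half-length, mm
        center = config.stenosis_position - half
        local = np.abs(x - center) <= half
        bump = 0.5 * (1.0 + np.cos(np.pi * (x[local] - center) / half))
        r[local] = r0 * (1.0 - s * bump)
    return r


def _disturbance_envelope(x: np.ndarray, config: FlowConfig) -> np.ndarray:
    """Perturbation amplitude A(x) in cm/s versus axial position (mm)."""
    rel = (x - config.stenosis_position) / config.peak_distance
    a = np.where(rel > 0, rel * np.exp(1.0 - rel), 0.0)
    return config.vortex_strength * config.stenosis_severity * a


def _vortex_pattern(
    x: np.ndarray,
    y: np.ndarray,
    phases: np.ndarray,
    config: FlowConfig,
    phase0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude counter-rotating vortex train at each cycle phase.

    Returns (px, py) of shape (n_phases, len(y), len(x)).  Vortex cores sit
    on the centreline, one vessel diameter apart with alternating
    circulation (spatial period = 2 diameters), Gaussian core radius D/4,
    peak tangential speed 1.  ``phases`` in [0, 1) advect the train by one
    period per unit phase.
    """
    d = config.vessel_diameter
    spacing, sigma, period = d, d / 4.0, 2.0 * d
    yc = config.lumen_center_y
    x0 = config.stenosis_position
    x_max = float(x[-1])
    # enough cores to cover [x0 - margin, x_max + margin] at every phase
    margin = 4.0 * sigma + period
    n_cores = int(np.ceil((x_max + margin - (x0 - margin)) / spacing)) + 2
    k = np.arange(n_cores)
    base_centers = x0 - margin + k * spacing
    signs = np.where(k % 2 == 0, 1.0, -1.0)

    px = np.zeros((phases.size, y.size, x.size))
    py = np.zeros_like(px)
    dy = (y - yc)[None, :, None]
    gamma = np.sqrt(np.e)  # normalises peak tangential speed to 1
    shift = (phase0 + phases * period) % period
    for center, sign in zip(base_centers, signs):
        dx = x[None, None, :] - (center + shift)[:, None, None]
        g = sign * gamma * np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
        px += g * (-dy / sigma)
        py += g * (dx / sigma)
    return px, py


# ---------------------------------------------------------------------------
# generators

def _generate(config: FlowConfig, waveform: CardiacWaveform, with_vortices: bool) -> CineLoop:
    x, y = config.grid()
    yc = config.lumen_center_y
    r0 = config.vessel_diameter / 2.0
    if yc - r0 < 0 or yc + r0 > config.image_depth:
        raise ConfigurationError("lumen extends outside the image depth")

    n_frames = config.n_frames
    t = np.arange(n_frames) / config.frame_rate
    w = waveform(t, config.heart_rate)

    lumen_rows = np.abs(y - yc) <= r0 + 1e-12
    y_lum = y[lumen_rows]

    # static base speed S(x, y): parabolic profile in the local lumen with
    # centreline velocity raised by flux conservation through the throat
    radius = _lumen_radius(x, config)
    u_center = config.peak_velocity * (r0 / radius) ** 2
    rel = (y_lum[:, None] - yc) / radius[None, :]
    base = u_center[None, :] * (1.0 - rel**2)
    base[np.abs(rel) >= 1.0] = 0.0  # outside the local (narrowed) lumen

    vx_lum = w[:, None, None] * base[None, :, :]
    vy_lum = np.zeros_like(vx_lum)

    seq = np.random.SeedSequence(config.seed)
    jitter_seq, vortex_seq = seq.spawn(2)

    if with_vortices and config.vortex_strength > 0 and config.stenosis_severity > 0:
        n_cycle = frames_per_cycle(config.frame_rate, config.heart_rate)
        phase0 = float(
            np.random.default_rng(vortex_seq).uniform(0.0, 2.0 * config.vessel_diameter)
        )
        phases = (np.arange(n_cycle) / n_cycle) % 1.0
        px, py = _vortex_pattern(x, y_lum, phases, config, phase0)
        # the disturbance rides on the local flow: modulate by the same
        # parabolic shape as the base profile so the flow-angle dispersion is
        # uniform across the lumen depth and tracks the envelope A(x) alone
        shape = np.divide(base, u_center[None, :],
                          out=np.zeros_like(base), where=u_center[None, :] > 0)
        amp = _disturbance_envelope(x, config)[None, None, :] * shape[None, :, :]
        idx = np.arange(n_frames) % n_cycle
        vx_lum += w[:, None, None] * amp * px[idx]
        vy_lum += w[:, None, None] * amp * py[idx]

    # von Mises angular jitter: rotate each in-lumen vector, preserving speed
    if np.isfinite(config.kappa):
        eps = np.random.default_rng(jitter_seq).vonmises(
            0.0, config.kappa, size=vx_lum.shape
        )
        speed = np.hypot(vx_lum, vy_lum)
        angle = np.arctan2(vy_lum, vx_lum) + eps
        vx_lum = speed * np.cos(angle)
        vy_lum = speed * np.sin(angle)

    vx = np.zeros((n_frames, y.size, x.size))
    vy = np.zeros_like(vx)
    vx[:, lumen_rows, :] = vx_lum
    vy[:, lumen_rows, :] = vy_lum

    return CineLoop(
        x=x, y=y, vx=vx, vy=vy,
        frame_rate=config.frame_rate,
        heart_rate=config.heart_rate,
        vessel_diameter=config.vessel_diameter,
        lumen_center_y=yc,
        stenosis_position=config.stenosis_position if config.stenosis_severity > 0 else None,
        meta={"config": asdict(config), "waveform": asdict(waveform)},
    )


def generate_laminar(
    config: FlowConfig, waveform: CardiacWaveform | None = None
) -> CineLoop:
    """Baseline loop: pulsatile parabolic flow with angular jitter only.

    Intended for ``stenosis_severity = 0`` (a straight, unstenosed vessel);
    with a nonzero severity it produces the narrowed base flow without the
    downstream vortex perturbation.
    """
    return _generate(config, waveform or CardiacWaveform(), with_vortices=False)


def generate_stenotic(
    config: FlowConfig, waveform: CardiacWaveform | None = None
) -> CineLoop:
    """Post-stenotic loop: narrowed base flow plus the advected vortex train
    under the rise-peak-decay envelope A(x)."""
    if config.stenosis_severity <= 0:
        raise ConfigurationError("generate_stenotic requires stenosis_severity > 0")
    return _generate(config, waveform or CardiacWaveform(), with_vortices=True)


def generate_noise_field(n_points: int, kappa: float, seed: int) -> AngleSample:
    """Draw ``n_points`` angles from a von Mises(0, kappa) distribution.

    The mean resultant length of this distribution is the Bessel ratio
    I1(kappa)/I0(kappa), giving a closed-form expected Tur index of
    ``(1 - I1/I0) * 100`` — the analytic oracle for the empirical statistic.
    """
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    return AngleSample(rng.vonmises(0.0, kappa, size=n_points))
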