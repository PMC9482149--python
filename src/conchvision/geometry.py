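"""Viewing geometry and looming-stimulus expansion profiles.

A looming stimulus is a disc whose angular size in the observer's visual
field grows over time, emulating the direct approach of a predator.  This
module holds the mapping between physical size on the display, pixel size
and visual angle for an observer at a fixed viewing distance, together
with the two angular-size trajectories used in the behavioural
experiments: an exponential expansion (slow start, rapid finish, 10 s)
for the contrast-sensitivity series and a linear expansion (5 s) for the
spatial-resolution series.  Both run from near zero up to 83 deg of the
visual field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "ProfileShape",
    "ViewingConfig",
    "ExpansionProfile",
    "angular_size",
    "physical_width",
    "alpha_at",
    "time_to_reach",
]


class ProfileShape(str, Enum):
    """Shape of the angular-size-versus-time trajectory."""

    LINEAR = "linear"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class ViewingConfig:
    """Physical geometry linking the display to the observer.

    Parameters
    ----------
    viewing_distance_mm : float
        Distance from the observer's eye to the display plane (mm).
        Default 50 mm, the experimental viewing distance.
    pixel_pitch_mm : float
        Physical size of one display pixel (mm/px).
    frame_width_px, frame_height_px : int
        Rendered frame dimensions in pixels.
    container_radius_mm : float or None
        Radius of the cylindrical experimental vessel (mm), recorded for
        provenance only.  Refraction through the curved wall is not
        modelled; along the curved plane it only makes the behavioural
        resolution a limiting value.
    """

    viewing_distance_mm: float = 50.0
    pixel_pitch_mm: float = 0.25
    frame_width_px: int = 256
    frame_height_px: int = 256
    container_radius_mm: float | None = 60.0

    def __post_init__(self) -> None:
        if self.viewing_distance_mm <= 0:
            raise ConfigurationError("viewing_distance_mm must be > 0")
        if self.pixel_pitch_mm <= 0:
            raise ConfigurationError("pixel_pitch_mm must be > 0")
        if self.frame_width_px < 1 or self.frame_height_px < 1:
            raise ConfigurationError("frame dimensions must be >= 1 px")

    @property
    def pixels_per_degree(self) -> float:
        """Pixels subtended by one degree at the frame centre."""
        return physical_width(1.0, self) / self.pixel_pitch_mm

    def pixel_angular_size_deg(self) -> float:
        """Visual angle of a single pixel — the smallest renderable object."""
        return angular_size(self.pixel_pitch_mm, self)


def angular_size(physical_width_mm: float, cfg: ViewingConfig) -> float:
    """Visual angle (deg) subtended by an object of the given width.

    Uses the exact perpendicular-viewing relation
    ``alpha = 2 * arctan(w / (2 * D))``.
    """
    if physical_width_mm < 0:
        raise DomainError("physical width must be >= 0")
    return math.degrees(2.0 * math.atan2(physical_width_mm, 2.0 * cfg.viewing_distance_mm))


def physical_width(angle_deg: float, cfg: ViewingConfig) -> float:
    """On-screen width (mm) subtending the given visual angle; inverse of
    :func:`angular_size`."""
    if angle_deg < 0 or angle_deg >= 180.0:
        raise DomainError("angle must lie in [0, 180) deg")
    return 2.0 * cfg.viewing_distance_mm * math.tan(math.radians(angle_deg) / 2.0)


@dataclass(frozen=True)
class ExpansionProfile:
    """Angular size versus time of one expanding-stimulus presentation.

    ``linear`` grows as ``alpha_max * t / T``; ``exponential`` grows as
    ``alpha_start * exp(g t)`` with ``g = ln(alpha_max / alpha_start) / T``
    so that both reach ``alpha_max`` exactly at ``t = T``.  The
    exponential trajectory cannot start at 0 deg; ``alpha_start_deg``
    should be set to the angular size of one pixel at the configured
    geometry (see :meth:`ViewingConfig.pixel_angular_size_deg`).
    """

    shape: ProfileShape = ProfileShape.EXPONENTIAL
    duration_s: float = 10.0
    alpha_max_deg: float = 83.0
    alpha_start_deg: float | None = None
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", ProfileShape(self.shape))
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if not 0 < self.alpha_max_deg <= 180:
            raise ConfigurationError("alpha_max_deg must lie in (0, 180]")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if self.shape is ProfileShape.EXPONENTIAL:
            if self.alpha_start_deg is None:
                raise ConfigurationError(
                    "exponential profile needs alpha_start_deg > 0 "
                    "(e.g. ViewingConfig.pixel_angular_size_deg())"
                )
            if not 0 < self.alpha_start_deg <= self.alpha_max_deg:
                raise ConfigurationError("need 0 < alpha_start_deg <= alpha_max_deg")

    # -- trajectory ----------------------------------------------------

    @property
    def growth_rate(self) -> float:
        """Exponential rate g (1/s); 0 for the degenerate constant case."""
        return math.log(self.alpha_max_deg / self.alpha_start_deg) / self.duration_s

    def alpha_at(self, t: float) -> float:
        """Angular size (deg) at time ``t`` seconds from onset."""
        if t < 0 or t > self.duration_s:
            raise DomainError(f"t={t} outside [0, {self.duration_s}]")
        if self.shape is ProfileShape.LINEAR:
            return self.alpha_max_deg * t / self.duration_s
        return self.alpha_start_deg * math.exp(self.growth_rate * t)

    def time_to_reach(self, angle_deg: float) -> float:
        """Time (s) at which the trajectory reaches ``angle_deg``; inverse
        of :meth:`alpha_at`."""
        if self.shape is ProfileShape.LINEAR:
            if not 0 <= angle_deg <= self.alpha_max_deg:
                raise DomainError("angle outside [0, alpha_max] for linear profile")
            return self.duration_s * angle_deg / self.alpha_max_deg
        if not self.alpha_start_deg <= angle_deg <= self.alpha_max_deg:
            raise DomainError("angle outside [alpha_start, alpha_max] for exponential profile")
        if self.growth_rate == 0.0:  # degenerate constant trajectory
            return 0.0
        return math.log(angle_deg / self.alpha_start_deg) / self.growth_rate

    def frame_times(self) -> np.ndarray:
        """Sample times of the rendered frame sequence (inclusive of T)."""
        n = int(round(self.duration_s * self.frame_rate))
        return np.linspace(0.0, self.duration_s, n + 1)


# Functional aliases mirroring the method surface.

def alpha_at(profile: ExpansionProfile, t: float) -> float:
    """Angular size (deg) of ``profile`` at time ``t``."""
    return profile.alpha_at(t)


def time_to_reach(profile: ExpansionProfile, angle_deg: float) -> float:
    """Time (s) at which ``profile`` reaches ``angle_deg``."""
    return profile.time_to_reach(angle_deg)
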