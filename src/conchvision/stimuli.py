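"""Stimulus rendering and display photometry.

Two stimulus families are produced as 8-bit greyscale frames:

* a *contrast loom* — a dark disc expanding on a bright uniform
  background, labelled by the Michelson contrast between disc and
  background luminance;
* a *resolution loom* — a grey disc expanding on a black-and-white
  checkerboard whose grey level is calibrated to the space-average
  luminance of the checks (isoluminant), so the disc is invisible to an
  eye that cannot resolve the check pattern.

Byte values are mapped to relative luminance through a power-law display
model ``L = (b/255)**gamma``.  The default gamma of 1 treats byte values
as linear luminance, which is the convention under which the published
contrast labels (e.g. 0.07 for byte 220 against 255) arise; a grey byte
of 153 as the isoluminant point of a 0/255 checkerboard instead implies
a non-linear display with gamma close to 1.36, so gamma is exposed as
configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .exceptions import ConfigurationError, DomainError
from .geometry import ExpansionProfile, ViewingConfig, physical_width

__all__ = [
    "DisplayModel",
    "LoomSpec",
    "CheckerLoomSpec",
    "michelson_contrast",
    "isoluminant_grey",
    "render_loom_frame",
    "render_checker_frame",
    "write_frame_sequence",
    "read_frame_sequence",
    "CONTRAST_SERIES_BYTES",
]

#: Object byte values of the published contrast-sensitivity loom series
#: (background byte 255 throughout).
CONTRAST_SERIES_BYTES: tuple[int, ...] = (0, 50, 100, 150, 175, 200, 210, 220, 230)


def _check_byte(b: int, name: str) -> int:
    if not 0 <= int(b) <= 255:
        raise DomainError(f"{name} must lie in [0, 255], got {b}")
    return int(b)


@dataclass(frozen=True)
class DisplayModel:
    """Power-law byte-to-luminance mapping ``L = (b/255)**gamma``."""

    gamma: float = 1.0
    max_byte: int = 255

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ConfigurationError("display gamma must be > 0")

    def luminance(self, byte):
        """Relative luminance in [0, 1] of a byte value (scalar or array)."""
        b = np.asarray(byte, dtype=float)
        out = (b / self.max_byte) ** self.gamma
        return float(out) if np.isscalar(byte) else out


def michelson_contrast(object_byte: int, background_byte: int, display: DisplayModel | None = None) -> float:
    """Michelson contrast ``(Lmax - Lmin) / (Lmax + Lmin)`` between two bytes.

    Symmetric in its byte arguments and 0 for identical bytes (including
    the degenerate all-black pair).  The value is returned unrounded;
    the published labels round to 2 decimals.
    """
    display = display or DisplayModel()
    lo = display.luminance(_check_byte(object_byte, "object_byte"))
    lb = display.luminance(_check_byte(background_byte, "background_byte"))
    lmax, lmin = max(lo, lb), min(lo, lb)
    if lmax + lmin == 0.0:
        return 0.0
    return (lmax - lmin) / (lmax + lmin)


def isoluminant_grey(black_byte: int, white_byte: int, display: DisplayModel | None = None) -> int:
    """Byte value whose luminance best matches the mean luminance of the
    two check bytes; ties broken toward the lower byte."""
    display = display or DisplayModel()
    b = _check_byte(black_byte, "black_byte")
    w = _check_byte(white_byte, "white_byte")
    target = 0.5 * (display.luminance(b) + display.luminance(w))
    bytes_ = np.arange(256)
    err = np.abs(display.luminance(bytes_) - target)
    return int(np.argmin(err))  # argmin returns the first (lowest) byte on ties


@dataclass(frozen=True)
class LoomSpec:
    """One contrast-sensitivity presentation: dark disc on bright field."""

    object_byte: int
    background_byte: int = 255
    profile: ExpansionProfile = ExpansionProfile(
        shape="exponential", duration_s=10.0, alpha_max_deg=83.0, alpha_start_deg=0.3
    )

    def __post_init__(self) -> None:
        _check_byte(self.object_byte, "object_byte")
        _check_byte(self.background_byte, "background_byte")

    def contrast(self, display: DisplayModel | None = None) -> float:
        return michelson_contrast(self.object_byte, self.background_byte, display)

    def contrast_label(self, display: DisplayModel | None = None) -> float:
        """Contrast rounded to 2 decimals, the published labelling."""
        return round(self.contrast(display), 2)


@dataclass(frozen=True)
class CheckerLoomSpec:
    """One spatial-resolution presentation: grey disc on a checkerboard."""

    check_width_deg: float
    black_byte: int = 0
    white_byte: int = 255
    grey_byte: int = 153
    profile: ExpansionProfile = ExpansionProfile(
        shape="linear", duration_s=5.0, alpha_max_deg=83.0
    )

    def __post_init__(self) -> None:
        for name in ("black_byte", "white_byte", "grey_byte"):
            _check_byte(getattr(self, name), name)
        if not self.black_byte < self.grey_byte < self.white_byte:
            raise ConfigurationError("need black_byte < grey_byte < white_byte")
        if self.check_width_deg <= 0:
            raise ConfigurationError("check_width_deg must be > 0")

    def check_width_px(self, cfg: ViewingConfig) -> int:
        px = round(physical_width(self.check_width_deg, cfg) / cfg.pixel_pitch_mm)
        if px < 1:
            raise ConfigurationError(
                f"check width {self.check_width_deg} deg is below one pixel "
                f"at pitch {cfg.pixel_pitch_mm} mm/px — unrenderable"
            )
        return px


def _disc_mask(cfg: ViewingConfig, radius_px: float) -> np.ndarray:
    """Boolean mask of the centred stimulus disc."""
    h, w = cfg.frame_height_px, cfg.frame_width_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def _radius_px(profile: ExpansionProfile, cfg: ViewingConfig, t: float) -> float:
    return physical_width(profile.alpha_at(t), cfg) / 2.0 / cfg.pixel_pitch_mm


def render_loom_frame(spec: LoomSpec, cfg: ViewingConfig, t: float) -> np.ndarray:
    """Render the contrast loom at time ``t`` as a uint8 (H, W) array."""
    frame = np.full((cfg.frame_height_px, cfg.frame_width_px), spec.background_byte, dtype=np.uint8)
    frame[_disc_mask(cfg, _radius_px(spec.profile, cfg, t))] = spec.object_byte
    return frame


def checkerboard(spec: CheckerLoomSpec, cfg: ViewingConfig) -> np.ndarray:
    """Full-frame checkerboard, anchored with a black check at top-left."""
    px = spec.check_width_px(cfg)
    yy, xx = np.ogrid[: cfg.frame_height_px, : cfg.frame_width_px]
    parity = (yy // px + xx // px) % 2
    return np.where(parity == 0, spec.black_byte, spec.white_byte).astype(np.uint8)


def render_checker_frame(spec: CheckerLoomSpec, cfg: ViewingConfig, t: float) -> np.ndarray:
    """Render the isoluminant checker loom at time ``t``."""
    frame = checkerboard(spec, cfg)
    frame[_disc_mask(cfg, _radius_px(spec.profile, cfg, t))] = spec.grey_byte
    return frame


def render_sequence(render, spec, cfg: ViewingConfig) -> list[np.ndarray]:
    """Render every frame of a presentation at the profile frame rate."""
    return [render(spec, cfg, t) for t in spec.profile.frame_times()]


_FRAME_RE = re.compile(r"frame_(\d{4})\.png$")


def write_frame_sequence(frames: Sequence[np.ndarray], path: str | Path) -> list[Path]:
    """Write frames as ``frame_0000.png`` ... under ``path`` (8-bit grey)."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        out = []
        for i, frame in enumerate(frames):
            p = path / f"frame_{i:04d}.png"
            Image.fromarray(np.asarray(frame, dtype=np.uint8), mode="L").save(p)
            out.append(p)
    except OSError as exc:
        raise IOError(f"cannot write frame sequence under {path}: {exc}") from exc
    return out


def read_frame_sequence(path: str | Path) -> list[np.ndarray]:
    """Read back a sequence written by :func:`write_frame_sequence`."""
    files = sorted(p for p in Path(path).glob("frame_*.png") if _FRAME_RE.search(p.name))
    return [np.asarray(Image.open(p).convert("L"), dtype=np.uint8) for p in files]
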