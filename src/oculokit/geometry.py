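"""Screen geometry and visual-angle conversions.

Gaze is stored in degrees of visual angle throughout the package; screen
units (cm or pixels) only appear at ingest time. The conversion uses the
per-axis arctangent model for a flat screen viewed head-on at eye level:
``angle = arctan(offset / viewing_distance)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry", "degrees_from_screen", "screen_from_degrees"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical layout of the display relative to the observer.

    Parameters
    ----------
    viewing_distance : float
        Eye-to-screen distance in cm (default 45, the tablet-on-pole-mount
        setup this package targets).
    screen_width, screen_height : float
        Physical screen size in cm.
    pixel_pitch : float
        Size of one pixel in cm.
    """

    viewing_distance: float = 45.0
    screen_width: float = 26.3
    screen_height: float = 19.7
    pixel_pitch: float = 0.0096

    def __post_init__(self) -> None:
        for name in ("viewing_distance", "screen_width", "screen_height", "pixel_pitch"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be finite and > 0, got {v!r}")


def _check_finite(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite {what} passed to geometry conversion")
    return arr


def degrees_from_screen(offset_x_cm, offset_y_cm, geometry: ScreenGeometry):
    """Convert on-screen offsets (cm from screen center) to visual angle.

    Right/up positive. Accepts scalars or arrays; returns a pair of
    degrees-of-visual-angle values of the same shape.
    """
    ox = _check_finite(offset_x_cm, "x offset")
    oy = _check_finite(offset_y_cm, "y offset")
    d = geometry.viewing_distance
    return np.degrees(np.arctan(ox / d)), np.degrees(np.arctan(oy / d))


def screen_from_degrees(x_deg, y_deg, geometry: ScreenGeometry):
    """Inverse of :func:`degrees_from_screen` (round-trips to < 1e-9 cm)."""
    xd = _check_finite(x_deg, "x angle")
    yd = _check_finite(y_deg, "y angle")
    d = geometry.viewing_distance
    return d * np.tan(np.radians(xd)), d * np.tan(np.radians(yd))
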