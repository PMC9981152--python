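"""Screen and rendering geometry: degree/pixel/physical-size conversions.

Two geometries coexist in this package:

* :class:`ScreenGeometry` — a physical display (pixel raster plus physical
  size and viewing distance).  Used for exact visual-angle computations,
  e.g. how large a figure appears to a freely moving animal at a given
  distance from a touchscreen.
* :class:`CanvasGeometry` — the retinotopic raster on which stimulus movies
  are rendered, specified directly in degrees of visual angle with a fixed
  pixels-per-degree resolution.  This is the small-angle (linear) mapping
  appropriate for a head-fixed observer with the screen centered on the
  receptive fields under study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "CanvasGeometry",
    "visual_angle_deg",
    "angular_geometry",
    "cycles_per_degree",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """A physical display raster.

    Parameters
    ----------
    width_px, height_px
        Pixel dimensions of the display.
    width_cm, height_cm
        Physical dimensions.  Pixel pitch ``width_cm / width_px`` is assumed
        constant across the screen.
    view_distance_cm
        Eye-to-screen distance.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    view_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "view_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cm_per_px(self) -> float:
        return self.width_cm / self.width_px

    def px_to_cm(self, n_px: float) -> float:
        return n_px * self.cm_per_px

    def visual_angle_of_px(self, n_px: float,
                           distance_cm: float | None = None) -> float:
        """Exact visual angle (degrees) subtended by ``n_px`` pixels."""
        return visual_angle_deg(self.px_to_cm(n_px),
                                self.view_distance_cm
                                if distance_cm is None else distance_cm)


# Touchscreen used for the freely-moving behavior: 24 x 18.5 cm, 800 x 600 px.
# Stimulus movies (200 px wide) were stretched to the full screen width, so a
# movie pixel is 24/200 cm on the glass.
BEHAVIOR_SCREEN = ScreenGeometry(width_px=800, height_px=600,
                                 width_cm=24.0, height_cm=18.5,
                                 view_distance_cm=10.0)
BEHAVIOR_MOVIE_WIDTH_PX = 200


def visual_angle_deg(object_width_cm: float, view_distance_cm: float) -> float:
    """Visual angle of a centered object: ``2 atan(w / 2d)`` in degrees."""
    if view_distance_cm <= 0:
        raise ValueError("view distance must be positive")
    if object_width_cm < 0:
        raise ValueError("object width must be nonnegative")
    return math.degrees(2.0 * math.atan2(object_width_cm / 2.0,
                                         view_distance_cm))


def angular_geometry(geometry: ScreenGeometry, object_width_px: float,
                     view_distance_cm: float | None = None,
                     movie_width_px: int = BEHAVIOR_MOVIE_WIDTH_PX) -> float:
    """Visual angle (degrees) of an object given in movie pixels.

    The stimulus movie (``movie_width_px`` wide) is assumed stretched to the
    full physical screen width, so one movie pixel spans
    ``width_cm / movie_width_px`` centimeters.  A 50-px figure on a 24-cm
    screen therefore spans 6 cm, i.e. 15 degrees at 23 cm viewing distance
    and 143 degrees at 1 cm.
    """
    if object_width_px < 0:
        raise ValueError("object width must be nonnegative")
    d = geometry.view_distance_cm if view_distance_cm is None else view_distance_cm
    width_cm = object_width_px * geometry.width_cm / movie_width_px
    return visual_angle_deg(width_cm, d)


def cycles_per_degree(cycles_per_cm: float, view_distance_cm: float) -> float:
    """Convert a physical grating frequency to cycles/degree at the fovea.

    Uses the small-angle rate at the screen center: one degree spans
    ``d tan(1 deg)`` centimeters.
    """
    if view_distance_cm <= 0:
        raise ValueError("view distance must be positive")
    cm_per_deg = view_distance_cm * math.tan(math.radians(1.0))
    return cycles_per_cm * cm_per_deg


@dataclass(frozen=True)
class CanvasGeometry:
    """Rendering raster in retinotopic coordinates.

    Azimuth increases rightward, elevation upward; the canvas is centered on
    (0, 0) degrees.  ``px_per_deg`` fixes the linear degree-to-pixel mapping
    used for head-fixed stimulus synthesis and model filtering.
    """

    width_deg: float = 80.0
    height_deg: float = 60.0
    px_per_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.width_deg <= 0 or self.height_deg <= 0 or self.px_per_deg <= 0:
            raise ValueError("canvas dimensions must be positive")

    @property
    def width_px(self) -> int:
        return int(round(self.width_deg * self.px_per_deg))

    @property
    def height_px(self) -> int:
        return int(round(self.height_deg * self.px_per_deg))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def deg_to_px(self, deg: float) -> float:
        return deg * self.px_per_deg

    def px_to_deg(self, px: float) -> float:
        return px / self.px_per_deg

    def azimuth_of_columns(self) -> np.ndarray:
        """Azimuth (deg) of each pixel-column center, left to right."""
        w = self.width_px
        return (np.arange(w) - (w - 1) / 2.0) / self.px_per_deg

    def elevation_of_rows(self) -> np.ndarray:
        """Elevation (deg) of each pixel-row center, top to bottom."""
        h = self.height_px
        return ((h - 1) / 2.0 - np.arange(h)) / self.px_per_deg

    def pixel_of(self, azimuth_deg: float, elevation_deg: float) -> tuple[float, float]:
        """(row, col) pixel coordinates of a point given in degrees."""
        col = (self.width_px - 1) / 2.0 + self.deg_to_px(azimuth_deg)
        row = (self.height_px - 1) / 2.0 - self.deg_to_px(elevation_deg)
        return row, col
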