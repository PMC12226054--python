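"""Screen geometry and pixel/visual-angle conversion.

The recording setup is a 22-inch 1920x1080 LCD viewed at 60 cm.  The
physical panel size is taken as 475 x 267 mm (a standard 22" 16:9 active
area); conversions use the small-angle linear approximation, accurate to
<1 % inside the central 20 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScreenGeometry", "AOI", "InvalidGeometryError", "aoi_for_side"]


class InvalidGeometryError(ValueError):
    """Raised when an AOI falls outside the screen."""


@dataclass(frozen=True)
class ScreenGeometry:
    width_px: int = 1920
    height_px: int = 1080
    width_mm: float = 475.0
    height_mm: float = 267.0
    viewing_distance_mm: float = 600.0

    @property
    def mm_per_px(self) -> float:
        return self.width_mm / self.width_px

    def px_to_deg(self, px: float) -> float:
        """Linear visual-angle subtense of a span of ``px`` pixels."""
        return math.degrees(px * self.mm_per_px / self.viewing_distance_mm)

    def deg_to_px(self, deg: float) -> float:
        return math.radians(deg) * self.viewing_distance_mm / self.mm_per_px

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass(frozen=True)
class AOI:
    """Rectangular area of interest, origin top-left, half-open bounds.

    A point (x, y) is inside iff ``left <= x < left + width`` and
    ``top <= y < top + height``.
    """

    label: str
    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidGeometryError("AOI width and height must be positive")

    def validate_on_screen(self, screen: ScreenGeometry) -> None:
        if (self.left < 0 or self.top < 0
                or self.left + self.width > screen.width_px
                or self.top + self.height > screen.height_px):
            raise InvalidGeometryError(
                f"AOI {self.label!r} [{self.left},{self.top},{self.width},"
                f"{self.height}] exceeds screen {screen.width_px}x{screen.height_px}"
            )

    def contains(self, x: float, y: float) -> bool:
        return (self.left <= x < self.left + self.width
                and self.top <= y < self.top + self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (self.left + self.width / 2.0, self.top + self.height / 2.0)


def aoi_for_side(side: str, stimulus_px: tuple[int, int] = (800, 600),
                 eccentricity_deg: float = 8.0,
                 screen: ScreenGeometry = ScreenGeometry()) -> AOI:
    """AOI rectangle for the picture shown at the given horizontal eccentricity.

    The image center sits ``eccentricity_deg`` left or right of screen
    center at the vertical midline; the AOI is exactly the image bounds.
    Images this large at 8 degrees overlap screen center, which is fine:
    membership is decided by fixation centroids, not the stimulus edge.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    cx, cy = screen.center
    off = screen.deg_to_px(eccentricity_deg)
    cx = cx - off if side == "left" else cx + off
    w, h = stimulus_px
    aoi = AOI(label=f"stimulus_{side}", left=cx - w / 2.0, top=cy - h / 2.0,
              width=float(w), height=float(h))
    aoi.validate_on_screen(screen)
    return aoi
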