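"""Axis-aligned pixel boxes shared by every stage of the pipeline.

Coordinates are 0-based, half-open: a box covers the pixel lattice
``[x_min, x_max) x [y_min, y_max)``.  Conversion to the centre-normalized
(YOLO) and ``(x, y, w, h)`` (COCO-style) dialects happens only at the I/O
boundary (:mod:`roiadj.roidata`).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Box:
    """Half-open axis-aligned box ``[x_min, x_max) x [y_min, y_max)``."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def clamp(self, width: float, height: float) -> "Box":
        """Clip to image bounds ``[0, width) x [0, height)``.

        Raises ``ValueError`` if the intersection with the image is empty.
        """
        x0 = max(0.0, self.x_min)
        y0 = max(0.0, self.y_min)
        x1 = min(float(width), self.x_max)
        y1 = min(float(height), self.y_max)
        if not (x0 < x1 and y0 < y1):
            raise ValueError("box does not intersect the image")
        return Box(x0, y0, x1, y1)

    def pad(self, frac: float) -> "Box":
        """Symmetric fractional context padding (``frac`` of each side length)."""
        dx = frac * self.width
        dy = frac * self.height
        return Box(self.x_min - dx, self.y_min - dy, self.x_max + dx, self.y_max + dy)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def intersection_area(a: Box, b: Box) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


@dataclass(frozen=True)
class Detection:
    """A candidate box with its detector confidence ``s`` in [0, 1]."""

    box: Box
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"detector confidence must be in [0, 1], got {self.score}")
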