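"""Circular region-of-interest geometry shared by the simulator and the counter."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class SpotRegion:
    """A circular microarray-spot region in frame pixel coordinates.

    Coordinates are 0-based, row-major: ``cx`` indexes columns, ``cy`` rows.
    """

    cx: float
    cy: float
    radius_px: float

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ConfigurationError("spot radius must be positive")

    @property
    def area_px(self) -> float:
        return float(np.pi * self.radius_px**2)

    def contains(self, x, y):
        """Vectorised point-in-circle test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius_px**2

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of the region for a frame of the given shape."""
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius_px**2

    def inside_frame(self, shape: tuple[int, int]) -> bool:
        return (
            self.cx - self.radius_px >= 0
            and self.cy - self.radius_px >= 0
            and self.cx + self.radius_px <= shape[1] - 1
            and self.cy + self.radius_px <= shape[0] - 1
        )
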