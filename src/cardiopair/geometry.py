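"""Physical geometry of micropatterned substrates and engineered tissues.

All lengths are in micrometres (μm) unless stated otherwise.  Image rasters
use ``(row, col)`` indexing; physical ``x`` runs along columns (the long
axis of patterns and the base→neck axis of tissues) and ``y`` along rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatternGeometry", "TissueGeometry", "PlateLayout"]


@dataclass(frozen=True)
class PatternGeometry:
    """Rectangular ECM island for an end-to-end cardiomyocyte cell pair.

    Defaults reproduce the 14:1 stamp used for human iPSC-CM pairs:
    211 μm × 15 μm, i.e. an island area of ~3,200 μm² sized for two cells
    of ~1,600 μm² each.
    """

    length: float = 211.0  # μm, long axis
    width: float = 15.0    # μm, short axis

    def __post_init__(self) -> None:
        if not (self.length > self.width > 0):
            raise ValueError(
                f"require length > width > 0, got {self.length} × {self.width}"
            )

    @property
    def area(self) -> float:
        """Island area in μm²."""
        return self.length * self.width

    @property
    def aspect_ratio(self) -> float:
        """Length-to-width ratio (14:1 for the default stamp)."""
        return self.length / self.width


@dataclass(frozen=True)
class TissueGeometry:
    """Base-plus-neck engineered tissue for calcium wave mapping.

    The tissue is a wide rectangular base continued by a narrower
    rectangular neck along +x.  Point stimulation is applied at the base
    edge opposite the neck; the wave becomes quasi-planar inside the neck,
    where velocity is measured.
    """

    base_width: float = 2000.0   # μm, y extent of the base
    base_length: float = 2000.0  # μm, x extent of the base
    neck_width: float = 800.0    # μm, y extent of the neck
    neck_length: float = 3000.0  # μm, x extent of the neck
    stimulation_site: tuple[float, float] = field(default=None)  # (x, y) μm

    def __post_init__(self) -> None:
        if not (self.neck_width < self.base_width):
            raise ValueError("neck_width must be < base_width")
        for name in ("base_width", "base_length", "neck_width", "neck_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.stimulation_site is None:
            # centre of the base edge opposite the neck
            object.__setattr__(
                self, "stimulation_site", (0.0, self.base_width / 2.0)
            )

    @property
    def total_length(self) -> float:
        return self.base_length + self.neck_length

    @property
    def total_width(self) -> float:
        return self.base_width

    def raster_shape(self, px_size: float) -> tuple[int, int]:
        """(rows, cols) of the bounding raster at ``px_size`` μm/px."""
        ny = int(round(self.total_width / px_size))
        nx = int(round(self.total_length / px_size))
        return ny, nx

    def mask(self, px_size: float) -> np.ndarray:
        """Boolean tissue mask on the bounding raster."""
        ny, nx = self.raster_shape(px_size)
        y = (np.arange(ny) + 0.5) * px_size
        x = (np.arange(nx) + 0.5) * px_size
        xx, yy = np.meshgrid(x, y)
        yc = self.base_width / 2.0
        in_base = (xx <= self.base_length) & (np.abs(yy - yc) <= self.base_width / 2)
        in_neck = (xx > self.base_length) & (np.abs(yy - yc) <= self.neck_width / 2)
        return in_base | in_neck

    def neck_roi_mask(self, px_size: float, central_fraction: float = 0.8) -> np.ndarray:
        """Mask of the central ``central_fraction`` of the neck length.

        Used as the velocity-measurement region; the margins at the neck
        entry and free end are excluded to avoid wavefront curvature and
        boundary effects.
        """
        ny, nx = self.raster_shape(px_size)
        y = (np.arange(ny) + 0.5) * px_size
        x = (np.arange(nx) + 0.5) * px_size
        xx, yy = np.meshgrid(x, y)
        yc = self.base_width / 2.0
        pad = (1.0 - central_fraction) / 2.0 * self.neck_length
        x0 = self.base_length + pad
        x1 = self.base_length + self.neck_length - pad
        return (
            (xx >= x0)
            & (xx <= x1)
            & (np.abs(yy - yc) <= self.neck_width / 2)
        )

    def stimulation_px(self, px_size: float) -> tuple[int, int]:
        """Stimulation site as a (row, col) index, clipped into the raster."""
        ny, nx = self.raster_shape(px_size)
        x, y = self.stimulation_site
        col = int(np.clip(round(x / px_size), 0, nx - 1))
        row = int(np.clip(round(y / px_size), 0, ny - 1))
        return row, col


@dataclass(frozen=True)
class PlateLayout:
    """Regular grid of pattern islands on a plate.

    ``origin`` is the physical (x, y) μm position of the centre of island
    (row 0, col 0); islands are spaced ``pitch_x`` along x and ``pitch_y``
    along y.  ``angle_deg`` rotates the whole grid about the plate centre;
    ``None`` means unknown (to be fitted from the image).
    """

    n_rows: int
    n_cols: int
    pitch_x: float
    pitch_y: float
    origin: tuple[float, float]
    angle_deg: float | None = 0.0

    @property
    def n_islands(self) -> int:
        return self.n_rows * self.n_cols

    def centers(self) -> np.ndarray:
        """(n_islands, 2) array of unrotated island centres (x, y) in μm."""
        ox, oy = self.origin
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        xs = ox + cols.ravel() * self.pitch_x
        ys = oy + rows.ravel() * self.pitch_y
        return np.column_stack([xs, ys])
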