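"""Calibrated z-stack and ROI containers.

A :class:`ZStack` is the pipeline's raw input: a ``(sections, rows, cols)``
intensity grid plus the physical calibration of the acquisition (lateral
pixel size and axial step, both in micrometres). All downstream descriptor
values (areas, volumes, lengths, diameters) are reported in micrometre
units derived from this calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ZStack", "ROI"]


@dataclass
class ZStack:
    """A calibrated fluorescence z-stack.

    Parameters
    ----------
    data : ndarray, shape (sections, rows, cols)
        Intensity grid. Integer grays for raw data; floating point is
        accepted for processed intermediates (e.g. deconvolution output).
    pixel_size_xy : float
        Lateral pixel size in µm (x and y are assumed equal).
    z_step : float
        Axial section spacing in µm.
    bit_depth : int
        Nominal bit depth of the acquisition (8 or 16 for raw data).
    """

    data: np.ndarray
    pixel_size_xy: float = 1.0
    z_step: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3D (sections, rows, cols); got shape {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one section")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("calibration values must be positive")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        if np.issubdtype(self.data.dtype, np.integer):
            vmax = 2**self.bit_depth - 1
            if self.data.size and self.data.max() > vmax:
                raise ValueError(
                    f"intensities exceed {self.bit_depth}-bit range (max {vmax})"
                )

    # -- geometry -----------------------------------------------------
    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing ``(z, y, x)`` in µm."""
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.z_step * self.pixel_size_xy**2

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size_xy**2

    def with_data(self, data: np.ndarray) -> "ZStack":
        """Return a copy carrying ``data`` with the same calibration."""
        return replace(self, data=data)


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based half-open pixel coordinates.

    ``x`` indexes columns, ``y`` rows. ``z0``/``z1`` optionally restrict the
    section range (also half-open); ``None`` keeps all sections.
    """

    x0: int
    y0: int
    x1: int
    y1: int
    z0: int | None = None
    z1: int | None = None

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"ROI must have positive extent: {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI coordinates must be non-negative: {self}")
        if (self.z0 is None) != (self.z1 is None):
            raise ValueError("z0 and z1 must be given together")
        if self.z0 is not None and not (0 <= self.z0 < self.z1):
            raise ValueError(f"ROI section range invalid: {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def intersect(self, other: "ROI") -> "ROI":
        """Intersection of two ROIs (in-plane coordinates only)."""
        return ROI(
            max(self.x0, other.x0),
            max(self.y0, other.y0),
            min(self.x1, other.x1),
            min(self.y1, other.y1),
        )
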