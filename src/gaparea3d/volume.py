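"""CT volume container.

Conventions used throughout the package:

* voxel array axes are (x, y, z) with z the proximal–distal axis and
  "proximal" toward increasing z (the articular surface of a proximal
  tibia faces +z);
* voxel centres sit at ``origin + index * spacing`` in scanner/world
  millimetres (axis-aligned grid, 0-based indices);
* voxel values are Hounsfield Units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """A CT scan on a regular axis-aligned grid of Hounsfield Units.

    Parameters
    ----------
    voxels :
        3D array of HU values, axes (x, y, z), z proximal.
    spacing :
        Per-axis voxel size in mm, strictly positive.
    origin :
        World position (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError("all three axes must have length >= 2")
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ValueError("spacing must be three strictly positive values")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm coordinates."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing
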