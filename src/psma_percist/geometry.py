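"""Voxel geometry conventions shared by the phantom generator and the quantifier.

Conventions (fixed package-wide):

* arrays are indexed ``(z, y, x)``, 0-based;
* the physical coordinate of voxel ``i`` along an axis with spacing ``s`` is
  ``(i + 0.5) * s`` millimetres (voxel-center convention);
* a voxel belongs to an analytic shape iff its *center* lies inside the shape
  (boundary inclusive);
* lengths are millimetres, volumes millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def voxel_centers(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    """Per-axis 1-D arrays of voxel-center coordinates in mm (open grids)."""
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.ix_(*axes)


def ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside an axis-aligned ellipsoid."""
    zc, yc, xc = voxel_centers(shape, spacing)
    rz, ry, rx = radii
    d2 = (
        ((zc - center[0]) / rz) ** 2
        + ((yc - center[1]) / ry) ** 2
        + ((xc - center[2]) / rx) ** 2
    )
    return d2 <= 1.0


@dataclass(frozen=True)
class CylinderVoi:
    """A cylindrical volume of interest (the blood-pool reference region).

    ``center`` is the cylinder midpoint in mm (z, y, x); ``axis`` the direction
    of the cylinder's long axis; ``length`` defaults to the 3 cm used for the
    aortic reference VOI and ``diameter`` to 10 mm (a typical aortic lumen).
    """

    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    diameter: float = 10.0
    length: float = 30.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("cylinder diameter and length must be positive")
        if not np.any(np.asarray(self.axis, dtype=float)):
            raise ValueError("cylinder axis must be a non-zero vector")

    def mask(
        self, shape: tuple[int, int, int], spacing: tuple[float, float, float]
    ) -> np.ndarray:
        """Boolean mask of voxels whose centers lie inside the cylinder."""
        u = np.asarray(self.axis, dtype=float)
        u = u / np.linalg.norm(u)
        zc, yc, xc = voxel_centers(shape, spacing)
        dz = zc - self.center[0]
        dy = yc - self.center[1]
        dx = xc - self.center[2]
        axial = dz * u[0] + dy * u[1] + dx * u[2]
        d2 = dz**2 + dy**2 + dx**2
        radial2 = d2 - axial**2
        return (np.abs(axial) <= self.length / 2.0) & (
            radial2 <= (self.diameter / 2.0) ** 2 + 1e-12
        )
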