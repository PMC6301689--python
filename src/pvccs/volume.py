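"""In-memory container for CT intensity volumes.

A :class:`CTVolume` is a 3D grid of Hounsfield-unit intensities indexed
``[x, y, z]`` with anisotropic voxel spacing. The z axis is the slice
(scanning) direction; its spacing is the slice increment and is typically
much larger than the in-plane spacing in calcium-scoring protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CTVolume:
    """3D HU intensity grid with voxel spacing.

    Parameters
    ----------
    intensities
        3D array of Hounsfield units, indexed ``[x, y, z]``.
    spacing_mm
        Voxel spacing ``(dx, dy, dz)`` in mm; all strictly positive. ``dz``
        may exceed ``dx``/``dy`` (anisotropic reconstruction grids).
    origin_mm
        World coordinate of the corner of voxel ``(0, 0, 0)``.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(f"intensities must be 3D, got {self.intensities.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel, dx*dy*dz."""
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz
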