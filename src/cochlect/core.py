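"""Shared in-memory containers for grey-value and label volumes.

All volumes are dense numpy arrays indexed ``[z, y, x]`` with isotropic
voxels.  World coordinates are voxel centers; lengths are reported in mm,
volumes in mm³, voxel sizes in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Volume3D", "LabelVolume", "UM_PER_MM"]

UM_PER_MM = 1000.0


@dataclass
class Volume3D:
    """A scalar 3D image (attenuation in 1/mm, or grey values).

    Parameters
    ----------
    data
        3D array, ``[z, y, x]``.
    voxel_size_um
        Isotropic voxel edge length in µm.
    meta
        Free-form metadata (bit depth of origin, provenance, flags).
    """

    data: np.ndarray
    voxel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / UM_PER_MM

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy(), meta=dict(self.meta))


@dataclass
class LabelVolume:
    """Integer-labelled 3D volume assigning voxels to named structures.

    ``names`` maps structure name -> integer label.  Label 0 is background
    and need not appear in the map.
    """

    data: np.ndarray
    voxel_size_um: float
    names: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume requires an integer array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / UM_PER_MM

    def label_of(self, structure: str) -> int:
        try:
            return self.names[structure]
        except KeyError:
            raise KeyError(
                f"unknown structure {structure!r}; known: {sorted(self.names)}"
            ) from None

    def mask(self, structure: str) -> np.ndarray:
        """Boolean mask of one named structure (error if absent or empty)."""
        m = self.data == self.label_of(structure)
        if not m.any():
            raise ValueError(f"structure {structure!r} has no voxels")
        return m

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.voxel_size_um, dict(self.names))


def voxel_coords_mm(shape: tuple[int, int, int], voxel_size_um: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (mm) of voxel centers along each axis (z, y, x)."""
    vs = voxel_size_um / UM_PER_MM
    return tuple((np.arange(n) + 0.5) * vs for n in shape)
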