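"""Core in-memory containers for 3D image volumes and binary masks.

Axis convention used throughout the package: arrays are indexed ``(x, y, z)``
with axis 2 (``z``) the loading / supero-inferior axis. Indexing is 0-based
and voxel centers sit at integer coordinates. Voxel size is isotropic and
carried in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageVolume", "BinaryMask"]


@dataclass
class ImageVolume:
    """A 3D scalar image with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array, ``(nx, ny, nz)``. Either 8-bit grey (``uint8``) or float.
    voxel_size:
        Isotropic voxel edge length in micrometres; must be positive.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 µm, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_8bit(self) -> bool:
        return self.data.dtype == np.uint8

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.voxel_size)


@dataclass
class BinaryMask:
    """A 3D boolean grid aligned with its source :class:`ImageVolume`."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 µm, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.voxel_size)
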