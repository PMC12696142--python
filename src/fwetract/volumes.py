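"""Voxel-grid containers: scalar metric maps and integer label volumes.

All geometry is in world RAS millimetres; voxel indices are 0-based and the
affine maps voxel indices to world coordinates (NIfTI convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# BraTS-style compartment encoding (configurable at call sites).
DEFAULT_LABEL_MAP = {"necrotic": 1, "edema": 2, "enhancing": 4}
COMPARTMENTS = ("enhancing", "necrotic", "edema")


@dataclass
class Volume:
    """A 3D array with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to continuous 0-based voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


class MetricVolume(Volume):
    """Scalar map (FA, MD, FWF, ...) sampled by trilinear interpolation."""


class LabelVolume(Volume):
    """Integer segmentation volume; labels are never interpolated."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.asarray(self.data)
            if not np.all(as_int == np.round(as_int)):
                raise ValueError("label volume contains non-integer values")
            self.data = as_int.astype(np.int16)

    def compartment_mask(self, compartment: str,
                         label_map: dict[str, int] = DEFAULT_LABEL_MAP) -> np.ndarray:
        if compartment == "combined":
            labels = [label_map[c] for c in COMPARTMENTS]
            return np.isin(self.data, labels)
        return self.data == label_map[compartment]


def default_affine(shape: tuple[int, int, int], voxel_size: float = 2.0) -> np.ndarray:
    """RAS affine with isotropic voxels, grid centred on the world origin.

    Centring makes x = 0 the midsagittal plane, so left/right hemispheres are
    mirror images of each other at the voxel level (voxel centres fall at
    symmetric world coordinates).
    """
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return aff
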