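"""Gray-matter density volumes on a voxel lattice with a world-space affine."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "load_volume", "save_volume"]


@dataclass
class VolumeGrid:
    """A 3D scalar lattice (GM density in [0, 1]) plus a voxel-to-world affine.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field sampled at voxel centers.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> world-mm map. Must be invertible.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D lattice, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to world mm coordinates (n, 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid sharing this volume's affine."""
        return VolumeGrid(values=np.asarray(values, dtype=np.float64), affine=self.affine.copy())


def check_same_grid(volumes: list[VolumeGrid], names: list[str] | None = None) -> None:
    """Raise if any volume differs in shape or affine from the first."""
    if not volumes:
        raise ValueError("need at least one volume")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        label = names[i] if names else f"volume {i}"
        if v.shape != ref.shape:
            raise ValueError(f"{label}: shape {v.shape} != reference {ref.shape}")
        if not np.allclose(v.affine, ref.affine, atol=1e-8):
            raise ValueError(f"{label}: affine differs from reference")


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(values=np.asarray(img.get_fdata(), dtype=np.float64), affine=img.affine)


def save_volume(vol: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), vol.affine)
    nib.save(img, str(path))
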