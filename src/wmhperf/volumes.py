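"""Label and perfusion volumes with physical voxel dimensions.

All geometry in this package is done in physical millimetres on (possibly
anisotropic) voxel grids; nothing is ever resampled.  ``LabelVolume`` is the
small container the rest of the package passes around: a 3D array plus the
voxel size, with NIfTI round-trip via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

VoxelSize = tuple[float, float, float]


@dataclass
class LabelVolume:
    """A 3D volume (mask, label map or scalar map) with voxel dimensions.

    Parameters
    ----------
    data
        3D array.  Boolean for masks, integer for label maps, float for
        perfusion maps.
    voxel_size_mm
        Physical voxel edge lengths (dx, dy, dz) in mm; all strictly positive.
    """

    data: np.ndarray
    voxel_size_mm: VoxelSize = (1.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be three positive lengths, got {self.voxel_size_mm}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def astype_mask(self) -> np.ndarray:
        return self.data.astype(bool)

    def count(self) -> int:
        """Number of nonzero voxels."""
        return int(np.count_nonzero(self.data))

    def volume_mm3(self) -> float:
        """Physical volume of the nonzero voxels."""
        return self.count() * self.voxel_volume_mm3

    def same_grid(self, other: "LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size_mm, other.voxel_size_mm)

    def require_same_grid(self, other: "LabelVolume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} are not on the same grid: "
                f"{self.shape}@{self.voxel_size_mm} vs {other.shape}@{other.voxel_size_mm}"
            )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(self.voxel_size_mm)
        return img

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path, as_bool: bool = False) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if as_bool:
            data = data > 0
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, voxel_size_mm=zooms)  # type: ignore[arg-type]
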