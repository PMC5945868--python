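"""NIfTI I/O and the volumetric containers shared by every stage.

Conventions fixed here and relied on everywhere else:

* voxel indexing is 0-based and grid-aligned; world (mm) coordinates exist
  only through the affine and are never used in distance computations,
* in-mask voxels are enumerated in a fixed lexicographic order with the x
  index varying fastest, so every voxel has a stable linear index and every
  matrix-indexed structure is reproducible,
* atlas labels are dense: 0 outside the mask, 1..K_actual inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BoldVolume",
    "BrainMask",
    "Atlas",
    "read_volume",
    "read_mask",
    "read_atlas",
    "write_volume",
    "write_mask",
    "write_atlas",
    "mask_coords",
    "mask_series",
    "labels_to_atlas",
]


@dataclass
class BoldVolume:
    """A 4D BOLD series: ``data[x, y, z, t]`` with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"BoldVolume requires a 4D array, found rank {self.data.ndim}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("T >= 2 required for a BOLD time series")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def T(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """A binary mask congruent with the BOLD grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise ValueError(
                f"BrainMask requires a 3D array, found rank {self.data.ndim}"
            )
        if not self.data.any():
            raise ValueError("empty mask: N0 = 0")

    @property
    def n_voxels(self) -> int:
        """N0, the number of in-mask voxels."""
        return int(self.data.sum())


@dataclass
class Atlas:
    """A voxel-level parcellation: integer labels, 0 outside the mask."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(np.rint(self.labels), dtype=np.int32)
        if self.labels.ndim != 3:
            raise ValueError(
                f"Atlas requires a 3D label array, found rank {self.labels.ndim}"
            )
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be nonnegative")

    @property
    def n_clusters(self) -> int:
        """K_actual, the number of distinct nonzero labels."""
        return int(np.unique(self.labels[self.labels > 0]).size)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def is_dense(self) -> bool:
        present = np.unique(self.labels[self.labels > 0])
        return bool(present.size == 0 or np.array_equal(present, np.arange(1, present.size + 1)))

    def densified(self) -> "Atlas":
        """Relabel to a contiguous 1..K_actual range (order-preserving)."""
        present = np.unique(self.labels[self.labels > 0])
        lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int32)
        lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
        return Atlas(labels=lut[self.labels], affine=self.affine)


def mask_coords(mask: BrainMask) -> np.ndarray:
    """Voxel-index coordinates of in-mask voxels, shape (N0, 3).

    Order is the package-wide lexicographic enumeration with x fastest.
    """
    zz, yy, xx = np.nonzero(mask.data.transpose(2, 1, 0))
    return np.column_stack([xx, yy, zz]).astype(np.int64)


def mask_series(volume: BoldVolume, mask: BrainMask) -> np.ndarray:
    """In-mask voxel time courses, shape (N0, T), in the canonical order."""
    coords = mask_coords(mask)
    return volume.data[coords[:, 0], coords[:, 1], coords[:, 2], :]


def labels_to_atlas(labels_flat: np.ndarray, mask: BrainMask, affine=None) -> Atlas:
    """Lift a length-N0 label vector (canonical order) back onto the grid."""
    labels_flat = np.asarray(labels_flat)
    if labels_flat.shape[0] != mask.n_voxels:
        raise ValueError("label vector length does not match mask voxel count")
    out = np.zeros(mask.data.shape, dtype=np.int32)
    coords = mask_coords(mask)
    out[coords[:, 0], coords[:, 1], coords[:, 2]] = labels_flat
    return Atlas(labels=out, affine=np.eye(4) if affine is None else affine).densified()


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad payloads
        raise ValueError(f"not a readable NIfTI image: {path}") from exc
    return img


def read_volume(path) -> BoldVolume:
    """Read a 4D NIfTI BOLD series."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        raise ValueError("T >= 2 required: found a 4D image with a single volume")
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, found rank {data.ndim}: {path}")
    return BoldVolume(data=np.asarray(data, dtype=float), affine=img.affine)


def read_mask(path, volume: BoldVolume) -> BrainMask:
    """Read a 3D mask and check congruence with the paired volume grid."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask image, found rank {data.ndim}: {path}")
    if data.shape != volume.shape3d:
        raise ValueError(
            f"mask shape {data.shape} does not match volume grid {volume.shape3d}"
        )
    return BrainMask(data=data)


def read_atlas(path) -> Atlas:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D atlas image, found rank {data.ndim}: {path}")
    return Atlas(labels=data, affine=img.affine)


def write_volume(volume: BoldVolume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine), str(path))


def write_mask(mask: BrainMask, path, affine=None) -> None:
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), aff), str(path))


def write_atlas(atlas: Atlas, path) -> None:
    """Write an integer atlas; label values are densified to 1..K_actual."""
    if not atlas.is_dense():
        warnings.warn("atlas labels are not contiguous; densifying to 1..K before write")
        atlas = atlas.densified()
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.affine), str(path))
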