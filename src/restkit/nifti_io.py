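"""Volume containers and NIfTI-1 / ANALYZE 7.5 input-output.

The toolkit operates on whole 4D BOLD datasets held in memory as plain
NumPy arrays plus a 4x4 voxel-to-mm affine and the repetition time (TR).
Reading and writing delegate to :mod:`nibabel`; this module adds the
thin domain types the rest of the package shares (``Volume4D``,
``Volume3D``, ``Mask``) and a block-iteration contract that bounds peak
memory when maps are computed slab by slab.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple, Union

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "Volume4D",
    "Mask",
    "BlockPlan",
    "Block",
    "read_volume",
    "write_volume",
    "align_mask",
    "iter_blocks",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable headers or contract violations on volumes."""


@dataclass
class Volume3D:
    """A single 3D map (statistic, mask source, metric) on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Voxel values, arbitrary units.
    affine : ndarray, shape (4, 4)
        Voxel-index (0-based) to mm transform; mm coordinates of voxel
        ``(i, j, k)`` are ``affine @ [i, j, k, 1]``.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"Volume3D needs 3D data, got shape {self.data.shape}")
        _check_affine(self.affine)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (n x 3) to mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.hstack([ijk, np.ones((ijk.shape[0], 1))])
        return (self.affine @ hom.T).T[:, :3]


@dataclass
class Volume4D:
    """A 4D BOLD dataset: spatial grid x time, with affine and TR.

    Invariants: ``T >= 2``, ``tr > 0`` (seconds), affine invertible.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise VolumeFormatError(f"Volume4D needs 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise VolumeFormatError("Volume4D needs at least 2 time points")
        if not (self.tr is not None and float(self.tr) > 0):
            raise VolumeFormatError("tr must be a positive number of seconds")
        self.tr = float(self.tr)
        _check_affine(self.affine)

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency 1/(2*TR) in Hz."""
        return 1.0 / (2.0 * self.tr)

    def spatial_volume3d(self, data: np.ndarray) -> Volume3D:
        """Wrap a 3D array on this volume's grid as a Volume3D."""
        data = np.asarray(data)
        if data.shape != self.spatial_shape:
            raise VolumeFormatError(
                f"3D data shape {data.shape} does not match grid {self.spatial_shape}"
            )
        return Volume3D(data=data, affine=self.affine.copy())


@dataclass
class Mask:
    """Boolean 3D mask aligned to a reference grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"Mask needs 3D data, got shape {self.data.shape}")
        _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def full(cls, reference: Union[Volume4D, Volume3D]) -> "Mask":
        shape = reference.spatial_shape if isinstance(reference, Volume4D) else reference.shape
        return cls(data=np.ones(shape, dtype=bool), affine=reference.affine.copy())


@dataclass
class BlockPlan:
    """Plan for cutting a 4D dataset into z-slabs of bounded size.

    ``max_voxels_per_block`` bounds the spatial voxel count per block so
    large datasets (long T, big grids) can be processed with bounded
    memory — trading time for space.  Blocks partition the grid exactly;
    ``overlap`` adds read-only halo slices for neighborhood operations
    (callers must write back only the core region).
    """

    max_voxels_per_block: int
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.max_voxels_per_block < 1:
            raise ValueError("max_voxels_per_block must be >= 1")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")


@dataclass
class Block:
    """One slab yielded by :func:`iter_blocks`.

    ``grid_slices`` index the full grid (including halo); ``core`` indexes
    the slab itself and selects the non-overlapping region whose
    concatenation over all blocks reconstructs the full grid.
    """

    data: np.ndarray
    grid_slices: Tuple[slice, slice, slice]
    core: Tuple[slice, slice, slice]
    core_grid_slices: Tuple[slice, slice, slice]


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise VolumeFormatError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise VolumeFormatError("affine contains non-finite values")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise VolumeFormatError("affine spatial part is singular")


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm (column norms of the spatial affine)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def voxel_volume_mm3(affine: np.ndarray) -> float:
    """Volume of one voxel in mm^3."""
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def read_volume(
    path: Union[str, os.PathLike],
    tr: Optional[float] = None,
) -> Union[Volume4D, Volume3D]:
    """Read a NIfTI-1 (.nii/.nii.gz/.hdr+.img) or ANALYZE 7.5 volume.

    4D files return :class:`Volume4D`; the TR is taken from the header's
    time step unless ``tr`` overrides it.  A header time step of zero
    requires an explicit ``tr``.  3D files return :class:`Volume3D`.
    """
    path = os.fspath(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several error types
        raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    if affine is None:  # ANALYZE without orientation: build RAS+ from zooms
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        affine = np.diag(list(np.where(zooms > 0, zooms, 1.0)) + [1.0])
    data = np.squeeze(data) if data.ndim > 4 else data
    if data.ndim == 3:
        return Volume3D(data=data, affine=affine)
    if data.ndim != 4:
        raise VolumeFormatError(f"{path!r}: expected 3D or 4D data, got shape {data.shape}")
    if tr is None:
        zooms = img.header.get_zooms()
        header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if header_tr <= 0:
            raise VolumeFormatError(
                f"{path!r}: header time step is {header_tr}; pass an explicit tr"
            )
        tr = header_tr
    return Volume4D(data=data, affine=affine, tr=float(tr))


def write_volume(
    vol: Union[Volume4D, Volume3D, Mask],
    path: Union[str, os.PathLike],
    format: str = "nii",
) -> list:
    """Write a volume as .nii or as .hdr/.img pair(s).

    ``format="pair"`` on a 4D input writes one 3D .hdr/.img pair per time
    point, suffixed ``_0000``, ``_0001``, ...  Returns the list of paths
    written (the .img paths for pairs).
    """
    path = os.fspath(path)
    if format not in ("nii", "pair"):
        raise ValueError(f"format must be 'nii' or 'pair', got {format!r}")
    if isinstance(vol, Mask):
        vol = Volume3D(data=vol.data.astype(np.uint8), affine=vol.affine)
    _check_affine(vol.affine)

    def _save(arr: np.ndarray, out: str, tr: Optional[float] = None) -> None:
        if out.endswith(".img") or out.endswith(".hdr"):
            img = nib.Nifti1Pair(arr, vol.affine)
        else:
            img = nib.Nifti1Image(arr, vol.affine)
        if tr is not None and arr.ndim == 4:
            zooms = list(img.header.get_zooms())
            zooms[3] = tr
            img.header.set_zooms(zooms)
        nib.save(img, out)

    if format == "nii":
        if not (path.endswith(".nii") or path.endswith(".nii.gz")):
            path = path + ".nii"
        tr = vol.tr if isinstance(vol, Volume4D) else None
        _save(vol.data, path, tr)
        return [path]

    # pair format
    base = path
    for ext in (".img", ".hdr", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    written = []
    if isinstance(vol, Volume4D):
        ndigits = max(4, len(str(vol.n_timepoints - 1)))
        for t in range(vol.n_timepoints):
            out = f"{base}_{t:0{ndigits}d}.img"
            _save(np.ascontiguousarray(vol.data[..., t]), out)
            written.append(out)
    else:
        out = base + ".img"
        _save(vol.data, out)
        written.append(out)
    return written


def align_mask(mask: Union[Volume3D, Mask], reference: Union[Volume4D, Volume3D],
               threshold: float = 0.0) -> Mask:
    """Binarize a 3D map and attach the reference affine.

    Voxels with value strictly greater than ``threshold`` (default:
    nonzero) become True.  The mask grid must already match the reference
    spatial grid — resampling is out of scope and a mismatch is an error,
    never a silent crop.
    """
    ref_shape = (reference.spatial_shape if isinstance(reference, Volume4D)
                 else reference.shape)
    if mask.data.shape != ref_shape:
        raise VolumeFormatError(
            f"mask shape {mask.data.shape} does not match reference grid {ref_shape}"
        )
    data = np.abs(np.asarray(mask.data, dtype=float)) > threshold
    return Mask(data=data, affine=reference.affine.copy())


def iter_blocks(vol: Volume4D, plan: BlockPlan) -> Iterator[Block]:
    """Iterate a 4D volume as z-slabs bounded by ``plan.max_voxels_per_block``.

    Slabs are contiguous in the last spatial axis.  Cores partition the
    grid exactly once; with ``plan.overlap = r`` each slab carries up to
    ``r`` halo slices on each side so neighborhood operations of radius
    ``r`` computed per block and stitched from the cores are bit-identical
    to the whole-volume result.
    """
    nx, ny, nz = vol.spatial_shape
    per_slice = nx * ny
    if plan.max_voxels_per_block < per_slice:
        raise ValueError(
            f"max_voxels_per_block={plan.max_voxels_per_block} smaller than one "
            f"z-slice ({per_slice} voxels); cannot form slabs"
        )
    slices_per_block = max(1, plan.max_voxels_per_block // per_slice)
    r = plan.overlap
    z0 = 0
    while z0 < nz:
        z1 = min(nz, z0 + slices_per_block)
        lo = max(0, z0 - r)
        hi = min(nz, z1 + r)
        grid = (slice(0, nx), slice(0, ny), slice(lo, hi))
        core = (slice(0, nx), slice(0, ny), slice(z0 - lo, z0 - lo + (z1 - z0)))
        yield Block(
            data=vol.data[:, :, lo:hi, :],
            grid_slices=grid,
            core=core,
            core_grid_slices=(slice(0, nx), slice(0, ny), slice(z0, z1)),
        )
        z0 = z1
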