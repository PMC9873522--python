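"""Volumetric containers and NIfTI I/O.

Every object in the package lives on a :class:`Grid` — a 3-D voxel lattice
with a 4x4 affine mapping 0-based voxel indices to millimetre coordinates.
Scalar maps carry an explicit missing-value mask (written to disk as NaN) so
that downstream statistics can distinguish "zero" from "excluded".  Grids are
never implicitly resampled: any cross-object grid mismatch raises.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "ScalarMap",
    "MaskMap",
    "BoldSeries",
    "read_volume",
    "read_mask",
    "write_volume",
    "voxel_to_mm",
    "mm_to_voxel",
]


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Voxel lattice geometry: shape, and the affine to mm space."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(affine[3], [0, 0, 0, 1]):
            raise ValueError("affine last row must be (0, 0, 0, 1)")
        if np.any(np.linalg.norm(affine[:3, :3], axis=0) <= 0):
            raise ValueError("affine columns must have positive norm (voxel size > 0)")
        object.__setattr__(self, "shape", shape)
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @classmethod
    def isotropic(cls, shape, voxel_mm: float = 3.0, origin=None) -> "Grid":
        """Axis-aligned isotropic grid. ``origin`` defaults to centring mm=0."""
        shape = tuple(int(s) for s in shape)
        if origin is None:
            origin = [-voxel_mm * (s - 1) / 2.0 for s in shape]
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = origin
        return cls(shape, affine)

    def matches(self, other: "Grid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def check_matches(self, other: "Grid", what: str = "object") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch with {what}: shape {self.shape} vs {other.shape}, "
                "or affines differ"
            )


def voxel_to_mm(grid: Grid, ijk) -> np.ndarray:
    """Map 0-based voxel indices to mm coordinates through the affine."""
    ijk = np.asarray(ijk, dtype=float)
    idx = np.atleast_2d(ijk)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        raise IndexError(f"voxel index {ijk} outside grid shape {grid.shape}")
    hom = np.concatenate([idx, np.ones((idx.shape[0], 1))], axis=1)
    out = (grid.affine @ hom.T).T[:, :3]
    return out[0] if ijk.ndim == 1 else out


def mm_to_voxel(grid: Grid, xyz) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm` (continuous voxel coordinates)."""
    xyz = np.asarray(xyz, dtype=float)
    pt = np.atleast_2d(xyz)
    hom = np.concatenate([pt, np.ones((pt.shape[0], 1))], axis=1)
    out = (np.linalg.inv(grid.affine) @ hom.T).T[:, :3]
    return out[0] if xyz.ndim == 1 else out


@dataclass
class ScalarMap:
    """A 3-D map of real values with an explicit missing mask.

    ``values`` holds NaN at missing voxels; ``missing`` is the authoritative
    boolean mask.  Values must be finite wherever not missing.
    """

    grid: Grid
    values: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.grid.shape:
                raise ValueError("missing mask shape mismatch")
            if not np.all(np.isfinite(self.values[~self.missing])):
                raise ValueError("non-missing voxels must hold finite values")
        self.values = self.values.copy()
        self.values[self.missing] = np.nan

    @property
    def present(self) -> np.ndarray:
        return ~self.missing

    def with_values(self, values, missing=None) -> "ScalarMap":
        return ScalarMap(self.grid, values, missing)


@dataclass
class MaskMap:
    """Boolean voxel set on a grid (gray matter, whole brain, ...)."""

    grid: Grid
    inside: np.ndarray

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.inside.any():
            raise ValueError("mask has no voxels inside")

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())


@dataclass
class BoldSeries:
    """4-D BOLD data: space x time, with repetition time in seconds."""

    grid: Grid
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[:3] != self.grid.shape:
            raise ValueError(
                f"values must be 4-D on grid {self.grid.shape}, got {self.values.shape}"
            )
        if self.values.shape[3] < 2:
            raise ValueError("a BOLD series needs at least 2 timepoints")
        self.tr_seconds = float(self.tr_seconds)
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[3])

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def _resolve_tr(img, tr_override):
    if tr_override is not None:
        tr = float(tr_override)
    else:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        _, t_unit = img.header.get_xyzt_units()
        if t_unit == "msec":
            tr /= 1000.0
        elif t_unit == "usec":
            tr /= 1e6
    if not np.isfinite(tr) or tr <= 0:
        raise ValueError(
            "4-D image carries no usable repetition time; pass tr_override"
        )
    return tr


def read_volume(path, tr_override: float = None):
    """Read a NIfTI file as :class:`ScalarMap` (3-D) or :class:`BoldSeries` (4-D).

    NaN voxels in a 3-D image become missing.  For 4-D images the repetition
    time comes from the header time-axis spacing unless ``tr_override`` is
    given.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = Grid(data.shape[:3], img.affine)
    if data.ndim == 3:
        return ScalarMap(grid, data)
    if data.ndim == 4:
        return BoldSeries(grid, data, _resolve_tr(img, tr_override))
    raise ValueError(f"expected a 3-D or 4-D image, got {data.ndim}-D: {path}")


def read_series(path, tr_override: float = None) -> BoldSeries:
    """Read a 4-D image; raises if the file is not 4-D."""
    out = read_volume(path, tr_override=tr_override)
    if not isinstance(out, BoldSeries):
        raise ValueError(f"{path} is not a 4-D series")
    return out


def read_mask(path, threshold: float = 0.5) -> MaskMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError("masks must be 3-D")
    return MaskMap(Grid(data.shape, img.affine), data > threshold)


def write_volume(obj, path) -> None:
    """Write a map, mask, or series to NIfTI; missing voxels become NaN."""
    if isinstance(obj, ScalarMap):
        data = obj.values  # NaN already encodes missing
        img = nib.Nifti1Image(data.astype(np.float64), obj.grid.affine)
    elif isinstance(obj, MaskMap):
        img = nib.Nifti1Image(obj.inside.astype(np.uint8), obj.grid.affine)
    elif isinstance(obj, BoldSeries):
        img = nib.Nifti1Image(obj.values.astype(np.float64), obj.grid.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = obj.tr_seconds
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    nib.save(img, str(path))
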