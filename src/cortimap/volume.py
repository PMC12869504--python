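"""Voxel volumes and TIFF stack I/O.

The whole pipeline passes a single carrier type, :class:`VoxelVolume`: a 3D
scalar grid in ``(z, y, x)`` axis order with an isotropic voxel size in µm.
``x`` is the column index increasing rightward and ``y`` the row index
increasing downward, so pixel-coordinate conventions (e.g. "upper-left
quadrant = 0..side/2 in x and y") map directly onto array slices.

Voxel size is caller-supplied metadata, never parsed from TIFF tags —
synchrotron reconstructions are inconsistently tagged, and an explicit value
beats a fragile guess. A mismatch is therefore only detectable (and raised)
when two volumes are combined in one pipeline run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "read_stack", "write_stack"]

#: Recognised value kinds for a :class:`VoxelVolume`.
KINDS = ("greyscale", "mask", "labels", "distance")


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic voxel size.

    Parameters
    ----------
    values
        3D array, axis order ``(z, y, x)``.
    voxel_size_um
        Isotropic voxel edge length in µm; must be > 0.
    kind
        One of ``greyscale`` (raw intensities), ``mask`` (binary {0, 1}),
        ``labels`` (non-negative integers, 0 = background) or ``distance``
        (µm, ≥ 0, exactly 0 on out-of-domain voxels).
    """

    values: np.ndarray
    voxel_size_um: float
    kind: str = "greyscale"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.values.ndim}")
        if not (self.voxel_size_um > 0):
            raise ValueError(f"voxel size must be > 0 µm, got {self.voxel_size_um}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown value kind {self.kind!r}; expected one of {KINDS}")
        if self.kind == "mask":
            bad = np.setdiff1d(np.unique(self.values), [0, 1])
            if bad.size:
                raise ValueError(f"binary mask contains values other than 0/1: {bad[:10]}")
        elif self.kind == "labels":
            if not np.issubdtype(self.values.dtype, np.integer):
                raise ValueError("label maps must have an integer dtype")
            if self.values.size and self.values.min() < 0:
                raise ValueError("label maps must be non-negative (0 = background)")
        elif self.kind == "distance":
            if self.values.size and self.values.min() < 0:
                raise ValueError("distance maps must be non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in µm³."""
        return float(self.voxel_size_um) ** 3

    def astype_kind(self, kind: str) -> "VoxelVolume":
        """Re-wrap the same values under a different kind (re-validated)."""
        return VoxelVolume(self.values, self.voxel_size_um, kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "VoxelVolume":
        return VoxelVolume(values, self.voxel_size_um, kind or self.kind)

    def check_compatible(self, other: "VoxelVolume", *, same_shape: bool = True) -> None:
        """Raise if two volumes cannot be combined in one pipeline run."""
        if not np.isclose(self.voxel_size_um, other.voxel_size_um, rtol=0, atol=1e-9):
            raise ValueError(
                "voxel size mismatch: cannot combine volumes at "
                f"{self.voxel_size_um} µm and {other.voxel_size_um} µm"
            )
        if same_shape and self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")

    def foreground_count(self) -> int:
        """Number of non-zero voxels."""
        return int(np.count_nonzero(self.values))


def _tiff_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff")
    )
    return files


def read_stack(path: str | os.PathLike, voxel_size_um: float, kind: str = "greyscale") -> VoxelVolume:
    """Read a multipage TIFF, or a directory of per-slice TIFFs, as a volume.

    Directory slices are taken in lexicographic filename order and must all
    share one shape; a ragged stack raises with the offending file named.
    Values are preserved bit-exactly.
    """
    path = Path(path)
    if path.is_dir():
        files = _tiff_files(path)
        if not files:
            raise ValueError(f"no TIFF slices found in directory {path}")
        slices = []
        first_shape = None
        for f in files:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise ValueError(f"slice file {f} is not a single 2D image (ndim={arr.ndim})")
            if first_shape is None:
                first_shape = arr.shape
            elif arr.shape != first_shape:
                raise ValueError(
                    f"ragged stack: slice {f} has shape {arr.shape}, expected {first_shape}"
                )
            slices.append(arr)
        values = np.stack(slices, axis=0)
    else:
        values = tifffile.imread(path)
        if values.ndim == 2:  # single-slice TIFF -> (1, H, W)
            values = values[None, ...]
        if values.ndim != 3:
            raise ValueError(f"{path}: expected a 2D or 3D TIFF, got ndim={values.ndim}")
        if values.shape[0] == 0:
            raise ValueError(f"{path}: stack contains zero slices")
    return VoxelVolume(values, voxel_size_um, kind)


def write_stack(volume: VoxelVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multipage TIFF (bit-exact round trip with read_stack)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.ascontiguousarray(volume.values), photometric="minisblack"
    )
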