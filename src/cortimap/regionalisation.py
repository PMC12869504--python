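"""Principal-axis alignment, the −45° convention, and quadrant partitioning.

The cross-section is aligned as one rigid body: the in-plane principal axis
of the z-projected cortical mask is rotated onto the +x axis, the stack is
then rotated a further −45° and padded to an even square canvas, and the
canvas is split into four equal pixel-coordinate quadrants:

    upper-left  (x < side/2, y < side/2)  → posterior
    upper-right (x ≥ side/2, y < side/2)  → lateral
    lower-left  (x < side/2, y ≥ side/2)  → medial
    lower-right (x ≥ side/2, y ≥ side/2)  → anterior

Angles follow the image convention (x right, y down); a content rotation by
θ maps the direction (1, 0) to (cos θ, sin θ) in that frame, so −45° turns
a bar along x into a bar along the 135° diagonal.  All raster rotations are
nearest-neighbour so masks stay binary and label maps stay integral.

The 180° ambiguity of a principal axis is resolved, where the projection is
bilobed, by requiring the smaller lobe (the fibula) to sit in the upper
half after the −45° rotation; a ``flip`` override is exposed for atypical
anatomies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume import VoxelVolume

__all__ = [
    "REGION_NAMES",
    "RegionPartition",
    "principal_axis_angle",
    "principal_axis_align",
    "rotate_inplane",
    "rotate_minus45_and_pad",
    "assign_quadrants",
    "mask_to_region",
    "flip_needed",
    "region_of_point",
]

#: Region code (1-based; 0 is unused) per quadrant, in a fixed order.
REGION_NAMES = ("posterior", "lateral", "medial", "anterior")
_REGION_CODE = {name: i + 1 for i, name in enumerate(REGION_NAMES)}


@dataclass
class RegionPartition:
    """Per-pixel quadrant labels on a square (y, x) canvas."""

    side: int
    labels: np.ndarray  # (side, side) uint8, codes 1..4
    rotation_deg: float = 0.0  # total in-plane rotation that produced the canvas

    def code(self, region: str) -> int:
        try:
            return _REGION_CODE[region]
        except KeyError:
            raise ValueError(
                f"unknown region {region!r}; expected one of {REGION_NAMES}"
            ) from None

    def mask(self, region: str) -> np.ndarray:
        """Boolean (y, x) mask of one quadrant."""
        return self.labels == self.code(region)


def region_of_point(x: float, y: float, side: float) -> str:
    """Quadrant of a pixel/µm coordinate under the fixed naming convention."""
    half = side / 2.0
    if y < half:
        return "posterior" if x < half else "lateral"
    return "medial" if x < half else "anterior"


def principal_axis_angle(mask2d: np.ndarray, tie_tol: float = 1e-9) -> float:
    """In-plane principal-axis angle (degrees, in (−90, 90]) of a 2D mask.

    The angle of the eigenvector of the larger eigenvalue of the second
    central moment (covariance) matrix of foreground pixel centres, in the
    image frame (x right, y down).  A degenerate (isotropic) tensor — e.g. a
    circle — returns 0 by tie-break.
    """
    ys, xs = np.nonzero(mask2d)
    if xs.size == 0:
        raise ValueError("cannot compute a principal axis of an empty mask")
    coords = np.stack([xs, ys]).astype(np.float64)
    cov = np.cov(coords) if xs.size > 1 else np.zeros((2, 2))
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[1] - eigvals[0] <= tie_tol * max(eigvals[1], 1.0):
        return 0.0
    vx, vy = eigvecs[:, 1]  # eigenvector of the larger eigenvalue
    angle = np.degrees(np.arctan2(vy, vx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


def _pad_to_square(values: np.ndarray, side: int) -> np.ndarray:
    """Centre-pad (z, y, x) values with zeros to a (z, side, side) canvas."""
    _, ny, nx = values.shape
    py, px = side - ny, side - nx
    if py < 0 or px < 0:
        raise ValueError(f"canvas side {side} smaller than input plane {(ny, nx)}")
    return np.pad(
        values,
        ((0, 0), (py // 2, py - py // 2), (px // 2, px - px // 2)),
    )


def rotate_inplane(
    volume: VoxelVolume, angle_deg: float, order: int = 0, expand: bool = True
) -> VoxelVolume:
    """Rotate every slice in-plane by ``angle_deg`` about the canvas centre.

    With ``expand`` the canvas is first centre-padded to an even square large
    enough to hold any rotation of the input plane, so no foreground can be
    clipped.  ``order=0`` (nearest-neighbour) keeps masks binary.
    """
    nz, ny, nx = volume.shape
    if expand:
        side = int(np.ceil(np.hypot(ny, nx)))
        side += side % 2  # even canvas
        values = _pad_to_square(volume.values, side)
    else:
        values = volume.values
    _, ny, nx = values.shape
    c = np.array([(ny - 1) / 2.0, (nx - 1) / 2.0])
    th = np.radians(angle_deg)
    # inverse map in (y, x) order: p_in - c = M @ (p_out - c)
    m = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = np.empty_like(values)
    offset = c - m @ c
    for z in range(values.shape[0]):
        ndi.affine_transform(
            values[z], m, offset=offset, output=out[z], order=order, mode="constant", cval=0
        )
    return volume.with_values(out)


def principal_axis_align(volume: VoxelVolume) -> tuple[VoxelVolume, float]:
    """Rotate the stack so its in-plane principal axis lies along +x (0°).

    The angle is measured on the z-projection of the (binary) volume — the
    whole cross-section turns as one rigid body.  Returns the rotated volume
    and the applied angle in degrees (the negative of the measured axis
    angle); re-running on the output yields an angle below 1°.
    """
    projection = np.asarray(volume.values).any(axis=0)
    angle = principal_axis_angle(projection)
    rotated = rotate_inplane(volume, -angle, order=0)
    return rotated, -angle


def rotate_minus45_and_pad(volume: VoxelVolume, check_tol: float = 0.005) -> VoxelVolume:
    """Apply the fixed −45° rotation and pad to an even square canvas.

    Post-check: the foreground voxel count changes by at most ``check_tol``
    (fraction) under the nearest-neighbour resampling.
    """
    before = volume.foreground_count()
    out = rotate_inplane(volume, -45.0, order=0)
    after = out.foreground_count()
    if before and abs(after - before) > check_tol * before:
        raise RuntimeError(
            f"foreground not conserved by rotation: {before} -> {after} voxels"
        )
    return out


def flip_needed(mask2d: np.ndarray, min_lobe: int = 5) -> bool:
    """Whether the canvas should be rotated a further 180°.

    On a bilobed projection (tibia + fibula) the smaller lobe is required in
    the upper half-canvas; returns True when it sits in the lower half.
    Single-component projections never flip.
    """
    labels, n = ndi.label(mask2d, structure=np.ones((3, 3), dtype=int))
    if n < 2:
        return False
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[1]] < min_lobe:
        return False
    small = order[1] + 1
    cy = ndi.center_of_mass(labels == small)[0]
    return bool(cy > (mask2d.shape[0] - 1) / 2.0)


def assign_quadrants(side: int, rotation_deg: float = 0.0) -> RegionPartition:
    """Partition an even square canvas into the four named quadrants."""
    if side % 2:
        raise ValueError(f"canvas side must be even, got {side}")
    half = side // 2
    labels = np.empty((side, side), dtype=np.uint8)
    labels[:half, :half] = _REGION_CODE["posterior"]  # upper-left
    labels[:half, half:] = _REGION_CODE["lateral"]  # upper-right
    labels[half:, :half] = _REGION_CODE["medial"]  # lower-left
    labels[half:, half:] = _REGION_CODE["anterior"]  # lower-right
    return RegionPartition(side=side, labels=labels, rotation_deg=rotation_deg)


def mask_to_region(volume: VoxelVolume, partition: RegionPartition, region: str) -> VoxelVolume:
    """Zero every voxel outside the named quadrant (applied to all slices).

    Objects straddling a quadrant boundary are cut at the boundary.
    """
    keep = partition.mask(region)
    _, ny, nx = volume.shape
    if (ny, nx) != keep.shape:
        raise ValueError(f"canvas {(ny, nx)} does not match partition side {partition.side}")
    out = np.where(keep[None, :, :], volume.values, 0)
    return volume.with_values(out.astype(volume.values.dtype))
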