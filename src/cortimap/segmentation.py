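"""Binarisation and cortical mask construction.

Greyscale CT stacks are binarised with a global iterative (isodata)
threshold, after which the solid cortical compartment is built by
morphologically closing the bone mask and filling every fully enclosed
cavity.  Cortical porosity is then the set difference

    porosity = solid cortex AND NOT bone,

which partitions the solid cortex exactly into mineralised bone and pore
space.  The marrow cavity and the exterior are never filled: any background
component that reaches the canvas border — including the open first/last
slice faces of a cropped stack — is treated as outside the cortex.

Closing uses a true Euclidean ball realised through two distance
transforms.  Iterated 6-connected dilations (an L1 ball) of radius *n* only
guarantee closure of tubes of radius n/√3, so a Euclidean ball is required
for the "closing radius ≥ largest canal radius" contract to hold at face
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume import VoxelVolume

__all__ = [
    "CorticalGeometry",
    "iterative_threshold",
    "binarize",
    "fill_cortex",
    "extract_porosity",
    "segment",
]


@dataclass
class CorticalGeometry:
    """Masks derived from one greyscale stack.

    Invariants (checked on construction): bone ⊆ solid, porosity ⊆ solid,
    porosity ∩ bone = ∅ and porosity ∪ (bone ∩ solid) = solid.
    """

    bone: VoxelVolume
    solid_cortex: VoxelVolume
    porosity: VoxelVolume
    threshold: float

    def __post_init__(self) -> None:
        b = self.bone.values.astype(bool)
        s = self.solid_cortex.values.astype(bool)
        p = self.porosity.values.astype(bool)
        if np.any(p & ~s):
            raise ValueError("porosity mask extends outside the solid cortex")
        if np.any(p & b):
            raise ValueError("porosity and bone masks overlap")
        if np.any((p | (b & s)) != s):
            raise ValueError("porosity and bone do not partition the solid cortex")


def iterative_threshold(volume: VoxelVolume, tol: float = 0.5, max_iter: int = 500) -> float:
    """Global iterative (isodata) threshold of a greyscale volume.

    Starting from the global mean, iterate

        t ← (mean of values < t + mean of values ≥ t) / 2

    until the update is smaller than ``tol`` grey levels (default 0.5).
    Returns the converged threshold.  Raises on a constant image, which has
    no two classes to separate.
    """
    values = np.asarray(volume.values, dtype=np.float64).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant image")
    t = float(values.mean())
    for _ in range(max_iter):
        below = values < t
        if not below.any() or below.all():
            break
        t_new = 0.5 * (values[below].mean() + values[~below].mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = float(t_new)
    return float(t)


def binarize(volume: VoxelVolume, threshold: float) -> VoxelVolume:
    """Bone mask: voxel ≥ threshold → 1 else 0 (bright bone on dark background)."""
    mask = (np.asarray(volume.values) >= threshold).astype(np.uint8)
    return VoxelVolume(mask, volume.voxel_size_um, "mask")


def _ball_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilate by a Euclidean ball of ``radius`` voxels (centre-to-centre)."""
    return ndi.distance_transform_edt(~mask) <= radius


def _ball_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erode by a Euclidean ball of ``radius`` voxels."""
    return ndi.distance_transform_edt(mask) > radius


def _border_aware_fill(mask: np.ndarray) -> np.ndarray:
    """Fill cavities not connected to any canvas border face.

    Background components are traced with 6-connectivity; any component
    touching the border (all six faces, including the open z ends of a
    cropped stack) is kept as background — this is what prevents the marrow
    and the exterior from ever being filled.
    """
    background = ~mask
    labels, n = ndi.label(background)  # 6-connectivity by default
    if n == 0:
        return mask.copy()
    border = np.zeros(n + 1, dtype=bool)
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border[np.unique(labels[tuple(sl)])] = True
    border[0] = True  # foreground pseudo-label
    holes = background & ~border[labels]
    return mask | holes


def fill_cortex(bone_mask: VoxelVolume, closing_radius_vox: float = 8.0) -> VoxelVolume:
    """Solid cortical compartment: closing + border-aware hole filling.

    ``closing_radius_vox`` (voxels) must be at least the largest expected
    canal radius so that every intracortical tube is sealed; the paper-style
    "dilate until closed, then return to original size" is realised as one
    dilation/erosion pair with a Euclidean ball, followed by a 3D hole fill
    that preserves border-connected background (exterior and marrow).
    Idempotent on its own output.
    """
    if closing_radius_vox <= 0:
        raise ValueError(f"closing radius must be > 0 voxels, got {closing_radius_vox}")
    mask = bone_mask.values.astype(bool)
    # pad so the dilation is never clipped by the canvas edge (a clipped
    # dilation cannot be undone by the erosion and would leave spurious
    # caps outside the cortex), and erode half a voxel deeper than the
    # dilation: a digital concave surface (e.g. the endosteal circle) has
    # staircase notches the continuum ball cannot enter, and a symmetric
    # threshold would fill them with a one-voxel ring of spurious
    # "porosity"; genuine bone removed by the deeper erosion is restored
    # from the original mask below
    pad = int(np.ceil(closing_radius_vox)) + 2
    # z faces are artificial cuts through continuing bone: replicate the
    # end slices so canals intersecting them still seal; in-plane padding
    # is genuine empty space
    padded = np.pad(mask, ((pad, pad), (0, 0), (0, 0)), mode="edge")
    padded = np.pad(padded, ((0, 0), (pad, pad), (pad, pad)))
    closed = _ball_erode(_ball_dilate(padded, closing_radius_vox), closing_radius_vox + 0.5)
    closed = closed[pad:-pad, pad:-pad, pad:-pad]
    closed |= mask
    solid = _border_aware_fill(closed)
    return bone_mask.with_values(solid.astype(np.uint8), "mask")


def extract_porosity(solid_cortex: VoxelVolume, bone_mask: VoxelVolume) -> VoxelVolume:
    """Cortical porosity: solid cortex AND NOT bone."""
    solid_cortex.check_compatible(bone_mask)
    porosity = solid_cortex.values.astype(bool) & ~bone_mask.values.astype(bool)
    return solid_cortex.with_values(porosity.astype(np.uint8), "mask")


def segment(
    greyscale: VoxelVolume,
    closing_radius_vox: float = 8.0,
    threshold: float | None = None,
) -> CorticalGeometry:
    """Full segmentation stage: threshold → binarise → fill → porosity."""
    t = iterative_threshold(greyscale) if threshold is None else float(threshold)
    bone = binarize(greyscale, t)
    solid = fill_cortex(bone, closing_radius_vox)
    porosity = extract_porosity(solid, bone)
    return CorticalGeometry(bone=bone, solid_cortex=solid, porosity=porosity, threshold=t)
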