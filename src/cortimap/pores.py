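"""Connected pore components, the volume filter, and cortical morphometry.

Porosity voxels are grouped into maximal connected components (26-
connectivity by default, as in common particle analysers; 6-connectivity is
available) and sorted by volume into

    noise   [0, 25) µm³        — discarded from all densities,
    lacuna  [25, 2500] µm³     — osteocyte lacunae,
    canal   (2500, ∞) µm³      — intracortical vascular canals.

Both boundaries are inclusive on the lacuna side: the canal class is
defined strictly above 2500 µm³, and 25 µm³ is treated symmetrically.

Morphometry follows standard bone nomenclature: Ct.TV is the solid-cortex
volume (pores included), Ct.Po the lacuna+canal volume fraction of Ct.TV,
N.Ca/Ct.TV and N.Lc/Ct.TV the component number densities, Ca.V/Ct.TV and
Lc.V/Ct.TV the class volume fractions, and mean Ca.V / Lc.V the arithmetic
mean component volumes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .regionalisation import REGION_NAMES, RegionPartition, mask_to_region, region_of_point
from .volume import VoxelVolume

__all__ = [
    "CLASS_BOUNDARIES",
    "label_components",
    "classify_by_volume",
    "pore_table",
    "regional_pore_tables",
    "compute_morphometry",
    "morphometry_by_scope",
]

logger = logging.getLogger(__name__)

#: (noise/lacuna, lacuna/canal) volume boundaries in µm³.
CLASS_BOUNDARIES = (25.0, 2500.0)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=int)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def label_components(
    porosity: VoxelVolume, connectivity: int = 26
) -> tuple[VoxelVolume, np.ndarray]:
    """Label maximal connected foreground components.

    Returns the label map (ids 1..n) and the per-component voxel counts
    (``counts[i]`` is the size of component ``i + 1``).
    """
    labels, n = ndi.label(porosity.values.astype(bool), structure=_structure(connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return porosity.with_values(labels.astype(np.int32), "labels"), counts


def classify_by_volume(
    volume_um3: float, boundaries: tuple[float, float] = CLASS_BOUNDARIES
) -> str:
    """Volume filter: noise < b0 ≤ lacuna ≤ b1 < canal.  Volume must be > 0."""
    if not volume_um3 > 0:
        raise ValueError(f"component volume must be positive, got {volume_um3}")
    b0, b1 = boundaries
    if volume_um3 < b0:
        return "noise"
    if volume_um3 <= b1:
        return "lacuna"
    return "canal"


def _classify_array(volumes: np.ndarray, boundaries: tuple[float, float]) -> np.ndarray:
    b0, b1 = boundaries
    out = np.where(volumes < b0, "noise", np.where(volumes <= b1, "lacuna", "canal"))
    return out


def pore_table(
    label_volume: VoxelVolume,
    counts: np.ndarray,
    partition: RegionPartition | None = None,
    boundaries: tuple[float, float] = CLASS_BOUNDARIES,
) -> pd.DataFrame:
    """One row per component: id, voxels, volume, class, centroid, region.

    Centroids are in µm in the canvas frame.  When a partition is supplied
    the region is assigned from the component centroid; regional tables
    under the mask-then-analyse (split) convention come from
    :func:`regional_pore_tables` instead.
    """
    n = len(counts)
    vs = label_volume.voxel_size_um
    if n == 0:
        return pd.DataFrame(
            columns=["label", "voxels", "volume_um3", "class", "cz_um", "cy_um", "cx_um", "region"]
        )
    centroids = np.asarray(
        ndi.center_of_mass(
            np.ones(label_volume.shape, dtype=np.uint8),
            label_volume.values,
            index=np.arange(1, n + 1),
        )
    )
    volumes = counts * label_volume.voxel_volume_um3
    df = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "voxels": counts.astype(np.int64),
            "volume_um3": volumes,
            "class": _classify_array(volumes, boundaries),
            "cz_um": centroids[:, 0] * vs,
            "cy_um": centroids[:, 1] * vs,
            "cx_um": centroids[:, 2] * vs,
        }
    )
    if partition is not None:
        side_um = partition.side * vs
        df["region"] = [
            region_of_point(x, y, side_um) for x, y in zip(df["cx_um"], df["cy_um"])
        ]
    else:
        df["region"] = "whole"
    return df


def regional_pore_tables(
    porosity: VoxelVolume,
    partition: RegionPartition,
    connectivity: int = 26,
    boundaries: tuple[float, float] = CLASS_BOUNDARIES,
    whole_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mask-then-analyse regional tables: clip porosity to each quadrant first.

    A component straddling a quadrant boundary is cut at the boundary, so
    its clipped pieces are classified from their clipped volumes (a canal
    fragment may classify as a lacuna within one region); a warning is
    logged when clipping changes the class census relative to the
    whole-volume table.
    """
    tables = []
    for region in REGION_NAMES:
        clipped = mask_to_region(porosity, partition, region)
        labels, counts = label_components(clipped, connectivity)
        t = pore_table(labels, counts, boundaries=boundaries)
        t["region"] = region
        tables.append(t)
    out = pd.concat(tables, ignore_index=True)
    if whole_table is not None:
        whole = whole_table["class"].value_counts()
        clipped_census = out["class"].value_counts()
        for cls in ("lacuna", "canal"):
            if int(clipped_census.get(cls, 0)) != int(whole.get(cls, 0)):
                logger.warning(
                    "quadrant clipping changed the %s census: %d whole vs %d clipped",
                    cls,
                    int(whole.get(cls, 0)),
                    int(clipped_census.get(cls, 0)),
                )
    return out


def compute_morphometry(records: pd.DataFrame, ct_tv_mm3: float, scope: str = "whole") -> dict:
    """Standard morphometric parameters for one scope.

    ``records`` holds the pore components in scope; ``ct_tv_mm3`` the
    solid-cortex volume of that scope in mm³.  Noise components are
    excluded from porosity and densities.  Empty classes give density 0 and
    a missing (NaN) mean volume.
    """
    if not ct_tv_mm3 > 0:
        raise ValueError(f"Ct.TV must be > 0 mm³, got {ct_tv_mm3}")
    ct_tv_um3 = ct_tv_mm3 * 1e9
    canals = records.loc[records["class"] == "canal", "volume_um3"]
    lacunae = records.loc[records["class"] == "lacuna", "volume_um3"]
    ca_v, lc_v = float(canals.sum()), float(lacunae.sum())
    return {
        "scope": scope,
        "ct_tv_mm3": float(ct_tv_mm3),
        "ct_po_pct": (ca_v + lc_v) / ct_tv_um3 * 100.0,
        "n_ca_per_mm3": len(canals) / ct_tv_mm3,
        "n_lc_per_mm3": len(lacunae) / ct_tv_mm3,
        "ca_v_per_ct_tv_pct": ca_v / ct_tv_um3 * 100.0,
        "lc_v_per_ct_tv_pct": lc_v / ct_tv_um3 * 100.0,
        "mean_ca_v_um3": float(canals.mean()) if len(canals) else float("nan"),
        "mean_lc_v_um3": float(lacunae.mean()) if len(lacunae) else float("nan"),
    }


def morphometry_by_scope(
    whole_records: pd.DataFrame,
    regional_records: pd.DataFrame | None,
    ct_tv_mm3: dict[str, float],
) -> pd.DataFrame:
    """Morphometry rows for the whole cross-section and each quadrant."""
    rows = [compute_morphometry(whole_records, ct_tv_mm3["whole"], "whole")]
    if regional_records is not None:
        for region in REGION_NAMES:
            if ct_tv_mm3.get(region, 0) > 0:
                rows.append(
                    compute_morphometry(
                        regional_records[regional_records["region"] == region],
                        ct_tv_mm3[region],
                        region,
                    )
                )
    return pd.DataFrame(rows)
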