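"""Canal-included / canal-excluded distance mapping and the association filter.

Two Euclidean distance maps are built over the cortex:

* **Ca.Incl** — domain = solid cortex minus intracortical canals; distances
  measure the path to the nearest *vascular* surface, i.e. the endosteal or
  periosteal boundary **or** a canal wall.
* **Ca.Excl** — domain = solid cortex with canals treated as bone, so only
  the endosteal/periosteal surfaces count.

Each lacuna inherits the minimum map value over its voxels ("minimum
lacunar distance"); lacuna voxels themselves stay in-domain when the maps
are built — only the canal mask is subtracted from the cortex — so a lacuna
never shields itself.  Distances are voxel-centre to voxel-centre and a
surface (out-of-domain) voxel carries distance 0, so an in-domain voxel
face-adjacent to background reads one voxel width, not half.

A lacuna whose minimum distance shrinks when canals are included (beyond a
float-representation tolerance) is *canal-associated*; one whose minimum is
unchanged is *surface-associated*.  Per-lacuna minima are averaged with
equal weight per lacuna into the mean minimum lacunar distance (Mm.Lc.D),
and binned into [0,25), [25,50), [50,75), [75,100), [100,∞) µm to give the
lacunar percentage distance distribution (%Lc.D.D); the 100 µm ceiling is
the conventional diffusion-survival limit for an osteocyte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volume import VoxelVolume

__all__ = [
    "DEFAULT_BIN_EDGES",
    "ASSOCIATION_TOL_UM",
    "DistanceMapPair",
    "perforated_cortex",
    "distance_map",
    "build_distance_maps",
    "lacuna_min_distance",
    "lacuna_distance_table",
    "mean_min_distance",
    "bin_distance",
    "associate",
    "association_summary",
]

#: Distance-bin edges in µm; bins are [0,25), [25,50), [50,75), [75,100), [100,∞).
DEFAULT_BIN_EDGES = (25.0, 50.0, 75.0, 100.0)

#: Equality tolerance (µm) for the association filter.  The two maps are
#: deterministic transforms of their domains, so true equality is exact;
#: this guards floating-point representation only.
ASSOCIATION_TOL_UM = 1e-6


@dataclass
class DistanceMapPair:
    """Ca.Incl and Ca.Excl maps with their domains."""

    ca_incl: VoxelVolume
    ca_excl: VoxelVolume
    domain_incl: VoxelVolume
    domain_excl: VoxelVolume

    def __post_init__(self) -> None:
        inside = self.domain_incl.values.astype(bool)
        if np.any(self.ca_incl.values[inside] > self.ca_excl.values[inside] + ASSOCIATION_TOL_UM):
            raise ValueError("map invariant violated: Ca.Incl exceeds Ca.Excl in-domain")


def perforated_cortex(solid_cortex: VoxelVolume, canal_mask: VoxelVolume) -> VoxelVolume:
    """Cortex perforated by canals: solid AND NOT canal.

    Lacuna (and noise) voxels remain in-domain — only canal surfaces are
    added to the vascular boundary.  A canal voxel outside the cortex
    violates the construction and raises.
    """
    solid_cortex.check_compatible(canal_mask)
    solid = solid_cortex.values.astype(bool)
    canal = canal_mask.values.astype(bool)
    if np.any(canal & ~solid):
        raise ValueError("canal mask has voxels outside the solid cortex")
    return solid_cortex.with_values((solid & ~canal).astype(np.uint8), "mask")


def distance_map(domain: VoxelVolume) -> VoxelVolume:
    """Exact Euclidean distance (µm) to the nearest out-of-domain voxel centre.

    Out-of-domain voxels carry 0.  Raises if the domain is empty (nothing to
    map) or all-foreground (no surface exists).
    """
    mask = domain.values.astype(bool)
    if not mask.any():
        raise ValueError("distance map domain is empty")
    if mask.all():
        raise ValueError("domain is all-foreground: no surface exists")
    dist = ndi.distance_transform_edt(mask, sampling=domain.voxel_size_um)
    return domain.with_values(dist.astype(np.float64), "distance")


def build_distance_maps(solid_cortex: VoxelVolume, canal_mask: VoxelVolume) -> DistanceMapPair:
    """Construct the Ca.Incl / Ca.Excl pair from the cortex and canal masks."""
    domain_incl = perforated_cortex(solid_cortex, canal_mask)
    domain_excl = solid_cortex.astype_kind("mask")
    return DistanceMapPair(
        ca_incl=distance_map(domain_incl),
        ca_excl=distance_map(domain_excl),
        domain_incl=domain_incl,
        domain_excl=domain_excl,
    )


def lacuna_min_distance(lacuna_voxels: tuple[np.ndarray, ...], dist: VoxelVolume) -> float:
    """Minimum map value over one lacuna's voxel index arrays."""
    if len(lacuna_voxels[0]) == 0:
        raise ValueError("lacuna has no voxels")
    return float(dist.values[lacuna_voxels].min())


def bin_distance(minimum_um: float, edges: tuple[float, ...] = DEFAULT_BIN_EDGES) -> str:
    """Distance-bin label for one minimum, e.g. ``[25,50)`` or ``[100,inf)``."""
    if minimum_um < 0:
        raise ValueError(f"minimum distance must be ≥ 0, got {minimum_um}")
    prev = 0.0
    for e in edges:
        if minimum_um < e:
            return f"[{prev:g},{e:g})"
        prev = e
    return f"[{prev:g},inf)"


def associate(min_ca_incl: float, min_ca_excl: float, tol: float = ASSOCIATION_TOL_UM) -> str:
    """Association filter for one lacuna.

    Canal inclusion shortening the minimum distance (beyond ``tol``) means
    the nearest vascular supply is a canal; an unchanged minimum means it is
    a bone surface.
    """
    if min_ca_incl > min_ca_excl + tol:
        raise ValueError(
            f"Ca.Incl minimum ({min_ca_incl}) exceeds Ca.Excl minimum ({min_ca_excl})"
        )
    return "canal" if min_ca_incl < min_ca_excl - tol else "surface"


def lacuna_distance_table(
    label_volume: VoxelVolume,
    pore_records: pd.DataFrame,
    maps: DistanceMapPair,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Per-lacuna distance records.

    One row per lacuna-class component of ``pore_records``: its minimum
    distance under each map, the distance bin of each minimum, and the
    association class.  Noise components are ignored throughout.
    """
    lac = pore_records[pore_records["class"] == "lacuna"]
    if lac.empty:
        return pd.DataFrame(
            columns=[
                "label", "region", "volume_um3",
                "d_ca_incl_um", "d_ca_excl_um",
                "bin_ca_incl", "bin_ca_excl", "association",
            ]
        )
    labels = label_volume.values
    wanted = lac["label"].to_numpy()
    # Single pass over the label map: per-label minimum under each map.
    min_incl = ndi.minimum(maps.ca_incl.values, labels=labels, index=wanted)
    min_excl = ndi.minimum(maps.ca_excl.values, labels=labels, index=wanted)
    min_incl = np.atleast_1d(min_incl)
    min_excl = np.atleast_1d(min_excl)
    rows = pd.DataFrame(
        {
            "label": wanted,
            "region": lac["region"].to_numpy(),
            "volume_um3": lac["volume_um3"].to_numpy(),
            "d_ca_incl_um": min_incl,
            "d_ca_excl_um": min_excl,
            "bin_ca_incl": [bin_distance(d, edges) for d in min_incl],
            "bin_ca_excl": [bin_distance(d, edges) for d in min_excl],
            "association": [
                {"canal": "canal-associated", "surface": "surface-associated"}[associate(a, b)]
                for a, b in zip(min_incl, min_excl)
            ],
        }
    )
    return rows


def mean_min_distance(records: pd.DataFrame, column: str = "d_ca_incl_um") -> float:
    """Mm.Lc.D: equal-weight mean of per-lacuna minima (NaN for an empty scope)."""
    if records.empty:
        return float("nan")
    return float(records[column].mean())


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    labels, prev = [], 0.0
    for e in edges:
        labels.append(f"[{prev:g},{e:g})")
        prev = e
    labels.append(f"[{prev:g},inf)")
    return labels


def association_summary(
    records: pd.DataFrame,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    scopes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-scope distance summary.

    For the whole cross-section and each region present in ``records``:
    Mm.Lc.D under each map, % canal-associated, mean lacunar volume per
    association class, and %Lc.D.D per bin under each map (exclusive bins;
    a cumulative "% within edge" column per finite edge is included as
    well, since the exclusive 75–100 µm bin is often folded away in
    cumulative reports).
    """
    if scopes is None:
        scopes = ["whole"] + sorted(records["region"].dropna().unique().tolist())
    bins = _bin_labels(edges)
    out = []
    for scope in scopes:
        sub = records if scope == "whole" else records[records["region"] == scope]
        n = len(sub)
        row: dict = {"scope": scope, "n_lacunae": n}
        if n == 0:
            out.append(row)
            continue
        row["mm_lc_d_ca_incl_um"] = mean_min_distance(sub, "d_ca_incl_um")
        row["mm_lc_d_ca_excl_um"] = mean_min_distance(sub, "d_ca_excl_um")
        canal = sub[sub["association"] == "canal-associated"]
        surf = sub[sub["association"] == "surface-associated"]
        row["pct_canal_associated"] = 100.0 * len(canal) / n
        row["mean_lc_v_canal_assoc_um3"] = (
            float(canal["volume_um3"].mean()) if len(canal) else float("nan")
        )
        row["mean_lc_v_surface_assoc_um3"] = (
            float(surf["volume_um3"].mean()) if len(surf) else float("nan")
        )
        for suffix, bin_col, d_col in (
            ("ca_incl", "bin_ca_incl", "d_ca_incl_um"),
            ("ca_excl", "bin_ca_excl", "d_ca_excl_um"),
        ):
            counts = sub[bin_col].value_counts()
            for b in bins:
                row[f"pct_{suffix}_{b}"] = 100.0 * int(counts.get(b, 0)) / n
            for e in edges:
                row[f"pct_{suffix}_within_{e:g}um"] = (
                    100.0 * int((sub[d_col] < e).sum()) / n
                )
        out.append(row)
    return pd.DataFrame(out)
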