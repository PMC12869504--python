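"""End-to-end orchestration: stack → masks → tables → summaries.

The pipeline executes the five stages in order — segment, regionalise,
classify, distmap, summarise — persisting every intermediate volume and
table, and records a machine-readable manifest (parameters, stage list,
SHA-256 checksum of every output file).  Deterministic stages are
bit-identical under rerun with the same config.

Group comparison is deliberately descriptive: per-group mean ± sample s.d.
(n−1 denominator) of every parameter per scope.  Significance testing is
left to external statistics tooling; the pipeline exports tidy tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import distances, phantom, pores, regionalisation, segmentation
from .volume import VoxelVolume, read_stack, write_stack

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "sample_summary", "summarise_groups"]

logger = logging.getLogger(__name__)

STAGES = ("segment", "regionalise", "classify", "distmap", "summarise")


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Exactly one of ``input_path`` (a TIFF stack) or ``phantom_preset``
    (``"wt"`` / ``"ko"``) selects the input.  ``orient=False`` skips the
    principal-axis alignment and the −45° rotation for inputs that are
    already in the canonical orientation (phantoms are generated that way).
    """

    input_path: str | None = None
    phantom_preset: str | None = None
    phantom_overrides: dict = field(default_factory=dict)  # PhantomSpec fields
    voxel_size_um: float = 1.65
    threshold: float | None = None
    closing_radius_vox: float = 8.0
    connectivity: int = 26
    class_boundaries: tuple[float, float] = pores.CLASS_BOUNDARIES
    bin_edges: tuple[float, ...] = distances.DEFAULT_BIN_EDGES
    straddle_mode: str = "split"  # regional tables: "split" (clip) or "centroid"
    orient: bool = True
    flip: bool | None = None  # None = auto from the bilobed projection
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.phantom_preset is None):
            raise ValueError("exactly one of input_path / phantom_preset is required")
        if self.phantom_preset is not None and self.phantom_preset not in ("wt", "ko"):
            raise ValueError(f"unknown phantom preset {self.phantom_preset!r}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel size must be > 0 µm")
        if self.closing_radius_vox <= 0:
            raise ValueError("closing radius must be > 0 voxels")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        b0, b1 = self.class_boundaries
        if not 0 < b0 < b1:
            raise ValueError("class boundaries must be strictly increasing and positive")
        if list(self.bin_edges) != sorted(self.bin_edges) or self.bin_edges[0] <= 0:
            raise ValueError("bin edges must be positive and strictly increasing")
        if self.straddle_mode not in ("split", "centroid"):
            raise ValueError("straddle_mode must be 'split' or 'centroid'")


@dataclass
class PipelineResult:
    """In-memory outputs of one run (also persisted when out_dir is set)."""

    config: RunConfig
    threshold: float
    solid_cortex: VoxelVolume
    porosity: VoxelVolume
    partition: regionalisation.RegionPartition
    label_volume: VoxelVolume
    whole_pores: pd.DataFrame
    regional_pores: pd.DataFrame
    morphometry: pd.DataFrame
    maps: distances.DistanceMapPair
    distance_records: pd.DataFrame
    distance_summary: pd.DataFrame
    truth: "phantom.PhantomTruth | None" = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _pad_to_even_square(volume: VoxelVolume) -> VoxelVolume:
    _, ny, nx = volume.shape
    side = max(ny, nx)
    side += side % 2
    return volume.with_values(regionalisation._pad_to_square(volume.values, side))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow for one sample; see the module docstring."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def persist_volume(vol: VoxelVolume, name: str, as_mask: bool = False) -> None:
        if out_dir is None:
            return
        values = vol.values
        if as_mask:
            values = (values.astype(np.uint8) * 255)
        elif vol.kind == "distance":
            values = values.astype(np.float32)
        path = out_dir / name
        write_stack(VoxelVolume(values, vol.voxel_size_um, "greyscale"), path)
        written.append(path)

    def persist_table(df: pd.DataFrame, name: str) -> None:
        if out_dir is None:
            return
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    # --- input ----------------------------------------------------------
    truth = None
    if config.phantom_preset is not None:
        spec_fn = phantom.wt_like_spec if config.phantom_preset == "wt" else phantom.ko_like_spec
        spec = spec_fn(
            seed=config.seed,
            voxel_size_um=config.voxel_size_um,
            **config.phantom_overrides,
        )
        greyscale, truth = phantom.generate_phantom(spec)
        if out_dir:
            spec.to_json(out_dir / "phantom_spec.json")
            written.append(out_dir / "phantom_spec.json")
            persist_table(truth.objects, "phantom_truth.csv")
            persist_volume(greyscale, "phantom_greyscale.tif")
    else:
        greyscale = read_stack(config.input_path, config.voxel_size_um)

    # --- stage 1: segment (threshold + binarise) ------------------------
    threshold = (
        segmentation.iterative_threshold(greyscale)
        if config.threshold is None
        else float(config.threshold)
    )
    bone = segmentation.binarize(greyscale, threshold)
    logger.info("segment: shape=%s threshold=%.2f", greyscale.shape, threshold)

    # --- stage 2: regionalise (orient, pad, quadrants) ------------------
    applied_angle = 0.0
    if config.orient:
        bone, applied_angle = regionalisation.principal_axis_align(bone)
        bone = regionalisation.rotate_minus45_and_pad(bone)
        applied_angle -= 45.0
        projection = bone.values.any(axis=0)
        do_flip = (
            regionalisation.flip_needed(projection) if config.flip is None else config.flip
        )
        if do_flip:
            bone = bone.with_values(bone.values[:, ::-1, ::-1])
            applied_angle += 180.0
    else:
        bone = _pad_to_even_square(bone)
    side = bone.shape[1]
    partition = regionalisation.assign_quadrants(side, rotation_deg=applied_angle)
    logger.info("regionalise: canvas side=%d applied angle=%.2f deg", side, applied_angle)

    # --- stage 1b on the oriented canvas: cortex + porosity -------------
    solid = segmentation.fill_cortex(bone, config.closing_radius_vox)
    porosity = segmentation.extract_porosity(solid, bone)
    persist_volume(bone, "bone_mask.tif", as_mask=True)
    persist_volume(solid, "solid_cortex.tif", as_mask=True)
    persist_volume(porosity, "porosity.tif", as_mask=True)

    # --- stage 3: classify ----------------------------------------------
    label_volume, counts = pores.label_components(porosity, config.connectivity)
    whole = pores.pore_table(
        label_volume, counts, partition, boundaries=config.class_boundaries
    )
    if config.straddle_mode == "split":
        regional = pores.regional_pore_tables(
            porosity, partition, config.connectivity,
            boundaries=config.class_boundaries, whole_table=whole,
        )
    else:
        regional = whole
    vs = porosity.voxel_size_um
    solid_bool = solid.values.astype(bool)
    ct_tv = {"whole": float(solid.foreground_count()) * vs**3 * 1e-9}
    for region in regionalisation.REGION_NAMES:
        keep = partition.mask(region)
        ct_tv[region] = float(np.count_nonzero(solid_bool & keep[None])) * vs**3 * 1e-9
    morphometry = pores.morphometry_by_scope(whole, regional, ct_tv)
    persist_table(whole, "pores_whole.csv")
    persist_table(regional, "pores_regional.csv")
    persist_table(morphometry, "morphometry.csv")
    if out_dir:
        path = out_dir / "pore_labels.tif"
        write_stack(label_volume.with_values(label_volume.values.astype(np.uint16)), path)
        written.append(path)

    # --- stage 4: distmap -----------------------------------------------
    canal_ids = whole.loc[whole["class"] == "canal", "label"].to_numpy()
    canal_mask = porosity.with_values(
        np.isin(label_volume.values, canal_ids).astype(np.uint8), "mask"
    )
    maps = distances.build_distance_maps(solid, canal_mask)
    records = distances.lacuna_distance_table(
        label_volume, whole, maps, edges=config.bin_edges
    )
    persist_volume(maps.ca_incl, "distance_ca_incl.tif")
    persist_volume(maps.ca_excl, "distance_ca_excl.tif")
    persist_table(records, "lacuna_distances.csv")

    # --- stage 5: summarise ----------------------------------------------
    summary = distances.association_summary(
        records,
        edges=config.bin_edges,
        scopes=["whole", *regionalisation.REGION_NAMES],
    )
    persist_table(summary, "distance_summary.csv")

    manifest = {
        "stages": list(STAGES),
        "parameters": {
            **asdict(config),
            "threshold_used": threshold,
            "applied_rotation_deg": applied_angle,
            "canvas_side": side,
        },
        "files": {},
    }
    if out_dir:
        manifest["files"] = {p.name: _sha256(p) for p in written}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        config=config,
        threshold=threshold,
        solid_cortex=solid,
        porosity=porosity,
        partition=partition,
        label_volume=label_volume,
        whole_pores=whole,
        regional_pores=regional,
        morphometry=morphometry,
        maps=maps,
        distance_records=records,
        distance_summary=summary,
        truth=truth,
        manifest=manifest,
    )


def sample_summary(result: PipelineResult) -> pd.DataFrame:
    """One wide row per scope: morphometry joined with the distance summary."""
    return result.morphometry.merge(result.distance_summary, on="scope", how="outer")


def summarise_groups(
    samples: list[pd.DataFrame], group_labels: list[str]
) -> pd.DataFrame:
    """Per-group mean ± sample s.d. of every parameter, per scope.

    Each element of ``samples`` is a :func:`sample_summary` table; scopes
    must agree across samples.  Returns a wide frame with one row per
    (group, scope) and ``<param>_mean`` / ``<param>_sd`` columns plus the
    group size ``n``.  A single-sample group reports s.d. 0.
    """
    if len(samples) != len(group_labels) or not samples:
        raise ValueError("need one group label per sample and at least one sample")
    scopes = list(samples[0]["scope"])
    for s in samples[1:]:
        if list(s["scope"]) != scopes:
            raise ValueError("samples have mismatched scopes")
    stacked = pd.concat(
        [s.assign(group=g) for s, g in zip(samples, group_labels)], ignore_index=True
    )
    params = [c for c in samples[0].columns if c != "scope"]
    grouped = stacked.groupby(["group", "scope"], sort=False)[params]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).fillna(0.0).add_suffix("_sd")
    n = grouped.size().rename("n")
    return pd.concat([mean, sd, n], axis=1).reset_index()
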