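"""Synthetic cortical phantoms with planted, ground-truthed porosity.

The phantom emulates a tibiofibular-junction-like cross-section at desk
scale: an annular cortical shell (optionally thickened in the posterior
quadrant) whose marrow cavity and canal lumens are open at the first and
last slice, containing

* straight z-axis **canal** tubes (analytic volume π r² L, always
  > 2500 µm³),
* randomly oriented ellipsoidal **lacunae** with log-normal volumes
  truncated to [40, 2000] µm³ so voxelisation can never cross the
  25 / 2500 µm³ class boundaries, and
* 1–3-voxel **noise** specks (< 25 µm³).

Canal line density, lacuna density and the peri-canal stratum (a fraction
of lacunae placed within a stated distance of a canal wall, with a volume
multiplier) are configurable per region, which is how the WT-like preset
encodes the posterior-dominant canal density and enlarged canal-associated
lacunae, and the KO-like preset encodes a uniformly hyper-vascularised
cortex with no volume coupling.

Objects are placed by rejection sampling in a fixed order (canals, then
lacunae region by region, then noise) with a minimum inter-surface gap of
4 µm — wider than one voxel diagonal, so rasterised objects can never touch
even corner-to-corner and component counts are exactly recoverable.  Every
quantity is drawn from one seeded generator: the same spec and seed
reproduce the volume and the truth table bit-exactly.

Ground truth records, per object: centroid, analytic volume, region (the
same quadrant convention the analysis applies, evaluated at the centroid),
and — for lacunae — the minimum distance from its voxel centres to the
nearest canal wall and to the nearest endosteal/periosteal surface
(analytic cylinder/annulus geometry), plus the implied association class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .regionalisation import REGION_NAMES, region_of_point
from .volume import VoxelVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "rasterize_ellipsoid",
    "generate_phantom",
    "wt_like_spec",
    "ko_like_spec",
]


def _per_region(value: float | Mapping[str, float]) -> dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - set(REGION_NAMES)
        if unknown:
            raise ValueError(f"unknown region keys {sorted(unknown)}")
        return {r: float(value.get(r, 0.0)) for r in REGION_NAMES}
    return {r: float(value) for r in REGION_NAMES}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one phantom; see the module docstring.

    Defaults describe the geometry only (no planted objects); use
    :func:`wt_like_spec` / :func:`ko_like_spec` for the scenario presets.
    Densities accept a scalar (uniform) or a per-region mapping.
    """

    shape: tuple[int, int, int] = (200, 256, 256)  # (z, y, x) voxels
    voxel_size_um: float = 1.65
    outer_radius_um: float = 195.0
    wall_thickness_um: float = 85.0
    posterior_thickening: float = 1.0
    canal_density_per_mm3: float | Mapping[str, float] = 0.0
    canal_radius_um: tuple[float, float] = (3.0, 7.0)
    canal_surface_margin_um: float = 24.0
    lacuna_density_per_mm3: float | Mapping[str, float] = 0.0
    lacuna_volume_median_um3: float = 330.0
    lacuna_volume_sigma_log: float = 0.35
    lacuna_volume_bounds_um3: tuple[float, float] = (40.0, 2000.0)
    lacuna_max_aspect: float = 1.8
    lacuna_surface_margin_um: float = 4.0
    pericanal_fraction: float | Mapping[str, float] = 0.0
    pericanal_multiplier: float | Mapping[str, float] = 1.0
    pericanal_distance_um: float = 12.0
    min_gap_um: float = 4.0
    noise_count: int = 0
    noise_margin_um: float = 8.0
    bone_grey: float = 200.0
    pore_grey: float = 50.0
    grey_sd: float = 10.0
    preset: str = "custom"
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        vs = self.voxel_size_um
        if vs <= 0:
            raise ValueError("voxel size must be > 0 µm")
        if not (0 < self.wall_thickness_um < self.outer_radius_um):
            raise ValueError("need 0 < wall thickness < outer radius")
        if self.outer_radius_um > (min(ny, nx) / 2.0 - 2.0) * vs:
            raise ValueError("canvas too small to contain the cortex geometry")
        rmin, rmax = self.canal_radius_um
        length = nz * vs
        if any(v > 0 for v in _per_region(self.canal_density_per_mm3).values()):
            if not (0 < rmin <= rmax):
                raise ValueError("canal radius range must satisfy 0 < min ≤ max")
            if np.pi * rmin**2 * length <= 2500.0:
                raise ValueError(
                    "smallest canal volume would not exceed 2500 µm³ at this stack length"
                )
        b0, b1 = self.lacuna_volume_bounds_um3
        if not (25.0 < b0 < b1 < 2500.0):
            raise ValueError("lacuna volume bounds must lie strictly inside (25, 2500) µm³")
        if self.pericanal_distance_um <= self.min_gap_um:
            raise ValueError("peri-canal distance must exceed the minimum gap")
        if self.posterior_thickening < 1.0:
            raise ValueError("posterior thickening factor must be ≥ 1")

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("canal_density_per_mm3", "lacuna_density_per_mm3",
                  "pericanal_fraction", "pericanal_multiplier"):
            if isinstance(d[k], Mapping):
                d[k] = dict(d[k])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


@dataclass
class PhantomTruth:
    """Ground truth: one row per planted object, plus the planted label map."""

    objects: pd.DataFrame
    label_volume: VoxelVolume
    spec: PhantomSpec

    @property
    def canals(self) -> pd.DataFrame:
        return self.objects[self.objects["kind"] == "canal"]

    @property
    def lacunae(self) -> pd.DataFrame:
        return self.objects[self.objects["kind"] == "lacuna"]

    @property
    def noise(self) -> pd.DataFrame:
        return self.objects[self.objects["kind"] == "noise"]

    def porosity_mask(self) -> VoxelVolume:
        """Rasterised union of all planted objects."""
        return self.label_volume.with_values(
            (self.label_volume.values > 0).astype(np.uint8), "mask"
        )


_TRUTH_COLUMNS = [
    "label", "kind", "cz_um", "cy_um", "cx_um", "volume_um3", "raster_voxels",
    "region", "canal_radius_um", "d_canal_um", "d_surface_um", "association",
]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3×3 rotation matrix (via a normalised quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rasterize_ellipsoid(
    centre_um: np.ndarray,
    semi_axes_um: np.ndarray,
    orientation: np.ndarray | None,
    shape: tuple[int, int, int],
    voxel_size_um: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel set of an ellipsoid on a grid: all voxel centres satisfying
    the (inclusive) ellipsoid inequality.

    ``centre_um`` and ``semi_axes_um`` are (z, y, x) triples in µm;
    ``orientation`` is a rotation matrix whose columns are the ellipsoid
    axes in the (z, y, x) frame, or None for axis-aligned.  Voxel centres
    sit at ``index × voxel size``.  Raises if a semi-axis is non-positive
    or the ellipsoid's bounding box leaves the canvas.
    """
    centre = np.asarray(centre_um, dtype=float)
    axes = np.asarray(semi_axes_um, dtype=float)
    if np.any(axes <= 0):
        raise ValueError(f"semi-axes must be > 0 µm, got {axes}")
    rot = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
    vs = voxel_size_um
    a_max = float(axes.max())
    lo = np.floor((centre - a_max) / vs).astype(int)
    hi = np.ceil((centre + a_max) / vs).astype(int)
    if np.any(lo < 0) or np.any(hi > np.asarray(shape) - 1):
        raise ValueError("ellipsoid bounding box extends outside the canvas")
    grids = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij")
    p = np.stack([g.ravel() * vs for g in grids], axis=1) - centre
    q = p @ rot  # body-frame coordinates (rotᵀ · p, row-wise)
    inside = np.sum((q / axes) ** 2, axis=1) <= 1.0 + 1e-9  # inclusive boundary
    return tuple(g.ravel()[inside] for g in grids)  # type: ignore[return-value]


class _Placer:
    """Sphere-bound overlap bookkeeping for rejection sampling."""

    def __init__(self, gap_um: float) -> None:
        self.gap = gap_um
        self.centres: list[np.ndarray] = []  # (z, y, x) µm
        self.radii: list[float] = []
        self.canal_xy: list[tuple[float, float, float]] = []  # (y, x, r) µm

    def canal_clear(self, y: float, x: float, radius: float) -> bool:
        for cy, cx, cr in self.canal_xy:
            if np.hypot(y - cy, x - cx) <= cr + radius + self.gap:
                return False
        return True

    def sphere_clear(self, centre: np.ndarray, radius: float) -> bool:
        for c, r in zip(self.centres, self.radii):
            if np.linalg.norm(centre - c) <= r + radius + self.gap:
                return False
        return True

    def add_canal(self, y: float, x: float, r: float) -> None:
        self.canal_xy.append((y, x, r))

    def add_sphere(self, centre: np.ndarray, radius: float) -> None:
        self.centres.append(np.asarray(centre, dtype=float))
        self.radii.append(float(radius))


def _truncated_lognormal(
    rng: np.random.Generator,
    median: float,
    sigma: float,
    bounds: tuple[float, float],
    multiplier: float = 1.0,
    max_tries: int = 1000,
) -> float:
    for _ in range(max_tries):
        v = multiplier * median * np.exp(sigma * rng.standard_normal())
        if bounds[0] <= v <= bounds[1]:
            return float(v)
    raise RuntimeError(
        f"could not draw a lacuna volume inside {bounds} µm³ "
        f"(median {median}, multiplier {multiplier}): stratum over-constrained"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Render a greyscale phantom and its ground truth.

    Bone voxels are drawn N(bone grey, sd) and pore/background voxels
    N(pore grey, sd), clipped to 8 bits.  Raises when a stratum cannot be
    placed within ``spec.max_attempts`` rejection draws.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    vs = spec.voxel_size_um
    length_um = nz * vs
    r_out = spec.outer_radius_um
    wall = spec.wall_thickness_um

    # --- geometry -------------------------------------------------------
    cy_um, cx_um = (ny - 1) / 2.0 * vs, (nx - 1) / 2.0 * vs
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy * vs - cy_um, xx * vs - cx_um)
    # quadrant half-planes in pixel coordinates (side = canvas extent)
    half_y, half_x = ny / 2.0, nx / 2.0
    upper = yy < half_y
    left = xx < half_x
    r_in_map = np.full((ny, nx), r_out - wall)
    if spec.posterior_thickening != 1.0:
        r_in_map[upper & left] = r_out - wall * spec.posterior_thickening
    wall2d = (rr <= r_out) & (rr >= r_in_map)
    r_in_uniform = r_out - wall  # valid when thickening == 1

    def radial_margin(y_um: float, x_um: float) -> float:
        """Distance from an interior point to the nearest radial surface."""
        rad = np.hypot(y_um - cy_um, x_um - cx_um)
        if spec.posterior_thickening == 1.0:
            return min(rad - r_in_uniform, r_out - rad)
        j, i = int(round(y_um / vs)), int(round(x_um / vs))
        j, i = np.clip(j, 0, ny - 1), np.clip(i, 0, nx - 1)
        return float(_edt2d()[j, i]) - vs  # conservative by one voxel

    _edt_cache: list[np.ndarray] = []

    def _edt2d() -> np.ndarray:
        if not _edt_cache:
            _edt_cache.append(ndi.distance_transform_edt(wall2d, sampling=vs))
        return _edt_cache[0]

    wall_pixels = np.argwhere(wall2d)  # (N, 2) as (y, x)
    region_counts = {
        r: int(np.count_nonzero(wall2d & (upper & left if r == "posterior" else
                                          upper & ~left if r == "lateral" else
                                          ~upper & left if r == "medial" else
                                          ~upper & ~left)))
        for r in REGION_NAMES
    }
    region_vol_mm3 = {r: region_counts[r] * nz * vs**3 * 1e-9 for r in REGION_NAMES}

    canal_density = _per_region(spec.canal_density_per_mm3)
    lacuna_density = _per_region(spec.lacuna_density_per_mm3)
    peri_fraction = _per_region(spec.pericanal_fraction)
    peri_multiplier = _per_region(spec.pericanal_multiplier)

    placer = _Placer(spec.min_gap_um)
    label_values = np.zeros(spec.shape, dtype=np.int32)
    rows: list[dict] = []
    next_label = 1

    def _sample_wall_point() -> tuple[float, float]:
        j, i = wall_pixels[rng.integers(len(wall_pixels))]
        return (
            (j + rng.uniform(-0.5, 0.5)) * vs,
            (i + rng.uniform(-0.5, 0.5)) * vs,
        )

    # --- canals (straight z tubes, full stack length) -------------------
    canal_params: list[tuple[float, float, float, str]] = []  # y, x, r, region
    for region in REGION_NAMES:
        n_target = int(round(canal_density[region] * region_vol_mm3[region]))
        for _ in range(n_target):
            for attempt in range(spec.max_attempts):
                y_um, x_um = _sample_wall_point()
                r_c = float(rng.uniform(*spec.canal_radius_um))
                if region_of_point(x_um / vs, y_um / vs, nx) != region:
                    continue
                if radial_margin(y_um, x_um) <= r_c + spec.canal_surface_margin_um:
                    continue
                if not placer.canal_clear(y_um, x_um, r_c):
                    continue
                break
            else:
                raise RuntimeError(
                    f"could not place canal #{len(canal_params) + 1} in region "
                    f"{region!r} after {spec.max_attempts} attempts: "
                    "canal stratum over-constrained"
                )
            placer.add_canal(y_um, x_um, r_c)
            canal_params.append((y_um, x_um, r_c, region))
            disc = np.hypot(yy * vs - y_um, xx * vs - x_um) <= r_c
            label_values[:, disc] = next_label
            rows.append(
                {
                    "label": next_label,
                    "kind": "canal",
                    "cz_um": (nz - 1) / 2.0 * vs,
                    "cy_um": y_um,
                    "cx_um": x_um,
                    "volume_um3": float(np.pi * r_c**2 * length_um),
                    "raster_voxels": int(disc.sum()) * nz,
                    "region": region,
                    "canal_radius_um": r_c,
                    "d_canal_um": np.nan,
                    "d_surface_um": np.nan,
                    "association": None,
                }
            )
            next_label += 1

    # --- lacunae --------------------------------------------------------
    lacuna_voxel_sets: list[tuple[int, tuple[np.ndarray, ...]]] = []
    for region in REGION_NAMES:
        n_total = int(round(lacuna_density[region] * region_vol_mm3[region]))
        region_canals = [c for c in canal_params if c[3] == region]
        n_peri = int(round(peri_fraction[region] * n_total)) if region_canals else 0
        for k in range(n_total):
            peri = k < n_peri
            mult = peri_multiplier[region] if peri else 1.0
            stratum = f"{region}/{'peri-canal' if peri else 'baseline'}"
            for attempt in range(spec.max_attempts):
                vol = _truncated_lognormal(
                    rng,
                    spec.lacuna_volume_median_um3,
                    spec.lacuna_volume_sigma_log,
                    spec.lacuna_volume_bounds_um3,
                    mult,
                )
                r_eq = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
                q1, q2 = rng.uniform(1.0, spec.lacuna_max_aspect, size=2)
                axes = r_eq * np.array([q1, q2, 1.0]) / (q1 * q2) ** (1.0 / 3.0)
                a_max = float(axes.max())
                rot = _random_rotation(rng)
                if peri:
                    cyl_y, cyl_x, cyl_r, _ = region_canals[
                        rng.integers(len(region_canals))
                    ]
                    u = rng.uniform(spec.min_gap_um, spec.pericanal_distance_um)
                    phi = rng.uniform(0.0, 2.0 * np.pi)
                    axis_dist = cyl_r + a_max + u
                    y_um = cyl_y + axis_dist * np.sin(phi)
                    x_um = cyl_x + axis_dist * np.cos(phi)
                else:
                    y_um, x_um = _sample_wall_point()
                z_lo, z_hi = a_max + vs, length_um - vs - a_max - vs
                if z_hi <= z_lo:
                    continue
                z_um = rng.uniform(z_lo, z_hi)
                if region_of_point(x_um / vs, y_um / vs, nx) != region:
                    continue
                if radial_margin(y_um, x_um) <= a_max + spec.lacuna_surface_margin_um:
                    continue
                centre = np.array([z_um, y_um, x_um])
                if not placer.canal_clear(y_um, x_um, a_max):
                    continue
                if not placer.sphere_clear(centre, a_max):
                    continue
                idx = rasterize_ellipsoid(centre, axes, rot, spec.shape, vs)
                raster_vol = len(idx[0]) * vs**3
                if not (25.0 <= raster_vol <= 2500.0):
                    continue  # voxelisation crossed a class boundary: redraw
                if peri:
                    # the peri-canal stratum is canal-associated by
                    # construction: every voxel must be clearly nearer a
                    # canal wall than the endosteal/periosteal surface
                    py, px = idx[1] * vs, idx[2] * vs
                    rad_v = np.hypot(py - cy_um, px - cx_um)
                    r_in_v = np.where(
                        (py < half_y * vs) & (px < half_x * vs),
                        r_out - wall * spec.posterior_thickening,
                        r_in_uniform,
                    )
                    d_surf_v = float(np.minimum(rad_v - r_in_v, r_out - rad_v).min())
                    d_can_v = min(
                        float((np.hypot(py - cy, px - cx) - cr).min())
                        for cy, cx, cr, _ in canal_params
                    )
                    if d_can_v + 4.0 > d_surf_v:
                        continue
                break
            else:
                raise RuntimeError(
                    f"could not place lacuna #{k + 1} in stratum {stratum!r} "
                    f"after {spec.max_attempts} attempts"
                )
            placer.add_sphere(centre, a_max)
            label_values[idx] = next_label
            lacuna_voxel_sets.append((next_label, idx))
            rows.append(
                {
                    "label": next_label,
                    "kind": "lacuna",
                    "cz_um": z_um,
                    "cy_um": y_um,
                    "cx_um": x_um,
                    "volume_um3": float(4.0 / 3.0 * np.pi * np.prod(axes)),
                    "raster_voxels": len(idx[0]),
                    "region": region,
                    "canal_radius_um": np.nan,
                    "d_canal_um": np.nan,  # filled below
                    "d_surface_um": np.nan,
                    "association": None,
                }
            )
            next_label += 1

    # --- noise specks ---------------------------------------------------
    face_offsets = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    for k in range(spec.noise_count):
        for attempt in range(spec.max_attempts):
            y_um, x_um = _sample_wall_point()
            if radial_margin(y_um, x_um) <= spec.noise_margin_um:
                continue
            z = int(rng.integers(2, nz - 2))
            size = int(rng.integers(1, 4))
            centre = np.array([z * vs, y_um, x_um])
            speck_r = 2.0 * vs  # conservative bounding sphere
            if not placer.canal_clear(y_um, x_um, speck_r):
                continue
            if not placer.sphere_clear(centre, speck_r):
                continue
            break
        else:
            raise RuntimeError(
                f"could not place noise speck #{k + 1} after "
                f"{spec.max_attempts} attempts: noise stratum over-constrained"
            )
        placer.add_sphere(centre, speck_r)
        base = np.array([z, int(round(y_um / vs)), int(round(x_um / vs))])
        voxels = [base]
        if size > 1:
            for d in rng.choice(6, size=size - 1, replace=False):
                voxels.append(base + face_offsets[d])
        vox = np.array(voxels)
        idx = (vox[:, 0], vox[:, 1], vox[:, 2])
        label_values[idx] = next_label
        rows.append(
            {
                "label": next_label,
                "kind": "noise",
                "cz_um": float(vox[:, 0].mean()) * vs,
                "cy_um": float(vox[:, 1].mean()) * vs,
                "cx_um": float(vox[:, 2].mean()) * vs,
                "volume_um3": size * vs**3,
                "raster_voxels": size,
                "region": region_of_point(x_um / vs, y_um / vs, nx),
                "canal_radius_um": np.nan,
                "d_canal_um": np.nan,
                "d_surface_um": np.nan,
                "association": None,
            }
        )
        next_label += 1

    # --- analytic truth distances for lacunae ---------------------------
    use_analytic_surface = spec.posterior_thickening == 1.0
    if not use_analytic_surface:
        clean_wall3d = np.broadcast_to(wall2d, spec.shape)
        surf_edt = ndi.distance_transform_edt(clean_wall3d, sampling=vs)
    truth = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    for label, idx in lacuna_voxel_sets:
        pz, py, px = (idx[0] * vs, idx[1] * vs, idx[2] * vs)
        rad = np.hypot(py - cy_um, px - cx_um)
        if use_analytic_surface:
            d_surface = float(np.minimum(rad - r_in_uniform, r_out - rad).min())
        else:
            d_surface = float(surf_edt[idx].min())
        if canal_params:
            d_canal = min(
                float((np.hypot(py - cy, px - cx) - cr).min())
                for cy, cx, cr, _ in canal_params
            )
        else:
            d_canal = np.inf
        i = truth.index[truth["label"] == label][0]
        truth.loc[i, "d_canal_um"] = max(d_canal, 0.0)
        truth.loc[i, "d_surface_um"] = max(d_surface, 0.0)
        truth.loc[i, "association"] = (
            "canal-associated" if d_canal < d_surface else "surface-associated"
        )

    # --- invariants -----------------------------------------------------
    canal_rows = truth[truth["kind"] == "canal"]
    if len(canal_rows) and not (canal_rows["volume_um3"] > 2500.0).all():
        raise AssertionError("a planted canal has analytic volume ≤ 2500 µm³")
    lac_rows = truth[truth["kind"] == "lacuna"]
    if len(lac_rows):
        raster_vols = lac_rows["raster_voxels"] * vs**3
        if not ((raster_vols >= 25.0) & (raster_vols <= 2500.0)).all():
            raise AssertionError("a planted lacuna rasterised outside [25, 2500] µm³")
    noise_rows = truth[truth["kind"] == "noise"]
    if len(noise_rows) and not (noise_rows["volume_um3"] < 25.0).all():
        raise AssertionError("a planted noise speck reaches 25 µm³")

    # --- greyscale rendering -------------------------------------------
    wall3d = np.broadcast_to(wall2d, spec.shape)
    bone3d = wall3d & (label_values == 0)
    grey = np.where(bone3d, spec.bone_grey, spec.pore_grey).astype(np.float64)
    grey += rng.normal(0.0, spec.grey_sd, size=spec.shape)
    grey = np.clip(np.rint(grey), 0, 255).astype(np.uint8)

    greyscale = VoxelVolume(grey, vs, "greyscale")
    label_volume = VoxelVolume(label_values, vs, "labels")
    return greyscale, PhantomTruth(objects=truth, label_volume=label_volume, spec=spec)


def wt_like_spec(seed: int = 0, shape: tuple[int, int, int] = (200, 256, 256),
                 **overrides) -> PhantomSpec:
    """WT-like scenario: posterior-dominant canals, enlarged peri-canal lacunae.

    Canal density 500 mm⁻³ posterior vs 170 mm⁻³ elsewhere (the ~3:1
    regional contrast measured in healthy murine cortex, scaled to the
    desk-size wall); 30% of posterior lacunae (15% elsewhere) form the
    peri-canal, canal-associated stratum, with a ×2 volume multiplier in
    the posterior stratum only — reproducing the ~40% vs ~20% regional
    canal-association fractions and the enlarged posterior canal-associated
    lacunae of healthy bone.
    """
    params = dict(
        shape=shape,
        canal_density_per_mm3={"posterior": 500.0, "lateral": 170.0,
                               "medial": 170.0, "anterior": 170.0},
        lacuna_density_per_mm3=15_000.0,
        pericanal_fraction={"posterior": 0.30, "lateral": 0.15,
                            "medial": 0.15, "anterior": 0.15},
        pericanal_multiplier={"posterior": 2.0, "lateral": 1.0,
                              "medial": 1.0, "anterior": 1.0},
        noise_count=150,
        preset="wt",
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def ko_like_spec(seed: int = 0, shape: tuple[int, int, int] = (200, 256, 256),
                 **overrides) -> PhantomSpec:
    """KO-like scenario: uniformly hyper-vascularised, no volume coupling.

    Canal density 600 mm⁻³ in every region (above the WT non-posterior
    level, as in the hyper-porous knockout cortex) and peri-canal
    multiplier 1 everywhere — the regional structure of the WT preset is
    erased, as in a bone-specific VEGF knockout.
    """
    params = dict(
        shape=shape,
        canal_density_per_mm3=600.0,
        lacuna_density_per_mm3=15_000.0,
        pericanal_fraction=0.15,
        pericanal_multiplier=1.0,
        noise_count=150,
        preset="ko",
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)
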