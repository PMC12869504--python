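"""Distance maps, minimum lacunar distances, bins and the association filter."""

import numpy as np
import pandas as pd
import pytest

import cortimap as cm
from cortimap.distances import ASSOCIATION_TOL_UM
from cortimap.volume import VoxelVolume

VS = 1.65


def _mask(values):
    return VoxelVolume(np.asarray(values, np.uint8), VS, "mask")


def _brute_force_sq_voxel_distances(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: squared voxel distance to the nearest background
    voxel centre, via a KD-tree over background coordinates."""
    from scipy.spatial import cKDTree

    out = np.zeros(mask.shape, dtype=np.int64)
    bg = np.argwhere(~mask)
    fg = np.argwhere(mask)
    if len(fg) == 0 or len(bg) == 0:
        return out
    d, _ = cKDTree(bg).query(fg)
    out[tuple(fg.T)] = np.rint(d**2).astype(np.int64)
    return out


class TestDistanceMap:
    def test_face_adjacent_voxel_is_one_voxel_away(self):
        values = np.zeros((3, 3, 3), np.uint8)
        values[1, 1, 1] = values[1, 1, 2] = 1
        dist = cm.distance_map(_mask(values))
        assert dist.values[1, 1, 1] == pytest.approx(VS)

    def test_diagonal_offset_distance(self):
        # single in-domain voxel whose nearest background is at offset (0,1,1)
        values = np.ones((1, 3, 3), np.uint8)
        values[0, 0, 0] = 0
        dist = cm.distance_map(_mask(values))
        assert dist.values[0, 1, 1] == pytest.approx(np.sqrt(2) * VS)

    @pytest.mark.parametrize("radius", [4, 7, 10])
    def test_ball_centre_distance(self, radius):
        n = 2 * radius + 5
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        c = n // 2
        ball = (np.hypot(np.hypot(zz - c, yy - c), xx - c) <= radius).astype(np.uint8)
        dist = cm.distance_map(_mask(ball))
        assert dist.values[c, c, c] == pytest.approx(radius * VS, abs=VS)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((10, 12, 12)) < 0.5
        dist = cm.distance_map(_mask(values.astype(np.uint8)))
        got_sq = np.rint((dist.values / VS) ** 2).astype(np.int64)
        np.testing.assert_array_equal(got_sq, _brute_force_sq_voxel_distances(values))

    def test_degenerate_domains_error(self):
        with pytest.raises(ValueError, match="empty"):
            cm.distance_map(_mask(np.zeros((2, 2, 2))))
        with pytest.raises(ValueError, match="all-foreground"):
            cm.distance_map(_mask(np.ones((2, 2, 2))))


class TestPerforatedCortex:
    def test_no_canals_returns_cortex(self):
        solid = _mask(np.ones((2, 4, 4)))
        empty = _mask(np.zeros((2, 4, 4)))
        out = cm.perforated_cortex(solid, empty)
        np.testing.assert_array_equal(out.values, solid.values)

    def test_domain_shrinks_by_canal_voxel_count(self):
        solid = np.ones((4, 6, 6), np.uint8)
        canal = np.zeros_like(solid)
        canal[:, 2:4, 2:4] = 1  # 16 voxels
        out = cm.perforated_cortex(_mask(solid), _mask(canal))
        assert out.foreground_count() == solid.sum() - 16

    def test_canal_outside_cortex_errors(self):
        solid = np.zeros((2, 4, 4), np.uint8)
        solid[:, :2] = 1
        canal = np.zeros_like(solid)
        canal[0, 3, 3] = 1
        with pytest.raises(ValueError, match="outside"):
            cm.perforated_cortex(_mask(solid), _mask(canal))


class TestPerLacuna:
    def test_min_distance_is_minimum_over_voxels(self):
        dist = _mask(np.zeros((1, 1, 3))).with_values(
            np.array([[[8.2, 4.9, 11.0]]]), "distance"
        )
        idx = (np.array([0, 0, 0]), np.array([0, 0, 0]), np.array([0, 1, 2]))
        assert cm.lacuna_min_distance(idx, dist) == pytest.approx(4.9)
        single = (np.array([0]), np.array([0]), np.array([0]))
        assert cm.lacuna_min_distance(single, dist) == pytest.approx(8.2)

    def test_empty_voxel_set_errors(self):
        dist = _mask(np.zeros((1, 1, 1))).with_values(np.zeros((1, 1, 1)), "distance")
        with pytest.raises(ValueError, match="no voxels"):
            cm.lacuna_min_distance((np.array([]), np.array([]), np.array([])), dist)

    def test_mean_min_distance(self):
        records = pd.DataFrame({"d_ca_incl_um": [10.0, 20.0, 30.0]})
        assert cm.mean_min_distance(records) == pytest.approx(20.0)
        assert cm.mean_min_distance(records.iloc[:1]) == pytest.approx(10.0)
        assert np.isnan(cm.mean_min_distance(records.iloc[:0]))


class TestBinsAndAssociation:
    @pytest.mark.parametrize(
        "minimum,expected",
        [
            (24.0, "[0,25)"),
            (101.0, "[100,inf)"),
            (80.0, "[75,100)"),
            (0.0, "[0,25)"),
            (25.0, "[25,50)"),
        ],
    )
    def test_bin_edges(self, minimum, expected):
        assert cm.bin_distance(minimum) == expected

    def test_negative_minimum_errors(self):
        with pytest.raises(ValueError):
            cm.bin_distance(-1.0)

    def test_association_filter(self):
        assert cm.associate(12.0, 30.0) == "canal"
        assert cm.associate(20.0, 20.0) == "surface"
        assert cm.associate(20.0, 20.0 + ASSOCIATION_TOL_UM / 2) == "surface"
        with pytest.raises(ValueError, match="exceeds"):
            cm.associate(30.0, 12.0)

    def test_summary_arithmetic(self):
        records = pd.DataFrame(
            {
                "region": ["posterior"] * 3,
                "volume_um3": [900.0, 900.0, 400.0],
                "d_ca_incl_um": [10.0, 12.0, 30.0],
                "d_ca_excl_um": [40.0, 50.0, 30.0],
                "bin_ca_incl": ["[0,25)", "[0,25)", "[25,50)"],
                "bin_ca_excl": ["[25,50)", "[50,75)", "[25,50)"],
                "association": ["canal-associated"] * 2 + ["surface-associated"],
            }
        )
        summary = cm.association_summary(records).set_index("scope")
        row = summary.loc["posterior"]
        assert row["pct_canal_associated"] == pytest.approx(100 * 2 / 3)
        assert row["mean_lc_v_canal_assoc_um3"] == pytest.approx(900.0)
        assert row["mean_lc_v_surface_assoc_um3"] == pytest.approx(400.0)
        assert row["mm_lc_d_ca_incl_um"] == pytest.approx(np.mean([10, 12, 30]))
        bin_cols = [c for c in summary.columns if c.startswith("pct_ca_incl_[")]
        assert row[bin_cols].sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_surface_associated_gives_zero_percent(self):
        records = pd.DataFrame(
            {
                "region": ["whole"],
                "volume_um3": [100.0],
                "d_ca_incl_um": [5.0],
                "d_ca_excl_um": [5.0],
                "bin_ca_incl": ["[0,25)"],
                "bin_ca_excl": ["[0,25)"],
                "association": ["surface-associated"],
            }
        )
        summary = cm.association_summary(records, scopes=["whole"])
        assert summary.iloc[0]["pct_canal_associated"] == 0.0


class TestDegenerateAgreement:
    def test_empty_canal_mask_makes_maps_identical(self, small_kwargs):
        """With no canals, Ca.Incl ≡ Ca.Excl and every lacuna is
        surface-associated."""
        kwargs = dict(small_kwargs)
        kwargs["canal_density_per_mm3"] = 0.0
        config = cm.RunConfig(
            phantom_preset="wt", seed=3, orient=False, phantom_overrides=kwargs
        )
        res = cm.run_pipeline(config)
        np.testing.assert_array_equal(res.maps.ca_incl.values, res.maps.ca_excl.values)
        assert (res.distance_records["association"] == "surface-associated").all()


def test_dominance_on_phantom(wt_small_result):
    res = wt_small_result
    inside = res.maps.domain_incl.values.astype(bool)
    assert np.all(
        res.maps.ca_incl.values[inside] <= res.maps.ca_excl.values[inside] + 1e-9
    )
    rec = res.distance_records
    assert (rec["d_ca_incl_um"] <= rec["d_ca_excl_um"] + 1e-9).all()
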