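"""Patch delineation and Landscape Elements metrics against closed forms
and the exhaustive raster oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, box

import raster_oracle
from conftest import grid_to_map, grid_unit
from hnvf import (
    LandCoverFeature,
    LandCoverMap,
    LandscapeUnit,
    clip_to_unit,
    delineate_patches,
    landscape_elements,
    patch_metrics,
    shannon_diversity,
    shannon_evenness,
)

CODES = [f"c{i}" for i in range(6)]


class TestClip:
    def test_inside_unchanged(self, unit_1ha):
        lc = LandCoverMap([LandCoverFeature(box(10, 10, 20, 20), "PP")])
        out = clip_to_unit(lc, unit_1ha)
        assert len(out.features) == 1
        assert out.features[0].geometry.equals(box(10, 10, 20, 20))

    def test_straddling_cut_at_boundary(self, unit_1ha):
        lc = LandCoverMap([LandCoverFeature(box(50, 50, 150, 150), "PP")])
        out = clip_to_unit(lc, unit_1ha)
        # geometric intersection: the 50x50 part inside the unit
        assert out.features[0].geometry.area == pytest.approx(2500.0)

    def test_outside_absent(self, unit_1ha):
        lc = LandCoverMap([LandCoverFeature(box(200, 200, 300, 300), "PP")])
        assert clip_to_unit(lc, unit_1ha).features == []

    def test_empty_intersection_is_empty_map(self, unit_1ha):
        assert clip_to_unit(LandCoverMap([]), unit_1ha).features == []


class TestDelineation:
    def test_disjoint_squares_two_patches(self, unit_1ha):
        lc = LandCoverMap([
            LandCoverFeature(box(0, 0, 10, 10), "PP"),
            LandCoverFeature(box(50, 50, 60, 60), "PP"),
        ])
        assert len(delineate_patches(lc, unit_1ha)) == 2

    def test_edge_adjacent_merge(self, unit_1ha):
        lc = LandCoverMap([
            LandCoverFeature(box(0, 0, 10, 10), "PP"),
            LandCoverFeature(box(10, 0, 20, 10), "PP"),
        ])
        patches = delineate_patches(lc, unit_1ha)
        assert len(patches) == 1
        assert patches[0].area_ha == pytest.approx(0.02)
        assert patches[0].perimeter_m == pytest.approx(60.0)  # shared edge interior

    def test_corner_contact_stays_separate(self, unit_1ha):
        lc = LandCoverMap([
            LandCoverFeature(box(0, 0, 10, 10), "PP"),
            LandCoverFeature(box(10, 10, 20, 20), "PP"),
        ])
        assert len(delineate_patches(lc, unit_1ha)) == 2

    def test_farmland_scope_drops_forest(self, unit_1ha, registry):
        lc = LandCoverMap([
            LandCoverFeature(box(0, 0, 10, 10), "PP"),
            LandCoverFeature(box(20, 0, 30, 10), "BF"),
        ])
        patches = delineate_patches(lc, unit_1ha, "farmland_only", registry)
        assert [p.code for p in patches] == ["PP"]

    def test_merge_invariance(self, unit_1ha):
        """Splitting a patch into two edge-adjacent halves changes no metric."""
        whole = LandCoverMap([LandCoverFeature(box(10, 10, 50, 30), "PP")])
        split = LandCoverMap([
            LandCoverFeature(box(10, 10, 30, 30), "PP"),
            LandCoverFeature(box(30, 10, 50, 30), "PP"),
        ])
        a = landscape_elements(whole, unit_1ha)
        b = landscape_elements(split, unit_1ha)
        for field in ("sdi_p", "sei_p", "np_p", "msi_p", "ed_p"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-6)


class TestShannon:
    @pytest.mark.parametrize(
        "shares, expected",
        [
            ([1.0], 0.0),
            ([0.25] * 4, math.log(4)),
            ([0.7, 0.2, 0.1], -(0.7 * math.log(0.7) + 0.2 * math.log(0.2) + 0.1 * math.log(0.1))),
        ],
    )
    def test_closed_forms(self, shares, expected):
        assert shannon_diversity(shares) == pytest.approx(expected, abs=1e-12)

    def test_empty_vector_error(self):
        with pytest.raises(ValueError, match="no classes"):
            shannon_diversity([])

    def test_unnormalised_shares_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            shannon_diversity([0.5, 0.4])

    def test_evenness_uniform_and_degenerate(self):
        assert shannon_evenness(math.log(4), 4) == pytest.approx(1.0)
        assert shannon_evenness(0.0, 1) == 0.0
        with pytest.raises(ValueError):
            shannon_evenness(1.0, 0)

    def test_three_class_evenness_closed_form(self):
        sdi = shannon_diversity([0.7, 0.2, 0.1])
        assert shannon_evenness(sdi, 3) == pytest.approx(sdi / math.log(3))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12))
    def test_sdi_matches_direct_summation_and_sei_bounded(self, weights):
        shares = np.array(weights) / np.sum(weights)
        direct = -sum(p * math.log(p) for p in shares if p > 1e-12)
        sdi = shannon_diversity(shares)
        assert sdi == pytest.approx(direct, abs=1e-12)
        assert 0.0 <= shannon_evenness(sdi, len(shares)) <= 1.0


class TestPatchMetrics:
    def test_square_closed_form(self, unit_1ha):
        lc = LandCoverMap([LandCoverFeature(box(0, 0, 100, 100), "PP")])
        patches = delineate_patches(lc, unit_1ha)
        np_p, msi_p, ed_p = patch_metrics(patches, unit_1ha)
        assert np_p == 1
        assert msi_p == pytest.approx(400 / (2 * math.sqrt(math.pi * 1e4)), abs=1e-9)
        assert msi_p == pytest.approx(1.128379, abs=1e-6)
        assert ed_p == pytest.approx(400.0)

    def test_circle_msi_approaches_one(self, unit_1ha):
        coarse = Point(50, 50).buffer(30, quad_segs=8)
        fine = Point(50, 50).buffer(30, quad_segs=256)
        unit = unit_1ha
        mk = lambda g: delineate_patches(LandCoverMap([LandCoverFeature(g, "PP")]), unit)
        _, msi_coarse, _ = patch_metrics(mk(coarse), unit)
        _, msi_fine, _ = patch_metrics(mk(fine), unit)
        # polygonal approximations of a disc stay >= 1 and converge to 1
        assert 1.0 <= msi_fine <= msi_coarse
        assert msi_fine == pytest.approx(1.0, abs=1e-4)

    def test_empty_patch_set_warns(self, unit_1ha, caplog):
        assert patch_metrics([], unit_1ha) == (0, 0.0, 0.0)
        assert any("no patches" in r.message for r in caplog.records)

    def test_boundary_exclusion_option(self, unit_1ha):
        lc = LandCoverMap([LandCoverFeature(box(0, 0, 100, 100), "PP")])
        patches = delineate_patches(lc, unit_1ha)
        _, _, ed_incl = patch_metrics(patches, unit_1ha)
        _, _, ed_excl = patch_metrics(patches, unit_1ha, exclude_unit_boundary=True)
        assert ed_incl == pytest.approx(400.0)
        assert ed_excl == pytest.approx(0.0, abs=1e-9)

    def test_raster_shape_index_variant(self, unit_1ha):
        lc = LandCoverMap([LandCoverFeature(box(0, 0, 100, 100), "PP")])
        patches = delineate_patches(lc, unit_1ha)
        _, msi, _ = patch_metrics(patches, unit_1ha, raster_shape_index=True)
        assert msi == pytest.approx(1.0)  # square-normalised: 1 for a square


class TestRasterOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_grid_mosaic_agreement(self, seed):
        """NP and total edge agree exactly with connected-component labelling
        and per-cell edge counting; SDI/SEI within 1e-9."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        k = int(rng.integers(2, 6))
        grid = rng.integers(0, k, size=(n, n))
        cell = 10.0
        lc = grid_to_map(grid, cell, CODES)
        unit = grid_unit(grid, cell)
        patches = delineate_patches(lc, unit)
        np_p, _, ed_p = patch_metrics(patches, unit)
        assert np_p == raster_oracle.patch_count(grid)
        assert sum(p.perimeter_m for p in patches) == raster_oracle.total_perimeter(grid, cell)
        assert ed_p == pytest.approx(raster_oracle.edge_density(grid, cell), rel=1e-12)
        le = landscape_elements(lc, unit)
        sdi, sei = raster_oracle.shannon(grid)
        assert le.sdi_p == pytest.approx(sdi, abs=1e-9)
        assert le.sei_p == pytest.approx(sei, abs=1e-9)


class TestComposition:
    def test_single_class_unit(self, unit_1ha):
        lc = LandCoverMap([LandCoverFeature(box(0, 0, 100, 100), "PP")])
        le = landscape_elements(lc, unit_1ha)
        assert (le.sdi_p, le.sei_p, le.np_p) == (0.0, 0.0, 1)

    def test_checkerboard_equal_shares_even(self, unit_1ha):
        lc = LandCoverMap([
            LandCoverFeature(box(0, 0, 50, 100), "PP"),
            LandCoverFeature(box(50, 0, 100, 100), "BF"),
        ])
        le = landscape_elements(lc, unit_1ha)
        assert le.sei_p == pytest.approx(1.0)

    def test_scope_monotonicity(self, municipality, registry):
        """Farmland-only patches are a subset in count and area."""
        for unit in municipality.units:
            lc = clip_to_unit(municipality.landcover, unit)
            all_p = delineate_patches(lc, unit, "all_classes")
            farm_p = delineate_patches(lc, unit, "farmland_only", municipality.registry)
            assert len(farm_p) <= len(all_p)
            assert sum(p.area_ha for p in farm_p) <= sum(p.area_ha for p in all_p) + 1e-9
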