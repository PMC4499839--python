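"""Cross-section contours, equivalent radii and thickness statistics."""

import numpy as np
import pandas as pd
import pytest

from vesselmorph.centerline import extract_centerline, label_segments, \
    resample_centerline
from vesselmorph.morphometry import (GridConfig, MeasurementError,
                                     equivalent_radius, measure_cross_section,
                                     polygon_area, segment_summary,
                                     wall_thickness_profile)
from vesselmorph.phantom import BranchSpec, PhantomSpec, PlaqueSpec, \
    generate_phantom, occupancy_fields

from conftest import VOX, make_tube_spec


@pytest.fixture(scope="module")
def annulus_50_80():
    """Straight tube, inner radius 50 um, outer 80 um."""
    spec = make_tube_spec(shape=(48, 64, 64), r_in=50.0, wall=30.0,
                          center_vox=(31.5, 31.5), lo_vox=16, hi_vox=32)
    return spec


class TestCrossSection:
    def test_annulus_areas_within_two_percent(self, annulus_50_80):
        fields = occupancy_fields(annulus_50_80, supersample=6)
        c = 31.5 * VOX
        cs = measure_cross_section(fields, np.array([24 * VOX, c, c]),
                                   np.array([1.0, 0, 0]),
                                   GridConfig(half_width_um=160))
        assert abs(cs.inner_area_um2 - np.pi * 50 ** 2) / (np.pi * 50 ** 2) \
            < 0.02
        assert abs(cs.outer_area_um2 - np.pi * 80 ** 2) / (np.pi * 80 ** 2) \
            < 0.02

    @pytest.mark.parametrize("r_vox", [3.0, 4.0])
    def test_small_radii_within_two_percent(self, r_vox):
        spec = make_tube_spec(shape=(48, 64, 64), r_in=r_vox * VOX,
                              wall=30.0, center_vox=(31.5, 31.5),
                              lo_vox=16, hi_vox=32)
        fields = occupancy_fields(spec, supersample=6)
        c = 31.5 * VOX
        cs = measure_cross_section(fields, np.array([24 * VOX, c, c]),
                                   np.array([1.0, 0, 0]),
                                   GridConfig(half_width_um=160))
        r_true = r_vox * VOX
        assert abs(cs.r_in_um - r_true) / r_true < 0.02
        assert abs(cs.r_out_um - (r_true + 30.0)) / (r_true + 30.0) < 0.02

    def test_tilted_tube_perpendicular_plane(self):
        # tube at 30 degrees to the grid; plane built against the true
        # tangent must recover the same circular areas
        d = np.array([np.cos(np.pi / 6), np.sin(np.pi / 6), 0.0])
        p0 = np.array([90.0, 120.0, 240.0])
        p1 = p0 + d * 500.0
        spec = PhantomSpec(shape=(90, 64, 64),
                           branches=[BranchSpec(np.vstack([p0, p1]),
                                                40.0, 30.0)],
                           voxel_size_um=VOX)
        fields = occupancy_fields(spec, supersample=6)
        mid = (p0 + p1) / 2
        cs = measure_cross_section(fields, mid, d,
                                   GridConfig(half_width_um=140))
        assert abs(cs.inner_area_um2 - np.pi * 40 ** 2) / (np.pi * 40 ** 2) \
            < 0.02

    def test_point_in_parenchyma_flagged(self, tube_bundle, tube_axis_um):
        p = tube_axis_um[0] + np.array([300.0, 150.0, 0.0])  # off-axis
        with pytest.raises(MeasurementError):
            measure_cross_section(tube_bundle.truth_labels, p,
                                  np.array([1.0, 0, 0]))

    def test_half_width_too_small_flagged(self, tube_bundle, tube_axis_um):
        p = tube_axis_um[0] + np.array([300.0, 0.0, 0.0])
        with pytest.raises(MeasurementError, match="border"):
            measure_cross_section(tube_bundle.truth_labels, p,
                                  np.array([1.0, 0, 0]),
                                  GridConfig(half_width_um=60.0))

    def test_basis_choice_invariant(self, tube_bundle, tube_axis_um):
        # areas must not depend on the arbitrary in-plane basis; compare
        # tangents that trigger different Gram-Schmidt seed axes
        p = tube_bundle.spec.branches[0].points_um.mean(axis=0)
        a = measure_cross_section(tube_bundle.truth_labels, p,
                                  np.array([1.0, 1e-9, 0.0]))
        b = measure_cross_section(tube_bundle.truth_labels, p,
                                  np.array([1.0, 0.0, 1e-9]))
        assert a.inner_area_um2 == pytest.approx(b.inner_area_um2, rel=1e-3)


class TestPolygonArea:
    def test_unit_square(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert polygon_area(sq) == pytest.approx(1.0)

    def test_orientation_invariance(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert polygon_area(sq[::-1]) == pytest.approx(1.0)

    def test_regular_64gon_closed_form(self):
        n, r = 64, 10.0
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
        expect = 0.5 * n * r ** 2 * np.sin(2 * np.pi / n)
        assert polygon_area(poly) == pytest.approx(expect, rel=1e-9)

    def test_degenerate_contour_zero_with_flag(self):
        with pytest.warns(UserWarning):
            assert polygon_area(np.array([[0.0, 0], [1, 1]])) == 0.0


class TestEquivalentRadius:
    @pytest.mark.parametrize("area,r", [(np.pi, 1.0), (0.0, 0.0),
                                        (np.pi * 50 ** 2, 50.0)])
    def test_inverts_circle_area(self, area, r):
        assert equivalent_radius(area) == pytest.approx(r, abs=1e-12)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            equivalent_radius(-1.0)


class TestThicknessProfile:
    def _profile(self, bundle, axis, **grid_kw):
        tree = extract_centerline(bundle.truth_labels.mask("lumen"), VOX,
                                  root_seed_um=axis[0] + [VOX, 0, 0])
        sam = label_segments(resample_centerline(tree))
        return wall_thickness_profile(bundle.truth_labels, sam,
                                      GridConfig(**grid_kw))

    def test_mean_within_one_voxel(self, tube_bundle, tube_axis_um):
        prof = self._profile(tube_bundle, tube_axis_um, half_width_um=130)
        ok = prof[prof.flag == ""]
        assert len(ok) > 10
        assert abs(ok.thickness_um.mean() - 30.0) <= VOX

    def test_supersampled_fields_within_half_voxel(self, tube_spec,
                                                   tube_axis_um):
        fields = occupancy_fields(tube_spec, supersample=4)
        bundle = generate_phantom(tube_spec)
        tree = extract_centerline(bundle.truth_labels.mask("lumen"), VOX,
                                  root_seed_um=tube_axis_um[0] + [VOX, 0, 0])
        sam = label_segments(resample_centerline(tree))
        prof = wall_thickness_profile(fields, sam,
                                      GridConfig(half_width_um=130))
        ok = prof[prof.flag == ""]
        assert abs(ok.thickness_um.mean() - 30.0) <= 0.5 * VOX

    def test_constant_thickness_sd_below_discretization(self, tube_bundle,
                                                        tube_axis_um):
        prof = self._profile(tube_bundle, tube_axis_um, half_width_um=130)
        ok = prof[prof.flag == ""]
        assert ok.thickness_um.std(ddof=1) <= VOX

    def test_focal_plaque_located(self):
        spec = make_tube_spec(shape=(140, 64, 64), lo_vox=12, hi_vox=128)
        spec.plaques = [PlaqueSpec(branch=0, arc_start_um=400.0,
                                   arc_stop_um=600.0,
                                   extra_thickness_um=20.0)]
        b = generate_phantom(spec)
        axis = spec.branches[0].points_um
        tree = extract_centerline(b.truth_labels.mask("lumen"), VOX,
                                  root_seed_um=axis[0] + [VOX, 0, 0])
        sam = label_segments(resample_centerline(tree))
        prof = wall_thickness_profile(b.truth_labels, sam,
                                      GridConfig(half_width_um=140))
        ok = prof[prof.flag == ""]
        peak_arc = ok.loc[ok.thickness_um.idxmax(), "arc_um"]
        # extraction clips ~1 voxel at the root, allow half a step of slack
        assert 400.0 - 22.2 <= peak_arc + 2 * VOX <= 600.0 + 22.2 + 2 * VOX

    def test_empty_centerline_empty_profile(self, tube_bundle):
        from vesselmorph.centerline import SampledCenterline

        empty = SampledCenterline(
            points_um=np.empty((0, 3)), tangents=np.empty((0, 3)),
            branch_id=np.empty(0, int), arc_um=np.empty(0),
            depth=np.empty(0, int), step_um=22.2, branch_lengths={})
        prof = wall_thickness_profile(tube_bundle.truth_labels, empty)
        assert prof.empty


class TestSegmentSummary:
    def test_hand_computed_mean_and_sd(self):
        prof = pd.DataFrame({
            "branch_id": 0, "arc_um": [0.0, 22.2, 44.4],
            "segment_class": "proximal main",
            "r_in_um": 50.0, "r_out_um": 70.0,
            "thickness_um": [20.0, 22.0, 24.0], "flag": ""})
        out = segment_summary(prof, min_n=3)
        assert out.loc[0, "mean_um"] == pytest.approx(22.0)
        assert out.loc[0, "sd_um"] == pytest.approx(2.0)
        assert not out.loc[0, "low_n"]

    def test_low_n_flagged(self):
        prof = pd.DataFrame({
            "branch_id": 0, "arc_um": [0.0], "segment_class": "mid main",
            "r_in_um": 1.0, "r_out_um": 2.0, "thickness_um": [10.0],
            "flag": ""})
        out = segment_summary(prof, min_n=100)
        assert bool(out.loc[0, "low_n"])

    def test_flagged_rows_excluded_and_counts_partition(self):
        prof = pd.DataFrame({
            "branch_id": 0, "arc_um": np.arange(6) * 22.2,
            "segment_class": ["proximal main"] * 3 + ["distal main"] * 3,
            "r_in_um": 1.0, "r_out_um": 2.0,
            "thickness_um": [10.0, 11.0, 99.0, 20.0, 21.0, 22.0],
            "flag": ["", "", "bad contour", "", "", ""]})
        out = segment_summary(prof, min_n=2)
        assert out["n"].sum() == 5
        prox = out[out.segment_class == "proximal main"].iloc[0]
        assert prox["n"] == 2 and prox["mean_um"] == pytest.approx(10.5)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            segment_summary(pd.DataFrame())

    def test_all_flagged_warns_empty(self):
        prof = pd.DataFrame({
            "branch_id": 0, "arc_um": [0.0], "segment_class": "mid main",
            "r_in_um": np.nan, "r_out_um": np.nan, "thickness_um": [np.nan],
            "flag": ["no contour"]})
        with pytest.warns(UserWarning):
            out = segment_summary(prof)
        assert out.empty
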