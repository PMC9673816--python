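"""Sensor designs, needle-fit constraint, and voxelization tests."""

import math

import numpy as np
import pytest

from glucolux.geometry import (
    MEDIA,
    Cuboid,
    Cylinder,
    GeometryError,
    Placement,
    PlacementError,
    RodBundle,
    SensorDesign,
    build_design,
    default_design,
    needle_fit,
    rasterize,
    tissue_scene,
)


class TestBuildDesign:
    def test_optimized_stacked_cylinder_has_12_domains(self):
        # 4.3-mm sensor with 0.36-mm repeating units -> 12 domains, 6/assay
        d = build_design("stacked_cylinder", 4.3, unit_thickness=0.36,
                         cross_section=Cylinder(1.0))
        assert d.n_units_total == 12
        assert d.n_units_per_assay == 6

    def test_current_barcode_coarsest_split(self):
        d = build_design("rect_barcode", 6.5, unit_thickness=3.25)
        assert d.n_units_total == 2
        assert d.n_units_per_assay == 1

    def test_fifteen_units_per_assay_thickness(self):
        d = build_design("rect_barcode", 6.5, n_units_per_assay=15)
        assert d.unit_thickness == pytest.approx(6.5 / 30, abs=1e-9)
        assert d.unit_thickness == pytest.approx(0.2167, abs=5e-4)

    def test_unit_thickness_must_tile_length(self):
        with pytest.raises(GeometryError, match="divide"):
            build_design("rect_barcode", 6.5, unit_thickness=1.7)

    def test_needle_violation_names_dimension(self):
        with pytest.raises(GeometryError, match="needle"):
            build_design("stacked_cylinder", 6.5, unit_thickness=0.65,
                         cross_section=Cylinder(1.3))

    def test_rod_design_spans_full_length(self):
        d = default_design("design3")
        assert isinstance(d.cross_section, RodBundle)
        assert d.unit_thickness == d.total_length
        assert d.n_units_total == 4


class TestNeedleFit:
    @pytest.mark.parametrize(
        "cs,expect",
        [
            (Cylinder(1.0), True),
            (Cuboid(0.7, 0.9), True),   # diagonal ~1.1402 mm
            (Cylinder(1.3), False),
        ],
    )
    def test_circumscribed_diameter_rule(self, cs, expect):
        d = SensorDesign("custom", 6.5, cs, 6.5, 1)
        assert needle_fit(d, 1.19) is expect

    def test_cuboid_diagonal_value(self):
        assert Cuboid(0.7, 0.9).circumscribed_diameter == pytest.approx(
            math.hypot(0.7, 0.9), rel=1e-12
        )

    def test_four_rod_bundle_circumscribed_diameter(self):
        rb = RodBundle(rod_diameter=0.49, n_rods=4)
        assert rb.circumscribed_diameter == pytest.approx(0.49 * (1 + math.sqrt(2)), rel=1e-12)


class TestRasterize:
    def test_cylinder_volume_close_to_analytic(self, skin_scene):
        d = build_design("stacked_cylinder", 4.3, unit_thickness=0.36,
                         cross_section=Cylinder(1.0))
        out = rasterize(d, Placement(0, 0, 2.0), skin_scene)
        sensor = np.isin(out.labels, [MEDIA["assay1"], MEDIA["assay2"]])
        vol = sensor.sum() * out.voxel_mm**3
        analytic = math.pi * 0.5**2 * 4.3  # 3.377 mm^3
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_zero_length_design_leaves_scene_unchanged(self, skin_scene):
        d = SensorDesign("custom", 0.0, Cylinder(1.0), None, 0)
        out = rasterize(d, Placement(0, 0, 2.0), skin_scene)
        assert np.array_equal(out.labels, skin_scene.labels)

    def test_center_voxel_indices(self, skin_scene):
        d = default_design("design2")
        out = rasterize(d, Placement(0, 0, 2.0), skin_scene)
        nx, ny, _ = out.shape
        assert out.labels[nx // 2, ny // 2, int(2.0 / 0.05)] in (
            MEDIA["assay1"], MEDIA["assay2"],
        )

    def test_compartments_alternate_along_axis(self, skin_scene):
        d = build_design("stacked_cylinder", 4.3, unit_thickness=0.36,
                         cross_section=Cylinder(1.0))
        out = rasterize(d, Placement(0, 0, 2.0), skin_scene)
        nx, ny, _ = out.shape
        row = out.labels[:, ny // 2, int(2.0 / 0.05)]
        run = row[np.isin(row, [MEDIA["assay1"], MEDIA["assay2"]])]
        changes = np.flatnonzero(np.diff(run.astype(int)))
        # 12 compartments -> 11 label changes, each between the two assays
        assert len(changes) == 11

    def test_mirror_symmetry_in_y(self, skin_scene):
        d = default_design("design1")
        plus = rasterize(d, Placement(0, 3.0, 2.0), skin_scene)
        minus = rasterize(d, Placement(0, -3.0, 2.0), skin_scene)
        assert np.array_equal(plus.labels, minus.labels[:, ::-1, :])

    def test_clipped_placement_rejected(self, skin_scene):
        d = default_design("design2")
        with pytest.raises(PlacementError):
            rasterize(d, Placement(6.0, 0, 2.0), skin_scene)
        with pytest.raises(PlacementError):
            rasterize(d, Placement(0, 0, 0.3), skin_scene)

    def test_voxel_refinement_halves_volume_error(self):
        # diameter/center chosen off the voxel lattice so the surface does
        # not align with voxel boundaries (the generic convergence case)
        d = build_design("stacked_cylinder", 2.0, n_units_per_assay=1,
                         cross_section=Cylinder(0.87))
        analytic = math.pi * 0.435**2 * 2.0
        errs = []
        for h in (0.05, 0.025):
            scene = tissue_scene(extent_mm=(4.0, 4.0, 4.0), voxel_mm=h)
            out = rasterize(d, Placement(0.0, 0.013, 2.017), scene)
            vol = np.isin(out.labels, [MEDIA["assay1"], MEDIA["assay2"]]).sum() * h**3
            errs.append(abs(vol - analytic) / analytic)
        assert errs[1] <= errs[0] / 2 + 1e-3


def test_tissue_scene_layers_follow_depths():
    scene = tissue_scene()
    z = scene.axis_centers("z")
    col = scene.labels[0, 0, :]
    assert set(col[z < 0.1]) == {MEDIA["epidermis"]}
    assert set(col[(z > 0.1) & (z < 1.6)]) == {MEDIA["dermis"]}
    assert set(col[z > 1.6]) == {MEDIA["hypodermis"]}


def test_scene_roundtrip(tmp_path):
    from glucolux.geometry import load_scene, save_scene

    scene = tissue_scene(extent_mm=(2.0, 2.0, 1.0), layer_depths=(0.1, 0.6))
    save_scene(scene, tmp_path / "scene.npz")
    back = load_scene(tmp_path / "scene.npz")
    assert np.array_equal(back.labels, scene.labels)
    assert back.voxel_mm == scene.voxel_mm
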