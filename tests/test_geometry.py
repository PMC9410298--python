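"""Vessel domains, transfinite quadrilateral meshing, and mask recovery."""

import numpy as np
import pytest

from hemocoherence.geometry import (
    UM,
    GeometryError,
    Mesh2D,
    MeshingError,
    VesselSegment,
    build_channel_domain,
    mesh_domain,
    mesh_vessel,
    segment_from_mask,
)


def _arc_segment(radius=60.0, width=15.0, sweep=np.pi / 2, n=60):
    theta = np.linspace(0.0, sweep, n)
    centerline = radius * np.column_stack([np.sin(theta), 1 - np.cos(theta)])
    return VesselSegment("arc", centerline, np.full(n, width), 15.0)


class TestVesselSegment:
    def test_straight_factory_matches_nominals(self):
        seg = VesselSegment.straight(17.2, 137.3, 15.0)
        assert seg.nominal_length == pytest.approx(137.3)
        assert seg.nominal_diameter == pytest.approx(17.2)

    def test_invalid_segments_rejected(self):
        with pytest.raises(GeometryError):
            VesselSegment("x", np.array([[0.0, 0.0]]), np.array([5.0]), 1.0)
        with pytest.raises(GeometryError):
            VesselSegment(
                "x", np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([5.0, -1.0]), 1.0
            )

    def test_csv_and_json_round_trip(self, tmp_path):
        seg = _arc_segment()
        seg.to_csv(tmp_path / "seg.csv")
        seg.to_json(tmp_path / "seg.json")
        back_csv = VesselSegment.from_csv(tmp_path / "seg.csv", inlet_velocity=15.0)
        back_json = VesselSegment.from_json(tmp_path / "seg.json")
        np.testing.assert_allclose(back_csv.centerline, seg.centerline)
        np.testing.assert_allclose(back_json.width_profile, seg.width_profile)
        assert back_json.inlet_velocity == 15.0


class TestChannelDomain:
    def test_straight_channel_is_a_rectangle(self):
        seg = VesselSegment.straight(20.0, 100.0, 10.0)
        lower, upper = build_channel_domain(seg)
        np.testing.assert_allclose(lower[:, 1], -10.0 * UM, atol=1e-18)
        np.testing.assert_allclose(upper[:, 1], 10.0 * UM, atol=1e-18)
        assert lower[0, 0] == pytest.approx(0.0)
        assert lower[-1, 0] == pytest.approx(100.0 * UM)

    def test_arc_offsets_are_concentric(self):
        seg = _arc_segment(radius=60.0, width=15.0)
        lower, upper = build_channel_domain(seg)
        # in the rotated frame the circle centre moves; radii are preserved
        for wall, r_expect in ((lower, 67.5), (upper, 52.5)):
            d = np.linalg.norm(np.diff(wall, axis=0), axis=1).sum()
            r = d / (np.pi / 2)  # arc length = r * sweep
            assert r == pytest.approx(r_expect * UM, rel=5e-3)

    def test_taper_halves_outlet(self):
        n = 30
        x = np.linspace(0, 100.0, n)
        seg = VesselSegment(
            "taper", np.column_stack([x, 0 * x]), np.linspace(20.0, 10.0, n), 15.0
        )
        lower, upper = build_channel_domain(seg)
        inlet_h = upper[0, 1] - lower[0, 1]
        outlet_h = upper[-1, 1] - lower[-1, 1]
        assert outlet_h == pytest.approx(inlet_h / 2, rel=1e-9)

    def test_overtight_curvature_rejected(self):
        seg = _arc_segment(radius=10.0, width=25.0)
        with pytest.raises(GeometryError, match="curvature"):
            build_channel_domain(seg)


class TestMeshing:
    def test_rectangle_area_is_exact(self):
        seg = VesselSegment.straight(20.0, 100.0, 10.0)
        mesh = mesh_vessel(seg, 100, 50)
        assert mesh.n_cells == 5000
        assert mesh.total_area == pytest.approx(100.0 * 20.0 * UM * UM, rel=1e-12)

    def test_transverse_refinement_scales_cell_count(self):
        seg = VesselSegment.straight(20.0, 100.0, 10.0)
        m1 = mesh_vessel(seg, 100, 25)
        m2 = mesh_vessel(seg, 100, 50)
        assert m2.n_cells == 2 * m1.n_cells
        dy1 = m1.nodes[0, 1, 1] - m1.nodes[0, 0, 1]
        dy2 = m2.nodes[0, 1, 1] - m2.nodes[0, 0, 1]
        assert dy2 == pytest.approx(dy1 / 2)

    def test_arc_area_matches_analytic_sector(self):
        seg = _arc_segment(radius=60.0, width=15.0)
        mesh = mesh_vessel(seg, 250, 20)
        r_out, r_in = 67.5 * UM, 52.5 * UM
        analytic = 0.25 * np.pi * (r_out**2 - r_in**2)
        assert mesh.total_area == pytest.approx(analytic, rel=1e-3)

    def test_refinement_preserves_total_area(self):
        seg = _arc_segment()
        mesh = mesh_vessel(seg, 120, 12)
        assert mesh.refine().total_area == pytest.approx(mesh.total_area, rel=1e-3)

    def test_inverted_cells_are_reported(self):
        nodes = np.zeros((3, 2, 2))
        nodes[:, :, 0] = [[0], [1], [0.5]]  # folded axial coordinates
        nodes[:, 1, 1] = 1.0
        with pytest.raises(MeshingError, match="cells"):
            Mesh2D(nodes)

    def test_vtk_export_is_well_formed(self, tmp_path):
        mesh = mesh_vessel(VesselSegment.straight(10.0, 40.0, 5.0), 8, 4)
        path = tmp_path / "mesh.vtk"
        mesh.to_vtk(path, cell_data={"p": np.arange(32.0).reshape(8, 4)})
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert f"POINTS {9 * 5} double" in text
        assert "CELL_TYPES 32" in text
        assert "SCALARS boundary_tag double 1" in text
        assert "SCALARS p double 1" in text


class TestMaskRecovery:
    def _rect_mask(self, h_px=20, l_px=200, pad=10):
        mask = np.zeros((h_px + 2 * pad, l_px + 2 * pad), dtype=np.uint8)
        mask[pad : pad + h_px, pad : pad + l_px] = 255
        return mask

    def test_rendered_rectangle_round_trips(self):
        seg = segment_from_mask(self._rect_mask(), pixel_size=1.0)
        assert seg.nominal_diameter == pytest.approx(20.0, rel=0.10)
        assert 130.0 <= seg.nominal_length <= 200.0
        # over the recovered (end-trimmed) extent the domain area matches the
        # rendered rectangle of the same length within 10 percent
        lower, upper = build_channel_domain(seg)
        mesh = mesh_domain(lower, upper, 60, 10)
        expected = seg.nominal_length * 20.0 * UM * UM
        assert mesh.total_area == pytest.approx(expected, rel=0.10)

    def test_empty_mask_rejected(self):
        with pytest.raises(GeometryError, match="foreground"):
            segment_from_mask(np.zeros((32, 32), dtype=np.uint8), 1.0)

    def test_bifurcation_rejected(self):
        mask = np.zeros((120, 120), dtype=np.uint8)
        mask[56:64, 5:60] = 255       # stem
        mask[10:60, 56:64] = 255      # branch up
        mask[60:110, 56:64] = 255     # branch down
        with pytest.raises(GeometryError, match="topology"):
            segment_from_mask(mask, 1.0)

    def test_multiple_components_rejected(self):
        mask = np.zeros((60, 120), dtype=np.uint8)
        mask[10:20, 10:50] = 255
        mask[40:50, 60:110] = 255
        with pytest.raises(GeometryError, match="component"):
            segment_from_mask(mask, 1.0)
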