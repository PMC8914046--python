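"""Mesh primitives: OBJ I/O, validation, area/volume, volume curve."""
import numpy as np
import pytest
import trimesh

from rvstrain import (
    FrameSeries,
    Mesh,
    VolumeCurve,
    enclosed_volume,
    read_obj,
    read_obj_dir,
    read_obj_series,
    surface_area,
    validate_mesh,
    volume_curve,
    write_obj,
    write_obj_series,
)
from rvstrain.errors import MeshValidationError, ObjParseError, SeriesError
from rvstrain.synthetic import MeshCycleParams, generate_mesh_cycle

from conftest import random_rotation


class TestObjIO:
    def test_round_trip_is_bit_exact(self, tmp_path, icosphere4):
        path = tmp_path / "m.obj"
        write_obj(icosphere4, path)
        back = read_obj(path)
        assert np.array_equal(back.vertices, icosphere4.vertices)
        assert np.array_equal(back.faces, icosphere4.faces)

    def test_series_round_trip(self, tmp_path, default_cycle):
        series, _ = default_cycle
        write_obj_series(series, tmp_path / "s")
        back = read_obj_dir(tmp_path / "s")
        assert back.n_frames == series.n_frames
        assert back.subject_id == series.subject_id
        assert np.array_equal(back.frame_times, series.frame_times)
        for a, b in zip(back.frames, series.frames):
            assert np.array_equal(a.vertices, b.vertices)

    def test_quad_faces_are_fan_triangulated(self, tmp_path):
        p = tmp_path / "quad.obj"
        p.write_text(
            "v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nv 0.5 0.5 1\n"
            "f 1 2 3 4\n"  # quad -> 2 triangles
            "f 1 5 2\nf 2 5 3\nf 3 5 4\nf 4 5 1\n"
        )
        mesh = read_obj(p)
        assert mesh.n_faces == 6
        assert np.array_equal(mesh.faces[0], [0, 1, 2])
        assert np.array_equal(mesh.faces[1], [0, 2, 3])
        assert validate_mesh(mesh).closed

    @pytest.mark.parametrize(
        "content, match",
        [
            ("v 0 0\n", "3 coordinates"),
            ("v 0 0 zero\n", "bad vertex"),
            ("v 0 0 0\nf 1 2\n", ">= 3 vertices"),
            ("v 0 0 0\nf 1 2 9\n", "out of range"),
            ("v 0 0 0\nf 0 1 1\n", "1-based"),
            ("vertex 0 0 0\n", "unsupported record"),
        ],
    )
    def test_malformed_records_name_file_and_line(self, tmp_path, content, match):
        p = tmp_path / "bad.obj"
        p.write_text(content)
        with pytest.raises(ObjParseError, match=match) as err:
            read_obj(p)
        assert "bad.obj:" in str(err.value)

    def test_topology_mismatch_names_frame(self, tmp_path, default_cycle):
        series, _ = default_cycle
        d = tmp_path / "s"
        paths = write_obj_series(series, d)
        # rewrite frame 7 with one fewer vertex
        short = Mesh(series.frames[7].vertices[:-1], series.frames[7].faces[:-200])
        lines = [f"v {x} {y} {z}" for x, y, z in short.vertices]
        lines += [f"f {a+1} {b+1} {c+1}" for a, b, c in short.faces]
        paths[7].write_text("\n".join(lines) + "\n")
        with pytest.raises(SeriesError, match="frame 7"):
            read_obj_series(paths)

    def test_open_surface_rejected_with_boundary_edges(self, tmp_path, icosphere4):
        opened = Mesh(icosphere4.vertices, icosphere4.faces[1:])
        d = tmp_path / "s"
        d.mkdir()
        write_obj(opened, d / "f0.obj")
        write_obj(opened, d / "f1.obj")
        with pytest.raises(MeshValidationError, match="boundary edges"):
            read_obj_dir(d)


class TestValidation:
    def test_icosphere_is_closed_and_oriented(self, icosphere4):
        rep = validate_mesh(icosphere4)
        assert rep.closed and rep.oriented and rep.n_degenerate == 0 and rep.ok

    def test_deleting_one_face_opens_three_boundary_edges(self, icosphere4):
        rep = validate_mesh(Mesh(icosphere4.vertices, icosphere4.faces[1:]))
        assert not rep.closed
        assert len(rep.boundary_edges) == 3

    def test_repeated_vertex_index_counts_degenerate(self, icosphere4):
        faces = icosphere4.faces.copy()
        faces[0, 1] = faces[0, 0]
        rep = validate_mesh(Mesh(icosphere4.vertices, faces))
        assert rep.n_degenerate == 1


class TestAreaVolume:
    def test_cube(self, cube_mesh):
        assert surface_area(cube_mesh) == pytest.approx(600.0)
        assert enclosed_volume(cube_mesh) == pytest.approx(1.0)

    def test_icosphere_against_analytic_sphere(self, icosphere4):
        # inscribed polyhedron: slightly below the analytic values
        assert surface_area(icosphere4) == pytest.approx(4 * np.pi * 100, rel=5e-3)
        big = icosphere4.scaled(2.0)  # r = 20 mm
        assert enclosed_volume(big) == pytest.approx(4 / 3 * np.pi * 8000 / 1000, rel=1e-2)

    @pytest.mark.parametrize("s", [0.5, 1.7])
    def test_similarity_scaling_exact(self, icosphere4, s):
        assert surface_area(icosphere4.scaled(s)) == pytest.approx(
            s**2 * surface_area(icosphere4), rel=1e-12
        )
        assert enclosed_volume(icosphere4.scaled(s)) == pytest.approx(
            s**3 * enclosed_volume(icosphere4), rel=1e-12
        )

    def test_rigid_motion_invariance(self, icosphere4):
        r = random_rotation(3)
        moved = Mesh(icosphere4.vertices @ r.T + np.array([4.0, -7.0, 11.0]), icosphere4.faces)
        assert surface_area(moved) == pytest.approx(surface_area(icosphere4), rel=1e-9)
        assert enclosed_volume(moved) == pytest.approx(enclosed_volume(icosphere4), rel=1e-9)

    def test_inverted_winding_is_auto_repaired(self, icosphere4):
        flipped = Mesh(icosphere4.vertices, icosphere4.faces[:, [0, 2, 1]])
        assert enclosed_volume(flipped) == pytest.approx(enclosed_volume(icosphere4))

    def test_open_mesh_volume_is_error(self, icosphere4):
        with pytest.raises(MeshValidationError, match="open mesh"):
            enclosed_volume(Mesh(icosphere4.vertices, icosphere4.faces[1:]))

    def test_voxelization_volume_oracle(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
        mesh = Mesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        assert mesh.n_faces >= 5000
        # independent column-integration oracle: for a grid of vertical rays,
        # sum the inside intervals between surface crossings
        assert enclosed_volume(mesh) == pytest.approx(
            _column_volume_oracle(mesh, pitch=0.8), rel=1e-2
        )


def _column_volume_oracle(mesh: Mesh, pitch: float) -> float:
    """Volume in mL by casting a vertical ray grid and summing inside spans."""
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    lo = mesh.vertices.min(axis=0) - pitch
    hi = mesh.vertices.max(axis=0) + pitch
    xs = np.arange(lo[0] + 0.137 * pitch, hi[0], pitch)  # offset avoids edge hits
    ys = np.arange(lo[1] + 0.271 * pitch, hi[1], pitch)
    a2, b2, c2 = tri[:, 0, :2], tri[:, 1, :2], tri[:, 2, :2]
    det = (b2[:, 0] - a2[:, 0]) * (c2[:, 1] - a2[:, 1]) - (c2[:, 0] - a2[:, 0]) * (
        b2[:, 1] - a2[:, 1]
    )
    ok = np.abs(det) > 1e-14
    total = 0.0
    for x in xs:
        for y in ys:
            px, py = x - a2[:, 0], y - a2[:, 1]
            u = ((c2[:, 1] - a2[:, 1]) * px - (c2[:, 0] - a2[:, 0]) * py) / np.where(ok, det, 1)
            v = (-(b2[:, 1] - a2[:, 1]) * px + (b2[:, 0] - a2[:, 0]) * py) / np.where(ok, det, 1)
            hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
            if not hit.any():
                continue
            z = (
                tri[hit, 0, 2]
                + u[hit] * (tri[hit, 1, 2] - tri[hit, 0, 2])
                + v[hit] * (tri[hit, 2, 2] - tri[hit, 0, 2])
            )
            z = np.sort(z)
            total += (z[1::2] - z[0::2]).sum() * pitch * pitch
    return total / 1000.0


class TestVolumeCurve:
    def _series_with_volumes(self, icosphere4, scales):
        frames = tuple(icosphere4.scaled(s) for s in scales)
        return FrameSeries(frames, np.arange(len(scales), dtype=float))

    def test_ed_es_at_max_min(self, icosphere4):
        vc = volume_curve(self._series_with_volumes(icosphere4, [1.0, 0.9, 0.8, 0.85, 0.95]))
        assert (vc.ed_index, vc.es_index) == (0, 2)
        assert (vc.volumes > 0).all()

    def test_tie_broken_to_earliest_frame(self, icosphere4):
        # constant volumes: both extrema land on frame 0
        vc = volume_curve(self._series_with_volumes(icosphere4, [1.0, 1.0, 1.0]))
        assert (vc.ed_index, vc.es_index) == (0, 0)

    def test_planted_ef_40(self):
        # circ^2 x long = 0.6 leaves ESV = 0.6 x EDV
        params = MeshCycleParams(
            circumferential_scale_es=0.9, longitudinal_scale_es=0.6 / 0.81
        )
        series, truth = generate_mesh_cycle(params)
        vc = volume_curve(series)
        assert truth.ef_pct == pytest.approx(40.0, abs=1e-9)
        assert vc.volumes[vc.es_index] == pytest.approx(0.6 * vc.volumes[vc.ed_index], rel=1e-9)

    def test_to_frame_flags(self, icosphere4):
        vc = volume_curve(self._series_with_volumes(icosphere4, [1.0, 0.8, 0.9]))
        df = vc.to_frame()
        assert df.loc[df.is_ED, "frame"].tolist() == [0]
        assert df.loc[df.is_ES, "frame"].tolist() == [1]


class TestFrameSeriesInvariants:
    def test_needs_two_frames(self, icosphere4):
        with pytest.raises(SeriesError, match=">= 2"):
            FrameSeries((icosphere4,), np.array([0.0]))

    def test_times_strictly_increasing(self, icosphere4):
        with pytest.raises(SeriesError, match="increasing"):
            FrameSeries((icosphere4, icosphere4), np.array([1.0, 1.0]))

    def test_face_list_must_match(self, icosphere4):
        other = Mesh(icosphere4.vertices, icosphere4.faces[::-1])
        with pytest.raises(SeriesError, match="face list"):
            FrameSeries((icosphere4, other), np.array([0.0, 1.0]))
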