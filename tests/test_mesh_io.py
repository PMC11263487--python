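import numpy as np
import pandas as pd
import pytest

from odontomech import ValidationError, mesh_io, synthetic as syn
from odontomech.errors import FormatError
from odontomech.types import LandmarkSet


def _vertex_set(mesh, decimals=5):
    """Order/duplication-independent vertex fingerprint."""
    return np.unique(np.round(mesh.vertices, decimals), axis=0)


class TestMeshRoundTrip:
    @pytest.mark.parametrize("ext", [".ply", ".obj", ".stl"])
    def test_roundtrip_preserves_geometry(self, cone_mesh, tmp_path, ext):
        path = tmp_path / f"tooth{ext}"
        mesh_io.write_mesh(cone_mesh, path)
        back = mesh_io.read_mesh(path, name="tooth")
        assert back.n_faces == cone_mesh.n_faces
        np.testing.assert_allclose(
            _vertex_set(back), _vertex_set(cone_mesh), atol=1e-6)

    def test_ply_roundtrip_is_lossless(self, cone_mesh, tmp_path):
        path = tmp_path / "t.ply"
        mesh_io.write_mesh(cone_mesh, path)
        back = mesh_io.read_mesh(path)
        np.testing.assert_array_equal(back.vertices, cone_mesh.vertices)
        np.testing.assert_array_equal(back.faces, cone_mesh.faces)

    def test_binary_stl_matches_ply_read(self, cone_mesh, tmp_path):
        ply, stl = tmp_path / "t.ply", tmp_path / "t.stl"
        mesh_io.write_mesh(cone_mesh, ply)
        mesh_io.write_mesh(cone_mesh, stl)
        a = _vertex_set(mesh_io.read_mesh(ply))
        b = _vertex_set(mesh_io.read_mesh(stl))
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_degenerate_mesh_rejected(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 3\n"
            "property float x\nproperty float y\nproperty float z\n"
            "element face 1\nproperty list uchar int vertex_indices\n"
            "end_header\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n")
        with pytest.raises(ValidationError):
            mesh_io.read_mesh(path)

    def test_unreadable_file_names_the_file(self, tmp_path):
        path = tmp_path / "junk.ply"
        path.write_text("this is not a mesh")
        with pytest.raises(FormatError, match="junk.ply"):
            mesh_io.read_mesh(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            mesh_io.read_mesh(tmp_path / "nope.stl")


class TestLabelmap:
    @pytest.mark.parametrize("ext", [".nrrd", ".nii.gz"])
    def test_three_blobs_three_meshes(self, tmp_path, ext):
        vol, dirs, origin = syn.make_box_labelmap(n_labels=3, box=2)
        path = tmp_path / f"seg{ext}"
        mesh_io.write_labelmap(path, vol, dirs, origin)
        meshes = mesh_io.read_labelmap(path)
        assert [m.label for m in meshes] == [1, 2, 3]

    def test_single_voxel_is_a_unit_cube(self, tmp_path):
        from odontomech.geometry import surface_area

        vol, dirs, origin = syn.make_box_labelmap(n_labels=1, box=1)
        path = tmp_path / "one.nrrd"
        mesh_io.write_labelmap(path, vol, dirs, origin)
        (mesh,) = mesh_io.read_labelmap(path)
        assert surface_area(mesh) == pytest.approx(6.0, rel=0.10)

    def test_all_zero_volume_yields_empty_list(self, tmp_path):
        vol, dirs, origin = syn.make_box_labelmap(n_labels=0)
        path = tmp_path / "zero.nrrd"
        mesh_io.write_labelmap(path, vol, dirs, origin)
        assert mesh_io.read_labelmap(path) == []

    def test_non_integer_volume_rejected(self, tmp_path):
        vol = np.random.default_rng(0).random((4, 4, 4))
        path = tmp_path / "float.nrrd"
        mesh_io.write_labelmap(path, vol)
        with pytest.raises(ValidationError):
            mesh_io.read_labelmap(path)

    def test_relabeling_permutes_output_only(self, tmp_path):
        vol, dirs, origin = syn.make_box_labelmap(n_labels=3, box=2)
        perm = np.zeros(4, dtype=vol.dtype)
        perm[[1, 2, 3]] = [3, 1, 2]  # 1->3, 2->1, 3->2
        a, b = tmp_path / "a.nrrd", tmp_path / "b.nrrd"
        mesh_io.write_labelmap(a, vol, dirs, origin)
        mesh_io.write_labelmap(b, perm[vol], dirs, origin)
        orig = {m.label: _vertex_set(m) for m in mesh_io.read_labelmap(a)}
        relab = {m.label: _vertex_set(m) for m in mesh_io.read_labelmap(b)}
        for old, new in [(1, 3), (2, 1), (3, 2)]:
            np.testing.assert_allclose(relab[new], orig[old], atol=1e-9)

    def test_spacing_scales_physical_size(self, tmp_path):
        from odontomech.geometry import surface_area

        vol, dirs, origin = syn.make_box_labelmap(n_labels=1, box=1,
                                                  spacing=(2.0, 2.0, 2.0))
        path = tmp_path / "sp.nrrd"
        mesh_io.write_labelmap(path, vol, dirs, origin)
        (mesh,) = mesh_io.read_labelmap(path)
        assert surface_area(mesh) == pytest.approx(24.0, rel=0.10)


class TestLandmarks:
    def test_minimal_json(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text('{"jaw_joint": [0, 0, 0], "jaw_tip": [10, 0, 0]}')
        lm = mesh_io.read_landmarks(path)
        np.testing.assert_array_equal(lm.jaw_tip, [10, 0, 0])

    def test_fcsv_lps_flips_first_two_axes(self, tmp_path):
        fcsv = tmp_path / "lm.fcsv"
        fcsv.write_text(
            "# Markups fiducial file version = 4.11\n"
            "# CoordinateSystem = LPS\n"
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
            "n1,1,2,3,0,0,0,1,1,1,0,jaw_joint,,\n"
            "n2,5,6,7,0,0,0,1,1,1,0,jaw_tip,,\n")
        lm = mesh_io.read_landmarks(fcsv)
        np.testing.assert_allclose(lm.jaw_joint, [-1, -2, 3])

    def test_fcsv_without_header_assumes_lps(self, tmp_path):
        fcsv = tmp_path / "lm.fcsv"
        fcsv.write_text(
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
            "n1,1,2,3,0,0,0,1,1,1,0,jaw_joint,,\n"
            "n2,5,6,7,0,0,0,1,1,1,0,jaw_tip,,\n")
        np.testing.assert_allclose(mesh_io.read_landmarks(fcsv).jaw_joint, [-1, -2, 3])

    def test_fcsv_ras_matches_json(self, tmp_path):
        fcsv = tmp_path / "lm.fcsv"
        fcsv.write_text(
            "# CoordinateSystem = RAS\n"
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
            "n1,1,2,3,0,0,0,1,1,1,0,jaw_joint,,\n"
            "n2,5,6,7,0,0,0,1,1,1,0,jaw_tip,,\n")
        js = tmp_path / "lm.json"
        js.write_text('{"jaw_joint": [1, 2, 3], "jaw_tip": [5, 6, 7]}')
        assert mesh_io.read_landmarks(fcsv) == mesh_io.read_landmarks(js)

    def test_missing_required_landmark_lists_it(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text('{"jaw_tip": [10, 0, 0]}')
        with pytest.raises(ValidationError, match="jaw_joint"):
            mesh_io.read_landmarks(path)

    def test_orphan_origin_rejected(self):
        with pytest.raises(ValidationError, match="origin_2"):
            LandmarkSet(points={"jaw_joint": [0, 0, 0], "jaw_tip": [9, 0, 0],
                                "origin_2": [1, 1, 1]})

    @pytest.mark.parametrize("ext", [".fcsv", ".json"])
    def test_roundtrip_is_identity(self, tmp_path, ext):
        lm = LandmarkSet(points={
            "jaw_joint": [0.25, -1.5, 3.0], "jaw_tip": [12.5, 0.125, -0.5],
            "insertion_1": [2.0, 0.5, 1.5], "origin_1": [1.0, 4.0, 5.0]})
        p1, p2 = tmp_path / f"a{ext}", tmp_path / f"b{ext}"
        mesh_io.write_landmarks(lm, p1)
        back = mesh_io.read_landmarks(p1)
        mesh_io.write_landmarks(back, p2)
        again = mesh_io.read_landmarks(p2)
        assert back == lm
        assert again == back


class TestTraitsTable:
    def _records(self, n=5, names=None):
        from odontomech.biomechanics import ToothTraits

        names = names or [f"T{i}" for i in range(n)]
        return [
            ToothTraits(name=names[i], jaw_length=20.0, position=2.0 + i,
                        out_lever=3.0 + i, in_levers={"m1": 2.0},
                        mechanical_advantage={"m1": 2.0 / (3.0 + i)},
                        force=2.0 / (3.0 + i), stress=0.1 * (i + 1),
                        height=2.0, width=1.0, aspect_ratio=2.0,
                        surface_area=4.0, tip=np.array([1.0, 2.0, 3.0]),
                        base=np.array([1.0, 2.0, 1.0]))
            for i in range(n)
        ]

    def test_row_per_tooth(self, tmp_path):
        path = tmp_path / "traits.csv"
        mesh_io.write_traits_table(self._records(5), path)
        assert len(pd.read_csv(path)) == 5

    def test_numeric_roundtrip(self, tmp_path):
        recs = self._records(4)
        path = tmp_path / "traits.csv"
        mesh_io.write_traits_table(recs, path)
        df = mesh_io.read_traits_table(path)
        for i, r in enumerate(recs):
            assert df.loc[i, "force"] == pytest.approx(r.force, abs=1e-9)
            assert df.loc[i, "stress"] == pytest.approx(r.stress, abs=1e-9)
            assert df.loc[i, "tip_z"] == pytest.approx(3.0, abs=1e-9)

    def test_comma_in_name_is_quoted(self, tmp_path):
        recs = self._records(2, names=["left, front", "left, back"])
        path = tmp_path / "traits.csv"
        mesh_io.write_traits_table(recs, path)
        df = mesh_io.read_traits_table(path)
        assert list(df["tooth"]) == ["left, front", "left, back"]

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            mesh_io.write_traits_table([], tmp_path / "x.csv")


def test_synthetic_bundle_rereads_exactly(tmp_path, jaw_spec):
    paths = syn.write_jaw_bundle(jaw_spec, tmp_path)
    meshes, landmarks, _ = syn.make_jaw(jaw_spec)
    for mesh, path in zip(meshes, paths["meshes"]):
        back = mesh_io.read_mesh(path)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)
    assert mesh_io.read_landmarks(paths["landmarks_fcsv"]) == landmarks
    assert mesh_io.read_landmarks(paths["landmarks_json"]) == landmarks
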