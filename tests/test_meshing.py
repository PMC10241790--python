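"""Meshing: size field, fluid mesh topology, tags, writers, determinism."""

import math
import os
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from nutbolt.params import ComplexParams
from nutbolt.geometry import build_bodies
from nutbolt.meshing import (GRADATION, SIZE_TABLE, make_size_field,
                             generate_fluid_mesh, mesh_complex)
from nutbolt.benchmarks import sphere_fluid_mesh


@pytest.fixture(scope="module")
def sphere_mesh():
    return sphere_fluid_mesh(a=1.0, outer_radius=20.0, near=0.45, far=5.0,
                             seed=0)


class TestSizeField:
    def test_values_on_fibre_and_far_field(self):
        p = ComplexParams(model=1)
        bodies = build_bodies(p)
        sf = make_size_field(p, 1.0, bodies)
        on_fibre = bodies["fibre"].dense_surface_points(2.0)[:5]
        np.testing.assert_allclose(sf(on_fibre), 0.75, atol=1e-6)
        far = np.array([[5000.0, 0.0, 0.0]])
        assert sf(far)[0] == pytest.approx(50.0)

    def test_scale_doubles_target_sizes(self):
        # target (regional) sizes are exactly linear in scale; in the blend
        # zones the gradation slope is kept scale-free so the per-cell
        # growth ratio stays bounded at every scale
        p = ComplexParams(model=1)
        bodies = build_bodies(p)
        sf1 = make_size_field(p, 1.0, bodies)
        sf2 = make_size_field(p, 2.0, bodies)
        assert sf2.sizes == {k: 2.0 * v for k, v in sf1.sizes.items()}
        on_fibre = bodies["fibre"].dense_surface_points(2.0)[:5]
        np.testing.assert_allclose(sf2(on_fibre), 2.0 * sf1(on_fibre),
                                   rtol=1e-9)
        far = np.array([[5000.0, 0.0, 0.0]])
        np.testing.assert_allclose(sf2(far), 2.0 * sf1(far), rtol=1e-12)

    def test_gradation_bound(self):
        p = ComplexParams(model=1)
        sf = make_size_field(p, 1.0)
        rng = np.random.default_rng(1)
        a = rng.uniform(-200, 200, size=(300, 3))
        b = a + rng.normal(scale=5.0, size=a.shape)
        gap = np.abs(sf(a) - sf(b))
        dist = np.linalg.norm(a - b, axis=1)
        assert np.all(gap <= GRADATION * dist + 1e-9)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            make_size_field(ComplexParams(), 0.0)


class TestSphereFixtureMesh:
    def test_positive_volumes_and_connectivity(self, sphere_mesh):
        vols = sphere_mesh.volumes()
        assert np.all(vols > 0)
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components
        t = sphere_mesh.tets
        i = np.concatenate([t[:, a] for a in range(4) for b in range(4)
                            if a != b])
        j = np.concatenate([t[:, b] for a in range(4) for b in range(4)
                            if a != b])
        g = sp.coo_matrix((np.ones(len(i)), (i, j)),
                          shape=(len(sphere_mesh.vertices),) * 2)
        ncomp, _ = connected_components(g, directed=False)
        assert ncomp == 1

    def test_boundary_is_two_closed_components(self, sphere_mesh):
        # every boundary facet tagged; each tag's facets close up (each edge
        # shared by exactly two facets of the same tag)
        tags = set(sphere_mesh.boundary_tags)
        assert tags == {"sphere", "outer"}
        for tag in tags:
            faces = sphere_mesh.boundary_faces[sphere_mesh.boundary_tags == tag]
            edges = np.sort(np.concatenate([faces[:, [0, 1]],
                                            faces[:, [1, 2]],
                                            faces[:, [0, 2]]]), axis=1)
            _, counts = np.unique(edges, axis=0, return_counts=True)
            assert np.all(counts == 2)

    def test_total_volume_matches_annulus(self, sphere_mesh):
        expected = 4.0 / 3.0 * math.pi * (20.0 ** 3 - 1.0 ** 3)
        assert sphere_mesh.volume_p2() == pytest.approx(expected, rel=0.005)

    def test_boundary_faces_belong_to_exactly_one_tet(self, sphere_mesh):
        key = {tuple(sorted(f)) for f in sphere_mesh.boundary_faces.tolist()}
        assert len(key) == len(sphere_mesh.boundary_faces)

    def test_refinement_never_decreases_cell_count(self):
        coarse = sphere_fluid_mesh(a=1.0, outer_radius=12.0, near=0.8,
                                   far=5.0, seed=0)
        fine = sphere_fluid_mesh(a=1.0, outer_radius=12.0, near=0.4,
                                 far=2.5, seed=0)
        assert fine.n_elements > coarse.n_elements

    def test_quality_metrics_reported(self, sphere_mesh):
        q = sphere_mesh.quality()
        assert q["min_dihedral_deg"] > 0.0
        assert q["max_radius_edge"] < 50.0
        assert q["min_volume"] > 0.0

    def test_outer_radius_too_small_rejected(self):
        from nutbolt.benchmarks import sphere_body, SimpleSizeField
        sf = SimpleSizeField(centre=np.zeros(3), inner_radius=1.0,
                             near=0.5, far=2.0)
        with pytest.raises(ValueError):
            generate_fluid_mesh({"sphere": sphere_body(1.0)}, sf, 1.2)


class TestComplexMesh:
    def test_deterministic_for_fixed_seed(self):
        p = ComplexParams(model=1, L_fib=60.0)
        m1 = mesh_complex(p, scale=8.0, outer_factor=2.0, seed=3)
        m2 = mesh_complex(p, scale=8.0, outer_factor=2.0, seed=3)
        np.testing.assert_array_equal(m1.tets10, m2.tets10)
        np.testing.assert_array_equal(m1.nodes, m2.nodes)

    @pytest.mark.parametrize("L_fl", [124.0, 248.0])
    def test_both_flagellum_lengths_mesh(self, L_fl):
        p = ComplexParams(model=1, L_fl=L_fl, L_fib=60.0)
        m = mesh_complex(p, scale=8.0, outer_factor=2.0, seed=0)
        counts = m.boundary_node_count()
        for tag in ("flagellum", "fibre", "tail", "head", "outer"):
            assert counts[tag] > 10
        assert np.all(m.volumes() > 0)

    def test_every_boundary_face_tagged(self):
        p = ComplexParams(model=2, L_fib=60.0)
        m = mesh_complex(p, scale=8.0, outer_factor=2.0, seed=0)
        assert set(m.boundary_tags) <= {"flagellum", "fibre", "tail", "head",
                                        "outer"}
        assert not np.any(m.boundary_tags == "")


class TestWriters:
    def test_vtu_roundtrip_structure(self, sphere_mesh, tmp_path):
        path = tmp_path / "mesh.vtu"
        sphere_mesh.export_vtu(path, point_data={
            "velocity": np.zeros((sphere_mesh.n_nodes, 3))})
        tree = ET.parse(path)
        piece = tree.getroot().find(".//Piece")
        assert int(piece.get("NumberOfPoints")) == sphere_mesh.n_nodes
        assert int(piece.get("NumberOfCells")) == sphere_mesh.n_elements
        types = piece.find(".//DataArray[@Name='types']").text.split()
        assert set(types) == {"24"}

    def test_msh_volume_structure(self, sphere_mesh, tmp_path):
        path = tmp_path / "mesh.msh"
        sphere_mesh.export_msh(path)
        text = path.read_text()
        assert text.startswith("$MeshFormat\n4.1")
        assert '"sphere"' in text and '"outer"' in text and '"fluid"' in text
        assert "$EndElements" in text

    def test_msh_surface_export(self, tmp_path):
        from nutbolt.geometry import build_scene
        scene = build_scene(ComplexParams(model=1), scale=2.0)
        path = scene.export_msh(tmp_path / "surf.msh")
        text = open(path).read()
        for tag in ("flagellum", "fibre", "tail", "head"):
            assert f'"{tag}"' in text

    def test_stl_export_ascii(self, tmp_path):
        from nutbolt.geometry import build_scene
        scene = build_scene(ComplexParams(model=1), scale=2.0)
        paths = scene.export_stl(tmp_path)
        head = open(paths["head"]).read(80)
        assert head.lstrip().startswith("solid")
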