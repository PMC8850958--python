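"""Mesh construction, revolution volumes, and domain labelling."""

import numpy as np
import pytest

from mwablate.geometry import (AntennaGeometry, MeshResolution, Region,
                               build_coax_segment, build_domain)
from mwablate.mesh import P1Assembler, graded_segment, structured_mesh


class TestMesh:
    def test_graded_segment_hits_endpoint_with_positive_steps(self):
        for h0, h1 in [(0.1, 0.1), (0.05, 0.4), (0.4, 0.05)]:
            x = graded_segment(2.0, 5.0, h0, h1)
            assert x[-1] == pytest.approx(5.0)
            assert np.all(np.diff(np.concatenate([[2.0], x])) > 0)

    def test_structured_mesh_total_area(self):
        mesh = structured_mesh(np.linspace(1, 3, 5), np.linspace(0, 1, 4))
        assert mesh.areas().sum() == pytest.approx(2.0)

    def test_revolved_volume_matches_pappus_exactly(self):
        # annulus r in [r0, r1], height h revolves to pi (r1^2 - r0^2) h
        r0, r1, h = 0.01, 0.03, 0.05
        mesh = structured_mesh(np.linspace(r0, r1, 7), np.linspace(0, h, 9))
        vol = mesh.revolved_volume(np.ones(mesh.n_elements, bool))
        assert vol == pytest.approx(np.pi * (r1**2 - r0**2) * h, rel=1e-12)

    def test_boundary_edges_form_the_rectangle_perimeter(self):
        mesh = structured_mesh(np.linspace(0, 1, 3), np.linspace(0, 2, 4))
        edges = mesh.boundary_edges(np.ones(mesh.n_elements, bool))
        length = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]],
                                axis=1).sum()
        assert length == pytest.approx(2 * (1 + 2))

    def test_p1_gradient_exact_on_linear_fields(self):
        mesh = structured_mesh(np.linspace(1, 2, 4), np.linspace(0, 1, 5))
        asm = P1Assembler(mesh)
        g = asm.gradient(2.0 * mesh.nodes[:, 0] - 3.0 * mesh.nodes[:, 1])
        assert np.allclose(g, [2.0, -3.0])

    def test_mass_matrix_integrates_revolution_measure(self):
        mesh = structured_mesh(np.linspace(0.5, 1.5, 6), np.linspace(0, 1, 6))
        asm = P1Assembler(mesh)
        M = asm.mass(np.ones(mesh.n_elements))
        one = np.ones(mesh.n_nodes)
        assert one @ (M @ one) == pytest.approx(1.0 * 1.0, rel=1e-9)  # int r dA = 1


class TestAntennaGeometry:
    def test_radii_must_increase(self):
        with pytest.raises(ValueError):
            AntennaGeometry(inner_conductor_radius=0.5)

    def test_slot_must_be_inside_inserted_length(self):
        with pytest.raises(ValueError):
            AntennaGeometry(slot_distance_from_tip=70.0)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        g = AntennaGeometry(insertion_depth=60.0)
        path = tmp_path / "antenna.yaml"
        path.write_text(yaml.safe_dump({"insertion_depth": 60.0}))
        assert AntennaGeometry.from_yaml(path) == g


@pytest.fixture(scope="module")
def domain():
    return build_domain(tumor_diameter_mm=20.0)


class TestBuildDomain:
    def test_all_named_boundary_sets_nonempty(self, domain):
        for name in ("port", "exterior", "axis", "cooling", "wall"):
            assert len(domain.mesh.edges[name]) > 0, name

    def test_port_lies_on_the_coax_cross_section(self, domain):
        g = domain.geometry
        nodes = domain.mesh.nodes[np.unique(domain.mesh.edges["port"])]
        assert np.allclose(nodes[:, 1], domain.extents[1])
        assert nodes[:, 0].min() == pytest.approx(g.inner_conductor_radius * 1e-3)
        assert nodes[:, 0].max() == pytest.approx(g.dielectric_outer_radius * 1e-3)

    def test_antenna_tip_at_insertion_depth(self, domain):
        assert domain.extents[1] - domain.z_tip == pytest.approx(65e-3)

    def test_slot_resolved_by_at_least_ten_elements(self, domain):
        assert np.sum(domain.mesh.regions == Region.SLOT) >= 10

    def test_every_element_labelled_once(self, domain):
        assert domain.mesh.regions.shape == (domain.mesh.n_elements,)
        assert set(np.unique(domain.mesh.regions)) <= {int(r) for r in Region}

    def test_axisymmetric_coordinates_nonnegative(self, domain):
        assert domain.mesh.nodes[:, 0].min() >= 0

    def test_tumor_volume_matches_analytic_sphere(self, domain):
        vol = domain.mesh.revolved_volume(domain.mesh.element_mask(Region.TUMOR))
        analytic = 4 / 3 * np.pi * 0.010**3
        assert vol == pytest.approx(analytic, rel=0.02)   # 4.19 cm^3 at mesh tol

    def test_tumor_volume_converges_under_refinement(self):
        analytic = 4 / 3 * np.pi * 0.010**3
        errs = []
        for scale in (2.0, 1.0):
            dom = build_domain(tumor_diameter_mm=20.0,
                               resolution=MeshResolution(scale=scale))
            vol = dom.mesh.revolved_volume(dom.mesh.element_mask(Region.TUMOR))
            errs.append(abs(vol - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_no_tumor_means_no_tumor_elements(self):
        dom = build_domain()
        assert not np.any(dom.mesh.regions == Region.TUMOR)

    def test_oversized_tumor_rejected(self):
        with pytest.raises(ValueError):
            build_domain(tumor_diameter_mm=120.0)

    def test_insufficient_antenna_clearance_rejected(self):
        with pytest.raises(ValueError):
            build_domain(liver_radius_mm=20.0)

    def test_full_3d_mode_unsupported(self):
        with pytest.raises(NotImplementedError):
            build_domain(mode="full_3d")

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(ValueError):
            build_domain(resolution=MeshResolution(slot=1.0, scale=4.0))


class TestCoaxSegment:
    def test_port_and_termination_edges(self):
        dom = build_coax_segment(length_mm=5, termination="matched")
        assert len(dom.mesh.edges["port"]) > 0
        assert len(dom.mesh.edges["exterior"]) > 0
        short = build_coax_segment(length_mm=5, termination="short")
        assert len(short.mesh.edges["exterior"]) == 0
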