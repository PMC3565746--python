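import json

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

import hes1rdme as h
from hes1rdme.geometry import ConfigurationError, Mesh

SPHERE_VOL = 4.0 / 3.0 * np.pi * 7.5**3  # 1767.15 um^3
NUCLEUS_VOL = 4.0 / 3.0 * np.pi * 3.0**3  # 113.10 um^3


class TestBuildMesh:
    def test_total_volume_close_to_ball(self, default_mesh):
        assert default_mesh.total_volume == pytest.approx(SPHERE_VOL, rel=0.05)

    def test_nuclear_volume_close_to_ball(self, default_mesh):
        nuc_vol = default_mesh.voxel_volumes[default_mesh.nucleus_mask].sum()
        assert nuc_vol == pytest.approx(NUCLEUS_VOL, rel=0.15)

    def test_volume_error_decreases_with_resolution(self):
        errs = []
        for edge in (1.0, 0.5):
            m = h.build_spherical_cell_mesh(voxel_edge=edge)
            errs.append(abs(m.total_volume - SPHERE_VOL) / SPHERE_VOL)
        assert errs[1] < errs[0]

    def test_coarse_voxel_rejected(self):
        with pytest.raises(ConfigurationError):
            h.build_spherical_cell_mesh(voxel_edge=5.0, nucleus_radius=3.0)

    @pytest.mark.parametrize("cell,nuc", [(3.0, 3.0), (3.0, 0.0), (2.0, 3.0)])
    def test_bad_radii_rejected(self, cell, nuc):
        with pytest.raises(ConfigurationError):
            h.build_spherical_cell_mesh(cell_radius=cell, nucleus_radius=nuc)

    def test_centers_inside_cell_and_subdomain_labels(self, default_mesh):
        radii = np.linalg.norm(default_mesh.voxel_centers, axis=1)
        assert np.all(radii < default_mesh.cell_radius)
        nuc = radii <= default_mesh.nucleus_radius
        assert np.array_equal(default_mesh.nucleus_mask, nuc)

    def test_adjacency_symmetric_and_zero_flux(self, default_mesh):
        m = default_mesh
        pairs = set()
        for i in range(m.n_voxels):
            for j in m.neighbors(i):
                assert 0 <= j < m.n_voxels  # no jump leaves the mesh
                pairs.add((i, int(j)))
        assert all((j, i) in pairs for i, j in pairs)
        assert np.all(m.degree() <= 6)

    def test_graph_connected(self, default_mesh):
        m = default_mesh
        data = np.ones(len(m.adjacency_indices))
        g = csr_matrix(
            (data, m.adjacency_indices, m.adjacency_indptr),
            shape=(m.n_voxels, m.n_voxels),
        )
        n_comp, _ = connected_components(g, directed=False)
        assert n_comp == 1

    def test_json_roundtrip(self, small_mesh, tmp_path):
        p = tmp_path / "mesh.json"
        small_mesh.to_json(p)
        back = Mesh.from_json(p)
        assert back.n_voxels == small_mesh.n_voxels
        assert back.gene_voxel == small_mesh.gene_voxel
        np.testing.assert_allclose(back.voxel_centers, small_mesh.voxel_centers)
        assert np.array_equal(back.adjacency_indices, small_mesh.adjacency_indices)
        assert list(back.subdomain) == list(small_mesh.subdomain)


class TestGeneVoxel:
    def test_max_depth_is_cell_center(self, default_mesh):
        g = h.select_gene_voxel(default_mesh, r=3.0)
        assert np.linalg.norm(default_mesh.voxel_centers[g]) < 1e-12

    def test_zero_depth_is_at_membrane(self, default_mesh):
        g = h.select_gene_voxel(default_mesh, r=0.0)
        radius = np.linalg.norm(default_mesh.voxel_centers[g])
        assert abs(radius - default_mesh.nucleus_radius) <= default_mesh.voxel_edge

    def test_intermediate_depth_matches_exhaustive_search(self, default_mesh):
        m = default_mesh
        g = h.select_gene_voxel(m, r=1.5)
        radii = np.linalg.norm(m.voxel_centers, axis=1)
        # brute-force oracle: nearest nuclear voxel to target radius, lowest index
        target = m.nucleus_radius - 1.5
        nuclear = np.flatnonzero(m.nucleus_mask)
        dev = np.abs(radii[nuclear] - target)
        expected = nuclear[np.lexsort((nuclear, dev))][0]
        assert g == expected
        assert abs(radii[g] - 1.5) <= m.voxel_edge

    @pytest.mark.parametrize("r", [-0.1, 3.5])
    def test_depth_out_of_range_rejected(self, default_mesh, r):
        with pytest.raises(ConfigurationError):
            h.select_gene_voxel(default_mesh, r)

    def test_gene_voxel_in_nucleus(self, default_mesh, small_mesh):
        for m in (default_mesh, small_mesh):
            assert m.subdomain[m.gene_voxel] == "nucleus"


class TestJumpRates:
    def test_default_diffusion_rate_per_face(self, default_mesh):
        # 6.00e-13 m^2/min = 0.6 um^2/min over 1-um faces
        jumps = h.compute_jump_rates(default_mesh, {"mRNA": 6.00e-13})
        assert jumps.edge_rates[0].min() == pytest.approx(0.6)
        assert jumps.edge_rates[0].max() == pytest.approx(0.6)

    def test_interior_outflow_matches_laplacian(self, default_mesh):
        jumps = h.compute_jump_rates(default_mesh, {"protein": 6.00e-13})
        out = jumps.outflow_totals(default_mesh)[0]
        interior = default_mesh.degree() == 6
        assert interior.any()
        np.testing.assert_allclose(out[interior], 6 * 0.6, rtol=1e-12)

    def test_zero_diffusion_gives_zero_rates(self, default_mesh):
        jumps = h.compute_jump_rates(default_mesh, {"mRNA": 0.0})
        assert not jumps.edge_rates.any()

    def test_promoter_species_pinned_with_warning(self, default_mesh):
        with pytest.warns(UserWarning, match="does not diffuse"):
            jumps = h.compute_jump_rates(
                default_mesh, {"P_f": 6.00e-13, "P_o": 0.0, "mRNA": 6.00e-13}
            )
        assert not jumps.edge_rates[0].any()  # P_f
        assert jumps.edge_rates[2].any()  # mRNA

    def test_negative_diffusion_rejected(self, default_mesh):
        with pytest.raises(ConfigurationError):
            h.compute_jump_rates(default_mesh, {"mRNA": -1e-13})

    def test_membrane_transparent_to_diffusion(self, default_mesh):
        # nucleus<->cytoplasm edges carry the same rate as interior edges
        m = default_mesh
        jumps = h.compute_jump_rates(m, {"mRNA": 6.00e-13})
        for i in np.flatnonzero(m.nucleus_mask)[:20]:
            for e in range(m.adjacency_indptr[i], m.adjacency_indptr[i + 1]):
                j = m.adjacency_indices[e]
                if m.subdomain[j] == "cytoplasm":
                    assert jumps.edge_rates[0, e] == pytest.approx(0.6)
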