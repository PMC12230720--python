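"""Chain parsing/writing, pose algebra, classification, Rg, domain partitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from emfit.errors import ClassificationError, ParameterError, StructureFormatError
from emfit.map_core import DensityMap
from emfit.simulate import make_helix_chain, simulate_map
from emfit.structure import (
    NA,
    PROTEIN,
    ChainModel,
    ComplexModel,
    Pose,
    apply_pose,
    classify_chain,
    map_radius_of_gyration,
    partition_domains,
    radius_of_gyration,
    read_structure,
    write_pdb,
)


def _mini_chain(residue_names, atom_name="CA", element="C"):
    n = len(residue_names)
    return ChainModel(
        chain_id="X",
        kind=PROTEIN,
        residue_names=list(residue_names),
        residue_seqids=np.arange(1, n + 1),
        atom_names=np.array([atom_name] * n, dtype=object),
        elements=np.array([element] * n, dtype=object),
        coords=np.arange(3 * n, dtype=float).reshape(n, 3),
        atom_residue=np.arange(n),
    )


class TestPose:
    def test_identity_and_group_inverse(self, helix60):
        p = Pose(Rotation.random(random_state=3).as_quat(), [4.0, -2.0, 1.0])
        ident = p.compose(p.inverse())
        assert ident.rotation.magnitude() < 1e-9
        np.testing.assert_allclose(ident.translation, 0, atol=1e-12)
        back = apply_pose(apply_pose(helix60, p), p.inverse())
        np.testing.assert_allclose(back.coords, helix60.coords, atol=1e-9)

    def test_analytic_rotation_about_z(self):
        chain = ChainModel(
            chain_id="Z", kind=PROTEIN, residue_names=["ALA", "ALA"],
            residue_seqids=np.array([1, 2]),
            atom_names=np.array(["CA", "CA"], dtype=object),
            elements=np.array(["C", "C"], dtype=object),
            coords=np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
            atom_residue=np.array([0, 1]),
        )  # centroid at origin
        p = Pose.from_euler([180.0, 0.0, 0.0])
        out = apply_pose(chain, p)
        np.testing.assert_allclose(out.coords[0], [-1, 0, 0], atol=1e-12)

    def test_quaternion_double_cover(self, helix60):
        q = Rotation.random(random_state=9).as_quat()
        a = apply_pose(helix60, Pose(q, [1, 2, 3]))
        b = apply_pose(helix60, Pose(-q, [1, 2, 3]))
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        quat=st.lists(st.floats(-1.0, 1.0), min_size=4, max_size=4).filter(
            lambda q: np.linalg.norm(q) > 1e-3),
        trans=st.lists(st.floats(-50.0, 50.0), min_size=3, max_size=3),
        point=st.lists(st.floats(-30.0, 30.0), min_size=3, max_size=3),
    )
    def test_pose_group_axioms_hold_for_arbitrary_poses(self, quat, trans,
                                                        point):
        """compose(p, inverse(p)) is the identity and application round-trips
        arbitrary points, for any normalizable quaternion and translation."""
        p = Pose(np.array(quat), np.array(trans))
        ident = p.compose(p.inverse())
        assert ident.rotation.magnitude() < 1e-9
        np.testing.assert_allclose(ident.translation, 0.0, atol=1e-9)
        x = np.array([point])
        center = np.array([1.0, -2.0, 3.0])
        back = p.inverse().apply(p.apply(x, center), center + p.translation)
        np.testing.assert_allclose(back, x, atol=1e-8)

    def test_rigidity_preserves_distances(self, helix60, rng):
        p = Pose(Rotation.random(random_state=1).as_quat(), rng.uniform(-9, 9, 3))
        out = apply_pose(helix60, p)
        sub = rng.integers(0, helix60.n_atoms, size=(40, 2))
        d_in = np.linalg.norm(helix60.coords[sub[:, 0]] - helix60.coords[sub[:, 1]],
                              axis=1)
        d_out = np.linalg.norm(out.coords[sub[:, 0]] - out.coords[sub[:, 1]], axis=1)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)


class TestClassification:
    def test_poly_alanine_is_protein(self):
        assert classify_chain(_mini_chain(["ALA"] * 10)) == PROTEIN

    def test_dna_residues_are_na(self):
        chain = _mini_chain(["DA", "DT", "DG", "DC"] * 3, atom_name="P",
                            element="P")
        assert classify_chain(chain) == NA

    def test_mixed_chain_raises(self):
        with pytest.raises(ClassificationError):
            classify_chain(_mini_chain(["ALA"] * 5 + ["DA"] * 5))

    def test_na_kind_forces_rigid(self, duplex16):
        assert duplex16.rigid


class TestStructureIO:
    def test_round_trip_coordinates(self, tmp_path, toy_complex):
        path = tmp_path / "complex.pdb"
        write_pdb(toy_complex, path)
        chains = read_structure(path)
        assert [c.chain_id for c in chains] == [c.chain_id for c in toy_complex.chains]
        for got, want in zip(chains, toy_complex.chains):
            np.testing.assert_allclose(got.coords, want.coords, atol=1e-3)
            assert got.kind == want.kind

    def test_waters_only_raises(self, tmp_path):
        path = tmp_path / "w.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O\n"
            "END\n")
        with pytest.raises(StructureFormatError):
            read_structure(path)

    def test_duplex_file_as_single_rigid_unit(self, tmp_path, duplex16):
        # write the duplex as two separate chains, then read as one rigid unit
        half = duplex16.n_atoms // 2
        strand_a = ChainModel(
            chain_id="A", kind=NA,
            residue_names=duplex16.residue_names[:16],
            residue_seqids=duplex16.residue_seqids[:16],
            atom_names=duplex16.atom_names[:half],
            elements=duplex16.elements[:half],
            coords=duplex16.coords[:half],
            atom_residue=duplex16.atom_residue[:half],
        )
        strand_b = ChainModel(
            chain_id="B", kind=NA,
            residue_names=duplex16.residue_names[16:],
            residue_seqids=duplex16.residue_seqids[:16],
            atom_names=duplex16.atom_names[half:],
            elements=duplex16.elements[half:],
            coords=duplex16.coords[half:],
            atom_residue=duplex16.atom_residue[:half],
        )
        path = tmp_path / "duplex.pdb"
        write_pdb([strand_a, strand_b], path)
        with pytest.warns(UserWarning):
            units = read_structure(path, rigid_group=True)
        assert len(units) == 1
        assert units[0].kind == NA
        assert units[0].rigid


class TestRadiusOfGyration:
    def test_two_points_analytic(self):
        assert radius_of_gyration(np.array([[0, 0, 0], [2.0, 0, 0]])) == pytest.approx(1.0)

    def test_coincident_points_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert radius_of_gyration(np.zeros((4, 3))) == 0.0

    def test_uniform_ball_moment(self, rng):
        # uniform ball of radius R has Rg = R * sqrt(3/5)
        n = 4000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = 10.0 * rng.random(n) ** (1 / 3)
        pts = v * r[:, None]
        assert radius_of_gyration(pts) == pytest.approx(10.0 * np.sqrt(0.6), rel=0.03)

    def test_map_rg_two_point_masses(self):
        grid = np.zeros((5, 5, 15), np.float32)
        grid[2, 2, 2] = 1.0
        grid[2, 2, 12] = 1.0
        dmap = DensityMap(grid=grid, voxel_size=1.0, resolution=5.0)
        assert map_radius_of_gyration(dmap) == pytest.approx(5.0)

    def test_map_rg_single_voxel_zero(self):
        grid = np.zeros((5, 5, 5), np.float32)
        grid[2, 2, 2] = 1.0
        dmap = DensityMap(grid=grid, voxel_size=1.0, resolution=5.0)
        with pytest.warns(UserWarning):
            assert map_radius_of_gyration(dmap) == 0.0

    def test_map_rg_close_to_chain_rg(self, helix60):
        dmap = simulate_map(helix60, resolution=5.0, voxel_size=1.0)
        chain_rg = radius_of_gyration(helix60.coords, helix60.masses)
        map_rg = map_radius_of_gyration(dmap)
        assert abs(map_rg - chain_rg) / chain_rg < 0.15


class TestDomainPartition:
    def test_short_chain_single_domain(self):
        chain = make_helix_chain("A", 50)
        part = partition_domains(chain)
        assert part.n_domains == 1
        assert part.segments == [(0, 49, 0)]

    def test_explicit_boundary(self):
        chain = make_helix_chain("A", 200)
        part = partition_domains(chain, boundaries=[101])
        assert part.n_domains == 2
        assert part.segments[0][:2] == (0, 99)
        assert part.segments[1][:2] == (100, 199)

    def test_boundary_out_of_range_raises(self):
        chain = make_helix_chain("A", 100)
        with pytest.raises(ParameterError):
            partition_domains(chain, boundaries=[500])

    def test_automatic_split_finds_hinge(self):
        # two compact arms joined at a sharp kink: the contact-graph
        # bisection should cut within a few residues of the hinge
        chain = make_helix_chain("A", 160, kink_at=80, kink_angle_deg=100.0)
        part = partition_domains(chain)
        assert part.n_domains == 2
        boundary = part.segments[0][1]
        assert abs(boundary - 80) <= 5

    def test_partition_covers_chain_exactly(self):
        chain = make_helix_chain("A", 160, kink_at=70, kink_angle_deg=90.0)
        part = partition_domains(chain)
        labels = part.residue_labels
        assert len(labels) == 160
        assert np.all(labels >= 0)
        for start, stop, label in part.segments:
            assert stop - start + 1 >= 20

    def test_na_chain_rejected(self, duplex16):
        with pytest.raises(ParameterError):
            partition_domains(duplex16)
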