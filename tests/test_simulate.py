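"""Synthetic complexes, simulated maps, noise, and ground-truth labels."""

import numpy as np
import pytest

from emfit.errors import ParameterError
from emfit.map_core import DensityMap
from emfit.scoring import global_cc
from emfit.segmentation import LABEL_NA, LABEL_OTHER, LABEL_PROTEIN
from emfit.simulate import (
    SyntheticComplexSpec,
    add_noise,
    ground_truth_labels,
    make_helix_chain,
    make_toy_complex,
    simulate_map,
)
from emfit.structure import NA, PROTEIN, ChainModel, ComplexModel


class TestToyComplex:
    def test_helix_ca_spacing(self):
        spec = SyntheticComplexSpec(protein_lengths=(60,), na_lengths=(), seed=1)
        chain = make_toy_complex(spec).chains[0]
        ca = chain.coords[chain.atom_names == "CA"]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert len(ca) == 60
        assert np.all(np.abs(d - 3.8) <= 0.1)

    def test_seed_determinism(self):
        spec = SyntheticComplexSpec(seed=7)
        a = make_toy_complex(spec)
        b = make_toy_complex(spec)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.coords, cb.coords)

    def test_chain_kinds(self):
        spec = SyntheticComplexSpec(protein_lengths=(40, 40), na_lengths=(12,),
                                    seed=2)
        model = make_toy_complex(spec)
        assert [c.kind for c in model.chains] == [PROTEIN, PROTEIN, NA]

    def test_minimum_interchain_gap(self, toy_complex):
        from scipy.spatial import cKDTree

        chains = toy_complex.chains
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                dmin = cKDTree(chains[i].coords).query(chains[j].coords)[0].min()
                assert dmin >= 2.5

    def test_truth_poses_recorded(self, toy_complex):
        poses = toy_complex.provenance["truth_poses"]
        assert set(poses) == {c.chain_id for c in toy_complex.chains}


class TestSimulateMap:
    def test_single_atom_peak_and_isotropy(self):
        chain = ChainModel(
            chain_id="C", kind=PROTEIN, residue_names=["ALA"],
            residue_seqids=np.array([1]),
            atom_names=np.array(["CA"], dtype=object),
            elements=np.array(["C"], dtype=object),
            coords=np.array([[0.0, 0.0, 0.0]]),
            atom_residue=np.array([0]),
        )
        dmap = simulate_map(chain, resolution=6.0, voxel_size=1.0)
        peak = np.unravel_index(np.argmax(dmap.grid), dmap.grid.shape)
        np.testing.assert_allclose(dmap.index_to_physical([peak])[0], 0.0,
                                   atol=1e-9)
        z0, y0, x0 = peak
        for r in (1, 2, 3):
            assert dmap.grid[z0, y0, x0 + r] == pytest.approx(
                dmap.grid[z0, y0, x0 - r], abs=1e-9)
            assert dmap.grid[z0 + r, y0, x0] == pytest.approx(
                dmap.grid[z0, y0 + r, x0], abs=1e-9)

    def test_kernel_width_scales_with_resolution(self):
        chain = ChainModel(
            chain_id="C", kind=PROTEIN, residue_names=["ALA"],
            residue_seqids=np.array([1]),
            atom_names=np.array(["CA"], dtype=object),
            elements=np.array(["C"], dtype=object),
            coords=np.array([[0.0, 0.0, 0.0]]),
            atom_residue=np.array([0]),
        )

        def half_max_radius(resolution):
            dmap = simulate_map(chain, resolution=resolution, voxel_size=0.5,
                                pad=4 * resolution)
            z0, y0, x0 = np.unravel_index(np.argmax(dmap.grid), dmap.grid.shape)
            profile = dmap.grid[z0, y0, x0:]
            below = np.nonzero(profile < profile[0] / 2)[0]
            return below[0] * 0.5

        r4, r8 = half_max_radius(4.0), half_max_radius(8.0)
        assert abs(r8 - 2 * r4) <= 0.5  # FWHM doubles within one voxel

    def test_self_consistency_cc(self, helix60):
        dmap = simulate_map(helix60, resolution=5.0, voxel_size=1.0)
        assert global_cc(helix60, dmap) >= 0.99

    def test_linearity_in_the_model(self, toy_complex):
        a, b = toy_complex.chains[0], toy_complex.chains[2]
        pair = ComplexModel(chains=[a, b])
        whole = simulate_map(pair, resolution=5.0, voxel_size=2.0)
        part_a = DensityMap(grid=np.zeros_like(whole.grid),
                            voxel_size=2.0, origin=whole.origin,
                            resolution=5.0)
        from emfit.simulate import simulate_on_grid

        ga = simulate_on_grid(a.coords, a.masses, part_a)
        gb = simulate_on_grid(b.coords, b.masses, part_a)
        np.testing.assert_allclose(ga + gb, whole.grid, atol=1e-4)

    def test_nyquist_violation_raises(self, helix60):
        with pytest.raises(ParameterError):
            simulate_map(helix60, resolution=3.0, voxel_size=2.0)


class TestNoise:
    def test_zero_noise_is_identity(self, toy_map):
        out = add_noise(toy_map, 0.0, seed=1)
        np.testing.assert_array_equal(out.grid, toy_map.grid)

    def test_same_seed_reproduces(self, toy_map):
        a = add_noise(toy_map, 0.1, seed=5)
        b = add_noise(toy_map, 0.1, seed=5)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_flat_zero_map_unchanged(self):
        dmap = DensityMap(grid=np.zeros((10, 10, 10), np.float32),
                          voxel_size=1.0, resolution=5.0)
        out = add_noise(dmap, 0.1, seed=2)
        np.testing.assert_array_equal(out.grid, 0.0)

    def test_noise_clipped_nonnegative(self, toy_map):
        out = add_noise(toy_map, 0.2, seed=3)
        assert out.grid.min() >= 0.0


class TestGroundTruthLabels:
    def test_label_codes_and_partition(self, toy_complex, toy_map, toy_labels):
        lab = toy_labels.labels
        assert set(np.unique(lab)) <= {LABEL_PROTEIN, LABEL_NA, LABEL_OTHER}
        assert (lab == LABEL_PROTEIN).any()
        assert (lab == LABEL_NA).any()

    def test_protein_only_has_no_na_labels(self):
        spec = SyntheticComplexSpec(protein_lengths=(40,), na_lengths=(), seed=3)
        model = make_toy_complex(spec)
        dmap = simulate_map(model, resolution=5.0, voxel_size=1.0)
        labels = ground_truth_labels(model, dmap)
        assert not (labels.labels == LABEL_NA).any()

    def test_distance_rule_on_single_atom(self):
        chain = ChainModel(
            chain_id="P", kind=PROTEIN, residue_names=["ALA"],
            residue_seqids=np.array([1]),
            atom_names=np.array(["CA"], dtype=object),
            elements=np.array(["C"], dtype=object),
            coords=np.array([[5.0, 5.0, 5.0]]),
            atom_residue=np.array([0]),
        )
        model = ComplexModel(chains=[chain])
        dmap = DensityMap(grid=np.ones((11, 11, 11), np.float32),
                          voxel_size=1.0, origin=np.zeros(3), resolution=5.0)
        labels = ground_truth_labels(model, dmap)
        # voxel 2.9-ish A away -> protein; > 3 A away -> other
        assert labels.labels[5, 5, 7] == LABEL_PROTEIN  # 2 A
        assert labels.labels[5, 5, 8] == LABEL_PROTEIN  # 3 A exactly
        assert labels.labels[5, 5, 9] == LABEL_OTHER  # 4 A
        assert labels.labels[5, 9, 8] == LABEL_OTHER  # 5 A

    def test_labeled_voxels_within_radius(self, toy_complex, toy_map, toy_labels):
        from scipy.spatial import cKDTree

        backbone = np.concatenate([
            c.coords[c.backbone_mask] for c in toy_complex.chains
        ])
        tree = cKDTree(backbone)
        labeled = np.argwhere(toy_labels.labels != LABEL_OTHER)
        xyz = toy_map.index_to_physical(labeled)
        d = tree.query(xyz)[0]
        assert d.max() <= 3.0 + 1e-6
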