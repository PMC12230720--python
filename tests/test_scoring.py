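"""Correlation scores, FSC, composite score, clash, RMSD, TM-score.

Oracle strategy: the grid-accelerated clash score is checked against O(n²)
pair counting; the TM-score against an exhaustive fragment-seed superposition
search; the two-point Kabsch case against its closed form.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from emfit.errors import ParameterError
from emfit.map_core import DensityMap, normalize, resample
from emfit.scoring import (
    ChainScorer,
    clash_score,
    composite_fit_score,
    fsc_curve,
    global_cc,
    integrated_fsc,
    kabsch_rotation,
    local_cc,
    per_residue_cc,
    rmsd_kabsch,
    tm_d0,
    tm_score,
)
from emfit.simulate import make_helix_chain, simulate_map
from emfit.structure import ComplexModel, Pose


@pytest.fixture(scope="module")
def chain_and_map():
    chain = make_helix_chain("A", 60, kink_at=25, kink_angle_deg=50.0)
    dmap = resample(normalize(simulate_map(chain, 5.0, 1.0)), 2.0)
    return chain, dmap


class TestGlobalCC:
    def test_self_correlation(self, chain_and_map):
        chain, dmap = chain_and_map
        assert global_cc(chain, dmap) >= 0.999

    def test_anti_correlation(self, chain_and_map):
        chain, dmap = chain_and_map
        neg = DensityMap(grid=-dmap.grid, voxel_size=dmap.voxel_size,
                         origin=dmap.origin, resolution=dmap.resolution)
        assert global_cc(chain, neg) <= -0.999

    def test_affine_invariance(self, chain_and_map):
        chain, dmap = chain_and_map
        base = global_cc(chain, dmap)
        # affine rescaling within the support (outside it the threshold that
        # defines the support region would change)
        grid = np.where(dmap.grid > 1e-6, dmap.grid * 3.7 + 0.11, dmap.grid)
        scaled = DensityMap(grid=grid.astype(np.float32),
                            voxel_size=dmap.voxel_size, origin=dmap.origin,
                            resolution=dmap.resolution)
        assert global_cc(chain, scaled) == pytest.approx(base, abs=1e-9)


class TestLocalCC:
    def test_window_is_nine_residues_clipped(self, chain_and_map):
        chain, dmap = chain_and_map
        scorer = ChainScorer(chain, dmap)
        assert scorer._win_lo[0] == 0  # residue 1 window clipped at the end
        # residue index 0 atoms contribute to windows 0..4 only
        assert scorer._win_hi[0] == 4

    def test_perfect_placement_high_displaced_low(self, chain_and_map):
        chain, dmap = chain_and_map
        ccs = per_residue_cc(chain, dmap)
        assert len(ccs) == chain.n_residues
        assert np.all(ccs >= 0.95)
        moved = chain.transformed(Pose(translation=[10.0, 0, 0]))
        assert np.median(per_residue_cc(moved, dmap)) < 0.5

    def test_single_residue_matches_batch(self, chain_and_map):
        chain, dmap = chain_and_map
        ccs = per_residue_cc(chain, dmap)
        assert local_cc(chain, dmap, 7) == pytest.approx(ccs[7])


class TestFsc:
    def test_self_fsc_is_one(self, chain_and_map):
        _, dmap = chain_and_map
        curve = fsc_curve(dmap, dmap)
        vals = np.array([v for _, v in curve])
        assert np.allclose(vals[vals != 0], 1.0, atol=1e-9)

    def test_scale_invariance(self, chain_and_map):
        _, dmap = chain_and_map
        scaled = DensityMap(grid=dmap.grid * 5.0, voxel_size=dmap.voxel_size,
                            origin=dmap.origin, resolution=dmap.resolution)
        a = fsc_curve(dmap, dmap)
        b = fsc_curve(dmap, scaled)
        np.testing.assert_allclose([v for _, v in a], [v for _, v in b],
                                   atol=1e-6)

    def test_noise_decays_high_frequency(self, chain_and_map):
        _, dmap = chain_and_map
        rng = np.random.default_rng(0)
        noisy = DensityMap(
            grid=(dmap.grid + rng.normal(0, 2.0 * dmap.grid.std(),
                                         dmap.grid.shape)).astype(np.float32),
            voxel_size=dmap.voxel_size, origin=dmap.origin,
            resolution=dmap.resolution)
        curve = fsc_curve(dmap, noisy)
        vals = [v for _, v in curve]
        assert np.mean(vals[1:4]) > 0.8  # low shells still correlated
        assert np.mean(vals[-4:]) < 0.5  # high shells washed out

    def test_shape_mismatch_raises(self, chain_and_map):
        _, dmap = chain_and_map
        other = DensityMap(grid=np.ones((8, 8, 8), np.float32), voxel_size=2.0,
                           resolution=5.0)
        with pytest.raises(ParameterError):
            fsc_curve(dmap, other)


class TestIntegratedFsc:
    def test_identical_maps_integrate_to_one(self, chain_and_map):
        _, dmap = chain_and_map
        curve = fsc_curve(dmap, dmap)
        assert integrated_fsc(curve, 0.02, 0.2) == pytest.approx(1.0, abs=1e-6)

    def test_constant_half_curve(self):
        curve = [(f, 0.5) for f in np.linspace(0, 0.25, 26)]
        assert integrated_fsc(curve, 0.05, 0.2) == pytest.approx(0.5)

    def test_truth_beats_displacement(self, chain_and_map):
        chain, dmap = chain_and_map
        st = ChainScorer(chain, dmap)
        truth = st.score(chain.coords)["ifsc"]
        moved = st.score(chain.coords + np.array([8.0, 0, 0]))["ifsc"]
        assert truth > moved

    def test_empty_band_raises(self):
        curve = [(f, 1.0) for f in np.linspace(0, 0.25, 26)]
        with pytest.raises(ParameterError):
            integrated_fsc(curve, 0.2, 0.2)


class TestComposite:
    def test_degenerate_weights_reduce_to_global_cc(self, chain_and_map):
        chain, dmap = chain_and_map
        comp = composite_fit_score(chain, dmap, weights=(1.0, 0.0, 0.0))
        assert comp == pytest.approx(global_cc(chain, dmap), abs=1e-9)

    def test_weights_are_normalized(self, chain_and_map):
        chain, dmap = chain_and_map
        a = composite_fit_score(chain, dmap, weights=(1, 1, 1))
        b = composite_fit_score(chain, dmap, weights=(2, 2, 2))
        assert a == pytest.approx(b, abs=1e-12)

    def test_invalid_weights_raise(self, chain_and_map):
        chain, dmap = chain_and_map
        with pytest.raises(ParameterError):
            composite_fit_score(chain, dmap, weights=(0.0, 0.0, 0.0))


def _brute_clash(model, cutoff=3.0):
    coords = np.concatenate([c.coords for c in model.chains])
    unit = np.concatenate([np.full(c.n_atoms, i)
                           for i, c in enumerate(model.chains)])
    n = 0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if unit[i] != unit[j] and np.linalg.norm(coords[i] - coords[j]) < cutoff:
                n += 1
    return n / len(coords)


class TestClash:
    def test_far_apart_is_zero(self):
        a = make_helix_chain("A", 20)
        b = make_helix_chain("B", 20).transformed(Pose(translation=[50, 0, 0]))
        assert clash_score(ComplexModel(chains=[a, b])) == 0.0

    def test_superposed_chains_lower_bound(self):
        a = make_helix_chain("A", 20)
        b = make_helix_chain("B", 20)
        model = ComplexModel(chains=[a, b])
        # every atom has its exact copy at distance 0 in the other unit
        assert clash_score(model) >= 0.5

    def test_grid_equals_brute_force(self, rng):
        chains = []
        for i, cid in enumerate("ABC"):
            pose = Pose(Rotation.random(random_state=i).as_quat(),
                        rng.uniform(-12, 12, 3))
            chains.append(make_helix_chain(cid, 30).transformed(pose))
        model = ComplexModel(chains=chains)
        assert clash_score(model) == pytest.approx(_brute_clash(model))

    def test_single_chain_zero(self, helix60):
        assert clash_score(ComplexModel(chains=[helix60])) == 0.0


class TestRmsdKabsch:
    def test_identical_sets_zero(self, helix60):
        assert rmsd_kabsch(helix60.coords, helix60.coords) == pytest.approx(
            0.0, abs=1e-12)

    def test_rigid_rotation_recovered(self, helix60):
        rot = Rotation.random(random_state=4)
        moved = rot.apply(helix60.coords) + np.array([5.0, -3.0, 2.0])
        assert rmsd_kabsch(helix60.coords, moved, superpose=True) < 1e-9

    def test_two_point_closed_form(self):
        # two points at distance d vs two coincident points: the optimal
        # superposition centers both, leaving RMSD d/2 exactly
        d = 3.0
        a = np.array([[0.0, 0, 0], [d, 0, 0], [d / 2, 0, 0]])
        b = np.array([[d / 2, 0, 0]] * 3)
        got = rmsd_kabsch(a[:2], b[:2], superpose=True)
        assert got == pytest.approx(d / 2, abs=1e-12)

    def test_no_reflection(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(20, 3))
        mirrored = a * np.array([-1.0, 1.0, 1.0])
        r, _, _ = kabsch_rotation(a, mirrored)
        assert np.linalg.det(r) == pytest.approx(1.0)


def _brute_tm(model, reference, seed_lengths=(4, 8, 16, 32)):
    """Exhaustive fragment-seeded superposition search (slow oracle)."""
    from emfit.scoring import _matched_representatives, _tm_from_superposition

    m, r, ref_len = _matched_representatives(model, reference)
    n = len(m)
    d0 = tm_d0(ref_len)
    best = 0.0
    for frag in seed_lengths:
        if frag > n:
            continue
        for start in range(0, n - frag + 1):
            sub = np.arange(start, start + frag)
            for _ in range(30):
                tm, d = _tm_from_superposition(m, r, sub, d0, ref_len)
                best = max(best, tm)
                new = np.nonzero(d < max(d0, 1.0) * 2.0)[0]
                if len(new) < 3 or np.array_equal(new, sub):
                    break
                sub = new
    return best


class TestTmScore:
    def test_identity_is_one(self, helix60):
        assert tm_score(helix60, helix60) == pytest.approx(1.0, abs=1e-9)

    def test_all_distances_at_d0_give_half(self):
        # direct evaluation of the score formula at d_i == d0
        n = 100
        d0 = tm_d0(n)
        assert 1.0 / (1.0 + (d0 / d0) ** 2) == pytest.approx(0.5)

    def test_displaced_half_matches_brute_force(self):
        ref = make_helix_chain("A", 100, kink_at=50, kink_angle_deg=60.0)
        coords = ref.coords.copy()
        mask = ref.atom_residue >= 50
        coords[mask] += np.array([20.0, 0, 0])
        model = ref.with_coords(coords)
        fast = tm_score(model, ref)
        brute = _brute_tm(model, ref)
        assert fast == pytest.approx(brute, abs=0.02)
        assert 0.3 < fast < 0.8

    def test_no_common_residues_raises(self, helix60):
        other = make_helix_chain("Z", 30)
        with pytest.raises(ParameterError):
            tm_score(other, helix60)
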