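"""Assembly energy, exhaustive/DE selection, joint refinement, final output."""

import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from emfit.assembly import (
    AssemblyState,
    DEConfig,
    assemble_de,
    assembly_energy,
    build_output,
    global_refine,
)
from emfit.errors import ParameterError
from emfit.fitting import FitCandidate, FitResult
from emfit.map_core import normalize, resample
from emfit.scoring import global_cc
from emfit.simulate import make_duplex_chain, make_helix_chain, simulate_map
from emfit.structure import ComplexModel, Pose


def _cand(pose, score=0.5):
    return FitCandidate(pose=pose, composite=score, global_cc=score,
                        mean_local_cc=score, ifsc=score)


@pytest.fixture(scope="module")
def two_chain_setup():
    """Two chains with hand-built candidate lists: truth + decoys."""
    rng = np.random.default_rng(3)
    a = make_helix_chain("A", 40, kink_at=15, kink_angle_deg=50.0)
    b = make_duplex_chain("B", 12, rng).transformed(
        Pose(translation=[30.0, 0.0, 0.0]))
    truth = ComplexModel(chains=[a, b])
    dmap = resample(normalize(simulate_map(truth, 5.0, 1.0)), 2.0)
    decoy = Pose(Rotation.from_euler("y", 90, degrees=True).as_quat(),
                 [10.0, 5.0, 0.0])
    results = {
        "A": FitResult(chain_id="A", candidates=[
            _cand(Pose.identity(), 0.9), _cand(decoy, 0.4)]),
        "B": FitResult(chain_id="B", candidates=[
            _cand(Pose.identity(), 0.9),
            _cand(Pose(translation=[-25.0, 0, 0]), 0.4)]),
    }
    return [a, b], results, dmap


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"F": 0.0}, {"F": 2.5}, {"CR": 1.2}, {"population": 2},
    ])
    def test_invalid_hyperparameters(self, kwargs):
        with pytest.raises(ParameterError):
            DEConfig(**kwargs)


class TestEnergy:
    def test_lambda_zero_reduces_to_negative_cc(self, two_chain_setup):
        chains, results, dmap = two_chain_setup
        e = assembly_energy([0, 0], chains, results, dmap, lambda_clash=0.0)
        model = ComplexModel(chains=[c.transformed(Pose.identity())
                                     for c in chains])
        assert e == pytest.approx(-global_cc(model, dmap), abs=1e-9)

    def test_overlap_strictly_raises_energy(self, two_chain_setup):
        chains, results, dmap = two_chain_setup
        # candidate 1 of B drops the duplex onto chain A
        apart = assembly_energy([0, 0], chains, results, dmap)
        overlap = assembly_energy([0, 1], chains, results, dmap)
        assert overlap > apart

    def test_out_of_range_selection_raises(self, two_chain_setup):
        chains, results, dmap = two_chain_setup
        with pytest.raises(ParameterError):
            assembly_energy([0, 7], chains, results, dmap)


class TestAssembleDE:
    def test_singleton_space(self, two_chain_setup):
        chains, _, dmap = two_chain_setup
        results = {
            "A": FitResult(chain_id="A", candidates=[_cand(Pose.identity())]),
            "B": FitResult(chain_id="B", candidates=[_cand(Pose.identity())]),
        }
        state = assemble_de(chains, results, dmap)
        np.testing.assert_array_equal(state.selection, [0, 0])

    def test_exhaustive_matches_brute_force(self, two_chain_setup):
        chains, results, dmap = two_chain_setup
        state = assemble_de(chains, results, dmap)
        # independent brute force over all 4 selections
        best, best_e = None, np.inf
        for sel in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            e = assembly_energy(sel, chains, results, dmap)
            if e < best_e:
                best, best_e = sel, e
        np.testing.assert_array_equal(state.selection, best)
        assert state.energy == pytest.approx(best_e, abs=1e-6)
        assert best == (0, 0)  # truth poses win

    def test_de_path_beats_greedy_on_many_chains(self):
        """Above the enumeration cutoff the DE search must at least match the
        per-chain-greedy (all top-1) selection."""
        rng = np.random.default_rng(0)
        chains = []
        results = {}
        for i in range(6):
            cid = chr(ord("A") + i)
            chain = make_helix_chain(cid, 15).transformed(
                Pose(translation=[18.0 * i, 0.0, 0.0]))
            chains.append(chain)
            # 4 candidates each: truth plus jittered decoys => 4^6 > 1024
            cands = [_cand(Pose.identity(), 0.9)]
            for j in range(3):
                cands.append(_cand(Pose(
                    Rotation.random(random_state=10 * i + j).as_quat(),
                    rng.uniform(-8, 8, 3)), 0.3))
            results[cid] = FitResult(chain_id=cid, candidates=cands)
        dmap = resample(normalize(
            simulate_map(ComplexModel(chains=chains), 5.0, 1.0)), 2.0)
        config = DEConfig(population=24, generations=30, seed=1)
        state = assemble_de(chains, results, dmap, config=config)
        greedy = assembly_energy([0] * 6, chains, results, dmap)
        assert state.energy <= greedy + 1e-9


class TestGlobalRefine:
    def test_fixed_point_at_optimum(self, two_chain_setup):
        chains, results, dmap = two_chain_setup
        state = assemble_de(chains, results, dmap)
        refined = global_refine(state, dmap, maxiter=10)
        for got, want in zip(refined.chains, state.model.chains):
            assert np.abs(got.coords - want.coords).max() < 0.3

    def test_joint_polish_reduces_displacement(self, two_chain_setup):
        chains, _, dmap = two_chain_setup
        jitter = Pose(Rotation.from_euler("z", 2.0, degrees=True).as_quat(),
                      [1.0, -0.8, 0.6])
        results = {
            c.chain_id: FitResult(chain_id=c.chain_id,
                                  candidates=[_cand(jitter, 0.8)])
            for c in chains
        }
        state = assemble_de(chains, results, dmap)
        refined = global_refine(state, dmap, maxiter=60)
        for chain in chains:
            before = np.sqrt(np.mean(np.sum(
                (state.model.get_chain(chain.chain_id).coords - chain.coords) ** 2,
                axis=1)))
            after = np.sqrt(np.mean(np.sum(
                (refined.get_chain(chain.chain_id).coords - chain.coords) ** 2,
                axis=1)))
            assert after < before

    def test_na_internal_geometry_rigid(self, two_chain_setup):
        chains, results, dmap = two_chain_setup
        state = assemble_de(chains, results, dmap)
        refined = global_refine(state, dmap, maxiter=15)
        duplex_in = state.model.get_chain("B")
        duplex_out = refined.get_chain("B")
        rng = np.random.default_rng(1)
        pairs = rng.integers(0, duplex_in.n_atoms, size=(60, 2))
        d_in = np.linalg.norm(duplex_in.coords[pairs[:, 0]]
                              - duplex_in.coords[pairs[:, 1]], axis=1)
        d_out = np.linalg.norm(duplex_out.coords[pairs[:, 0]]
                               - duplex_out.coords[pairs[:, 1]], axis=1)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)


class TestBuildOutput:
    def test_report_contents(self, tmp_path, two_chain_setup):
        chains, results, dmap = two_chain_setup
        state = assemble_de(chains, results, dmap)
        pdb = tmp_path / "model.pdb"
        rep = tmp_path / "report.json"
        payload = build_output(state.model, dmap, pdb, rep)
        assert pdb.exists()
        on_disk = json.loads(rep.read_text())
        assert set(on_disk["chains"]) == {"A", "B"}
        n_res = sum(c.n_residues for c in chains)
        assert len(on_disk["complex"]["per_residue_cc"]) == n_res
        assert on_disk["complex"]["global_cc"] > 0.8
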