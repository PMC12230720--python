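"""Complex assembly: pick one pose per chain, then refine everything jointly.

The retained fit candidates define a small product search space (≤ 5 poses
per chain).  One combination is selected by minimizing

    E(selection) = −global_CC(complex, map) + λ_clash × clash_score(complex)

against the original (unsegmented, unmasked) map, so protein and nucleic-acid
placements are judged jointly.  Spaces of ≤ 1024 combinations are enumerated
exhaustively (exact optimum); larger ones are searched with an integer-coded
differential evolution (rand/1/bin, rounding + reflection repair).

The selected complex then undergoes one joint L-BFGS refinement over all
rigid units simultaneously — every protein domain is its own 6-DOF unit,
nucleic-acid chains stay single rigid bodies — accepted only if the energy
improves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .fitting import FD_ROT_STEP_DEG, FD_TRANS_STEP, FitResult
from .map_core import DensityMap
from .scoring import (
    ChainScorer,
    DEFAULT_CLASH_CUTOFF,
    ScoreReport,
    clash_score,
    fsc_curve,
    global_cc,
    integrated_fsc,
    IFSC_FREQ_MIN,
)
from .structure import NA, PROTEIN, ChainModel, ComplexModel, Pose, write_pdb

ENUMERATION_CUTOFF = 1024
DEFAULT_LAMBDA_CLASH = 1.0

__all__ = [
    "AssemblyState", "DEConfig", "assembly_energy", "assemble_de",
    "global_refine", "build_output",
]


@dataclass
class DEConfig:
    """Differential-evolution hyperparameters (rand/1/bin, integer-coded)."""

    population: int = 40
    F: float = 0.7
    CR: float = 0.9
    generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.F <= 2):
            raise ParameterError("differential weight F must be in (0, 2]")
        if not (0 <= self.CR <= 1):
            raise ParameterError("crossover rate CR must be in [0, 1]")
        if self.population < 4:
            raise ParameterError("population must be at least 4")


@dataclass
class AssemblyState:
    """A candidate-index selection per chain plus its decoded complex."""

    selection: np.ndarray  # one candidate index per chain
    energy: float
    model: ComplexModel


class _EnergyModel:
    """Cached energy evaluator: −global CC + λ × clash on one map.

    The simulated density is linear in the model, so the complex density is
    the sum of per-part grids; parts that did not move between evaluations
    are never re-simulated.
    """

    def __init__(self, chains: list[ChainModel], dmap: DensityMap,
                 lambda_clash: float = DEFAULT_LAMBDA_CLASH) -> None:
        if lambda_clash < 0:
            raise ParameterError("lambda_clash must be nonnegative")
        self.chains = chains
        self.dmap = dmap
        self.lambda_clash = lambda_clash
        self.exp = dmap.grid.astype(np.float64)
        self.exp_support = self.exp > 1e-6

    def decoded(self, poses: list[Pose]) -> ComplexModel:
        placed = [c.transformed(p) for c, p in zip(self.chains, poses)]
        return ComplexModel(chains=placed)

    def density_of(self, coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
        from .simulate import simulate_on_grid

        return simulate_on_grid(coords, masses, self.dmap).astype(np.float64)

    def energy_from_density(self, sim: np.ndarray, coords_per_unit,
                            n_atoms_total: int) -> float:
        support = self.exp_support | (sim > 1e-6)
        a = self.exp[support]
        b = sim[support]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        cc = float((a * b).sum() / denom) if denom > 0 else 0.0
        clash = 0.0
        if self.lambda_clash > 0 and len(coords_per_unit) > 1:
            coords = np.concatenate(coords_per_unit)
            unit = np.concatenate([np.full(len(c), i)
                                   for i, c in enumerate(coords_per_unit)])
            tree = cKDTree(coords)
            pairs = tree.query_pairs(DEFAULT_CLASH_CUTOFF, output_type="ndarray")
            if len(pairs):
                inter = unit[pairs[:, 0]] != unit[pairs[:, 1]]
                pairs = pairs[inter]
                if len(pairs):
                    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]],
                                       axis=1)
                    clash = float(np.count_nonzero(d < DEFAULT_CLASH_CUTOFF)
                                  / n_atoms_total)
        return -cc + self.lambda_clash * clash

    def energy_of(self, model: ComplexModel) -> float:
        cc = global_cc(model, self.dmap)
        clash = clash_score(model) if self.lambda_clash > 0 else 0.0
        return -cc + self.lambda_clash * clash

    def energy(self, poses: list[Pose]) -> float:
        return self.energy_of(self.decoded(poses))


def _ordered_results(fit_results: dict[str, FitResult] | list[FitResult],
                     chains: list[ChainModel]) -> list[FitResult]:
    if isinstance(fit_results, dict):
        return [fit_results[c.chain_id] for c in chains]
    by_id = {r.chain_id: r for r in fit_results}
    return [by_id[c.chain_id] for c in chains]


def assembly_energy(
    selection: np.ndarray,
    chains: list[ChainModel],
    fit_results: dict[str, FitResult] | list[FitResult],
    dmap: DensityMap,
    lambda_clash: float = DEFAULT_LAMBDA_CLASH,
) -> float:
    """Energy of one candidate selection (lower is better)."""
    results = _ordered_results(fit_results, chains)
    selection = np.asarray(selection, dtype=int)
    for idx, result in zip(selection, results):
        if not 0 <= idx < len(result.candidates):
            raise ParameterError(f"selection index {idx} out of range for "
                                 f"chain {result.chain_id}")
    poses = [r.candidates[i].pose for r, i in zip(results, selection)]
    return _EnergyModel(chains, dmap, lambda_clash).energy(poses)


def assemble_de(
    chains: list[ChainModel],
    fit_results: dict[str, FitResult] | list[FitResult],
    dmap: DensityMap,
    config: DEConfig | None = None,
    lambda_clash: float = DEFAULT_LAMBDA_CLASH,
) -> AssemblyState:
    """Select one retained pose per chain by minimizing the assembly energy.

    Exhaustive enumeration below ``ENUMERATION_CUTOFF`` combinations (exact);
    integer-coded rand/1/bin differential evolution above it.
    """
    config = config or DEConfig()
    results = _ordered_results(fit_results, chains)
    sizes = np.array([len(r.candidates) for r in results])
    if np.any(sizes < 1):
        raise ParameterError("every chain needs at least one fit candidate")
    energy_model = _EnergyModel(chains, dmap, lambda_clash)
    # precompute coordinates and density grids of every retained candidate:
    # an energy evaluation then only sums cached grids
    cand_coords = [
        [cand.pose.apply(c.coords, c.centroid) for cand in r.candidates]
        for c, r in zip(chains, results)
    ]
    cand_density = [
        [energy_model.density_of(xyz, c.masses) for xyz in per_chain]
        for c, per_chain in zip(chains, cand_coords)
    ]
    n_atoms_total = sum(c.n_atoms for c in chains)

    def energy_of_selection(sel: np.ndarray) -> float:
        sim = cand_density[0][sel[0]].copy()
        for ci in range(1, len(chains)):
            sim += cand_density[ci][sel[ci]]
        coords = [cand_coords[ci][sel[ci]] for ci in range(len(chains))]
        return energy_model.energy_from_density(sim, coords, n_atoms_total)

    total = int(np.prod(sizes, dtype=np.int64))
    if total <= ENUMERATION_CUTOFF:
        best_sel, best_e = None, np.inf
        for sel in np.ndindex(*sizes):
            e = energy_of_selection(np.array(sel))
            if e < best_e:
                best_sel, best_e = np.array(sel), e
    else:
        best_sel, best_e = _integer_de(energy_of_selection, sizes, config)
    poses = [r.candidates[i].pose for r, i in zip(results, best_sel)]
    return AssemblyState(selection=best_sel, energy=float(best_e),
                         model=energy_model.decoded(poses))


def _integer_de(energy_fn, sizes: np.ndarray, config: DEConfig
                ) -> tuple[np.ndarray, float]:
    """rand/1/bin DE over integer index vectors with reflection repair."""
    rng = np.random.default_rng(config.seed)
    n = len(sizes)
    hi = sizes.astype(float) - 1.0
    pop = rng.uniform(0.0, hi, size=(config.population, n))
    pop[0] = 0.0  # include the per-chain-greedy (top candidate) selection

    def repair(x: np.ndarray) -> np.ndarray:
        # reflect out-of-range coordinates back into [0, hi]
        x = np.abs(x)
        over = x > hi
        x[over] = (2 * hi - x)[over]
        return np.clip(x, 0.0, hi)

    def as_index(x: np.ndarray) -> np.ndarray:
        return np.clip(np.round(x), 0, hi).astype(int)

    energies = np.array([energy_fn(as_index(x)) for x in pop])
    for _ in range(config.generations):
        for i in range(config.population):
            r1, r2, r3 = rng.choice(
                [j for j in range(config.population) if j != i], 3, replace=False)
            mutant = repair(pop[r1] + config.F * (pop[r2] - pop[r3]))
            cross = rng.random(n) < config.CR
            cross[rng.integers(n)] = True
            trial = np.where(cross, mutant, pop[i])
            e = energy_fn(as_index(trial))
            if e <= energies[i]:
                pop[i] = trial
                energies[i] = e
    best = int(np.argmin(energies))
    return as_index(pop[best]), float(energies[best])


# ---------------------------------------------------------------------------
# Joint global refinement


def _rigid_units(model: ComplexModel) -> list[tuple[int, np.ndarray]]:
    """(chain index, atom indices) per rigid unit: protein domains split,
    nucleic-acid chains whole."""
    units = []
    for ci, chain in enumerate(model.chains):
        if (chain.kind == PROTEIN and not chain.rigid
                and chain.domains is not None and chain.domains.n_domains > 1):
            for label in chain.domains.domain_labels():
                residues = chain.domains.domain_residues(label)
                units.append((ci, np.nonzero(
                    np.isin(chain.atom_residue, residues))[0]))
        else:
            units.append((ci, np.arange(chain.n_atoms)))
    return units


def global_refine(
    state: AssemblyState,
    dmap: DensityMap,
    lambda_clash: float = DEFAULT_LAMBDA_CLASH,
    maxiter: int = 100,
    ftol: float = 1e-6,
) -> ComplexModel:
    """One joint L-BFGS pass over all rigid-unit poses simultaneously.

    Six parameters per unit (translation + axis-angle about the unit
    centroid); central finite differences (0.25 Å / 1°).  The refined model is
    returned only if its energy improves; otherwise the input model is kept.
    NA units move rigidly by construction.
    """
    model = state.model
    units = _rigid_units(model)
    n_units = len(units)
    base_coords = [model.chains[ci].coords[idx].copy() for ci, idx in units]
    centers = [c.mean(axis=0) for c in base_coords]
    unit_masses = [model.chains[ci].masses[idx] for ci, idx in units]
    energy_model = _EnergyModel(list(model.chains), dmap, lambda_clash)
    n_atoms_total = sum(c.n_atoms for c in model.chains)
    n_params = 6 * n_units
    steps = np.tile([FD_TRANS_STEP] * 3 + [np.deg2rad(FD_ROT_STEP_DEG)] * 3,
                    n_units)

    def unit_coords(k: int, xk: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(xk[3:6])
        return centers[k] + rot.apply(base_coords[k] - centers[k]) + xk[:3]

    def chain_coords(per_unit: list[np.ndarray]) -> list[np.ndarray]:
        chains = [c.coords.copy() for c in model.chains]
        for k, (ci, idx) in enumerate(units):
            chains[ci][idx] = per_unit[k]
        return chains

    def decode(x: np.ndarray) -> ComplexModel:
        per_unit = [unit_coords(k, x[6 * k : 6 * k + 6]) for k in range(n_units)]
        chains = chain_coords(per_unit)
        return ComplexModel(chains=[c.with_coords(xyz)
                                    for c, xyz in zip(model.chains, chains)])

    def value_and_grad(x: np.ndarray):
        # densities are additive over units: only the perturbed unit is
        # re-simulated when forming each finite difference
        per_unit = [unit_coords(k, x[6 * k : 6 * k + 6]) for k in range(n_units)]
        unit_density = [energy_model.density_of(c, m)
                        for c, m in zip(per_unit, unit_masses)]
        total = np.sum(unit_density, axis=0)
        f0 = energy_model.energy_from_density(total, chain_coords(per_unit),
                                              n_atoms_total)
        grad = np.empty(n_params)
        for i in range(n_params):
            k = i // 6
            fs = []
            for sign in (+1.0, -1.0):
                xk = x[6 * k : 6 * k + 6].copy()
                xk[i % 6] += sign * steps[i]
                moved = unit_coords(k, xk)
                sim = total - unit_density[k] + energy_model.density_of(
                    moved, unit_masses[k])
                trial = list(per_unit)
                trial[k] = moved
                fs.append(energy_model.energy_from_density(
                    sim, chain_coords(trial), n_atoms_total))
            grad[i] = (fs[0] - fs[1]) / (2 * steps[i])
        return f0, grad

    e_start = energy_model.energy_of(model)
    try:
        result = optimize.minimize(
            value_and_grad, np.zeros(n_params), jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-12},
        )
    except FloatingPointError:
        warnings.warn("global refinement diverged; keeping the assembled model",
                      stacklevel=2)
        return model
    if not np.isfinite(result.fun):
        warnings.warn("global refinement produced non-finite energy; "
                      "keeping the assembled model", stacklevel=2)
        return model
    if result.fun < e_start:
        return decode(result.x)
    return model


# ---------------------------------------------------------------------------
# Final output


def score_complex(model: ComplexModel, dmap: DensityMap) -> ScoreReport:
    """Complex-level CC/iFSC/clash plus per-residue CC for every chain."""
    from .simulate import simulate_on_grid

    coords = model.all_coords
    weights = np.concatenate([c.masses for c in model.chains])
    sim = simulate_on_grid(coords, weights, dmap)
    cc = global_cc(model, dmap, sim_grid=sim)
    sim_map = DensityMap(grid=sim, voxel_size=dmap.voxel_size,
                         origin=dmap.origin.copy(), resolution=dmap.resolution)
    curve = fsc_curve(dmap, sim_map)
    fmax = 1.0 / dmap.resolution
    fmin = IFSC_FREQ_MIN if IFSC_FREQ_MIN < fmax else curve[1][0]
    ifsc = integrated_fsc(curve, fmin, fmax)
    per_res: list[tuple[str, int, float]] = []
    mean_local = []
    for chain in model.chains:
        scorer = ChainScorer(chain, dmap)
        ccs = scorer.local_cc_all(chain.coords)
        mean_local.extend(ccs.tolist())
        per_res.extend(
            (chain.chain_id, int(s), float(v))
            for s, v in zip(chain.residue_seqids, ccs)
        )
    composite = float(np.mean([cc, np.mean(mean_local), ifsc]))
    return ScoreReport(
        global_cc=cc,
        per_residue_cc=per_res,
        fsc_curve=curve,
        ifsc=ifsc,
        clash=clash_score(model),
        composite=composite,
    )


def build_output(
    model: ComplexModel,
    dmap: DensityMap,
    pdb_path,
    report_path=None,
) -> dict:
    """Write the final PDB and a JSON quality report.

    The report carries one global CC/iFSC entry per chain plus one for the
    whole complex, and the per-residue CC table for every residue.
    """
    report = score_complex(model, dmap)
    chain_entries = {}
    for chain in model.chains:
        scorer = ChainScorer(chain, dmap)
        s = scorer.score(chain.coords)
        chain_entries[chain.chain_id] = {
            "global_cc": s["global_cc"],
            "mean_local_cc": s["mean_local_cc"],
            "ifsc": s["ifsc"],
        }
    payload = {
        "complex": report.to_dict(),
        "chains": chain_entries,
        "n_residues": int(model.n_residues),
    }
    remarks = [
        f"EMFIT COMPLEX CC {report.global_cc:.4f} IFSC {report.ifsc:.4f} "
        f"CLASH {report.clash:.4f}",
    ] + [
        f"EMFIT CHAIN {cid} CC {e['global_cc']:.4f} IFSC {e['ifsc']:.4f}"
        for cid, e in chain_entries.items()
    ]
    try:
        write_pdb(model, pdb_path, remarks=remarks)
        if report_path is not None:
            with open(report_path, "w") as fh:
                json.dump(payload, fh, indent=2)
    except OSError as exc:
        raise OSError(f"cannot write output ({pdb_path} / {report_path}): {exc}")
    return payload
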