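"""Fitting individual chains into (segmented) density maps.

The fitting strategy is multi-start local optimization: translation seeds
come from the map's density centroid (plus local density maxima when the map
is much larger than the chain), rotation seeds from an Euler-angle lattice;
each start is refined by rigid-body L-BFGS on the composite score (global CC
+ mean local CC + integrated FSC), refined poses are deduplicated, and the
top five are retained per chain.

Chains are fitted longest-first; once a chain scores above the acceptance
threshold its map region is zeroed out (masking) so later chains fit the
residual density, and unplaced chains are retried in later rounds with the
threshold lowered step by step (0.6 → 0.3 by default).

Protein chains with a multi-domain partition get an extra flexible step:
each domain is refined as its own rigid body, accepted only if the composite
score improves and the inter-domain linker is not torn apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .errors import DegenerateMapError, FitFailure, ParameterError
from .map_core import DensityMap, mask_region, resample
from .scoring import ChainScorer, DEFAULT_WEIGHTS
from .structure import (
    NA,
    PROTEIN,
    ChainModel,
    Pose,
    density_centroid,
    radius_of_gyration,
)

DEDUP_TRANSLATION = 2.0  # Å
DEDUP_ROTATION = 10.0  # degrees
TOP_K = 5
COARSE_RESOLUTION_FLOOR = 15.0  # Å, low-pass stage (see lowpass_map)
COARSE_RESOLUTION_FACTOR = 3.0
COARSE_VOXEL = 3.0  # Å
FD_TRANS_STEP = 0.25  # Å, central-difference step for translations
FD_ROT_STEP_DEG = 1.0  # degrees, central-difference step for rotations
MAX_STARTS_DEFAULT = 20
MAX_STARTS_HARD_CAP = 512
MAX_TRANSLATION_SEEDS = 8

__all__ = [
    "FitCandidate", "FitResult", "FitSchedule", "init_poses",
    "refine_pose_lbfgs", "fit_chain", "iterative_fit_all", "domain_refine",
]


@dataclass
class FitCandidate:
    """One refined pose with its composite score and components."""

    pose: Pose
    composite: float
    global_cc: float
    mean_local_cc: float
    ifsc: float
    converged: bool = True


@dataclass
class FitResult:
    """Ranked pose candidates for one chain (composite descending, ≤ 5)."""

    chain_id: str
    candidates: list[FitCandidate]
    well_fitted: bool = False
    rounds: int = 1

    def __post_init__(self) -> None:
        self.candidates = sorted(self.candidates, key=lambda c: -c.composite)[:TOP_K]

    @property
    def best(self) -> FitCandidate:
        return self.candidates[0]


@dataclass
class FitSchedule:
    """Decaying acceptance-threshold schedule for iterative fitting."""

    threshold_init: float = 0.6
    threshold_step: float = 0.1
    threshold_floor: float = 0.3
    max_rounds: int = 4

    def __post_init__(self) -> None:
        if self.threshold_floor > self.threshold_init:
            raise ParameterError("threshold_floor must not exceed threshold_init")
        if self.threshold_step <= 0:
            raise ParameterError("threshold must strictly decrease between rounds")

    def thresholds(self) -> list[float]:
        out = []
        t = self.threshold_init
        for _ in range(self.max_rounds):
            out.append(max(t, self.threshold_floor))
            if out[-1] <= self.threshold_floor:
                break
            t -= self.threshold_step
        return out


# ---------------------------------------------------------------------------
# Low-pass stage

def lowpass_map(dmap: DensityMap, resolution: float | None = None,
                voxel: float = COARSE_VOXEL) -> DensityMap:
    """Low-pass-filtered, coarsely sampled copy of a map for pose triage.

    Elongated chains have a very narrow rotational basin at the map's native
    resolution (a few degrees misorientation decorrelates their ends), far
    narrower than any affordable Euler enumeration.  Blurring the map to
    ``resolution`` (default max(3× native, 15 Å)) widens the basin so that
    coarse grid poses can be ranked and pulled in by local optimization
    before the full-resolution polish.
    """
    if resolution is None:
        resolution = max(COARSE_RESOLUTION_FACTOR * dmap.resolution,
                         COARSE_RESOLUTION_FLOOR)
    sigma_native = dmap.resolution / (np.pi * np.sqrt(2.0))
    sigma_target = resolution / (np.pi * np.sqrt(2.0))
    extra = np.sqrt(max(sigma_target**2 - sigma_native**2, 1e-4))
    blurred = ndimage.gaussian_filter(dmap.grid.astype(np.float64),
                                      extra / dmap.voxel_size)
    low = DensityMap(grid=blurred.astype(np.float32),
                     voxel_size=dmap.voxel_size, origin=dmap.origin.copy(),
                     resolution=resolution, contour_level=dmap.contour_level)
    # keep at least 8 voxels per axis when coarsening the lattice
    max_voxel = min(low.grid.shape) * low.voxel_size / 8.0
    target = min(voxel, max(max_voxel, low.voxel_size))
    if target > low.voxel_size:
        low = resample(low, target)
    return low


# ---------------------------------------------------------------------------
# Pose initialization


def euler_rotation_seeds(angular_step: float) -> list[Rotation]:
    """Deduplicated rotations on a z-y-z Euler lattice with the given step.

    Lattice points closer than half the step (as rotations, double cover
    handled via |q·q'|) are merged greedily.
    """
    if angular_step <= 0 or angular_step > 180:
        raise ParameterError("angular_step must be in (0, 180] degrees")
    alphas = np.arange(0.0, 360.0, angular_step)
    betas = np.arange(0.0, 180.0 + 1e-9, angular_step)
    gammas = np.arange(0.0, 360.0, angular_step)
    grid = np.array([[a, b, g] for a in alphas for b in betas for g in gammas])
    quats = Rotation.from_euler("ZYZ", grid, degrees=True).as_quat()
    # relative angle = 2*arccos(|q1 . q2|); keep if >= step/2
    dot_cut = np.cos(np.deg2rad(angular_step) / 4.0)
    kept = np.empty((0, 4))
    for q in quats:
        if kept.size and np.any(np.abs(kept @ q) >= dot_cut):
            continue
        kept = np.vstack([kept, q])
    return [Rotation.from_quat(q) for q in kept]


def _translation_seeds(chain: ChainModel, dmap: DensityMap) -> list[np.ndarray]:
    """Candidate translation targets for the chain centroid.

    The density centroid is always a seed.  It is supplemented by the
    strongest local maxima of the map smoothed at the chain's own length
    scale: when the map holds several chains (or an elongated chain shares a
    map with others) the global centroid can fall between them, so the
    per-blob maxima are what actually localize the chain.  The gyration radii
    of map and chain set the smoothing scale and the seed spacing.
    """
    centroid = density_centroid(dmap)
    seeds = [centroid]
    chain_rg = radius_of_gyration(chain.coords, weights=chain.masses)
    sigma_vox = max(chain_rg / 4.0 / dmap.voxel_size, 1.0)
    smooth = ndimage.gaussian_filter(dmap.grid.astype(np.float64), sigma_vox)
    footprint = int(max(3, round(chain_rg / 2.0 / dmap.voxel_size)))
    local_max = (smooth == ndimage.maximum_filter(smooth, size=footprint))
    local_max &= smooth > 0.05 * smooth.max()
    peaks = np.argwhere(local_max)
    if len(peaks):
        order = np.argsort(-smooth[tuple(peaks.T)])
        xyz = dmap.index_to_physical(peaks[order])
        for p in xyz:
            if len(seeds) >= MAX_TRANSLATION_SEEDS:
                break
            if all(np.linalg.norm(p - s) > chain_rg / 3 for s in seeds):
                seeds.append(p)
    return seeds[:MAX_TRANSLATION_SEEDS]


SCAN_VOXEL = 4.0  # Å lattice of the FFT translation scan


def _scan_lattice(dmap: DensityMap, voxel: float) -> DensityMap:
    """Coarse copy of a map for the translation scan (no minimum-size rule)."""
    if voxel <= dmap.voxel_size:
        return dmap
    spacing = dmap.voxel_size
    old_n = np.array(dmap.grid.shape, dtype=float)
    new_n = np.maximum(np.ceil(old_n * spacing / voxel - 1e-9), 1).astype(int)
    axes = [np.arange(n) * voxel / spacing for n in new_n]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    grid = ndimage.map_coordinates(dmap.grid.astype(np.float64),
                                   np.stack([zz, yy, xx]), order=1,
                                   mode="nearest")
    return DensityMap(grid=grid.astype(np.float32), voxel_size=float(voxel),
                      origin=dmap.origin.copy(), resolution=dmap.resolution)


class _TranslationScan:
    """Exhaustive FFT translation search on a coarse copy of one map.

    For a rotated model density g the locally normalized cross-correlation

        s(t) = Σ_x ρ(x) g(x − t) / (‖g‖ · sqrt(Σ_{|x − t| < r} ρ(x)²))

    is evaluated for every lattice translation t at once; the local map
    energy under a sphere of the model's size (the denominator) is
    precomputed, so each rotation costs one forward and one inverse FFT.
    This finds the best centroid placement per rotation even when several
    chains share the map and the density centroid lies between them.
    """

    def __init__(self, dmap: DensityMap, patch_max_voxels: int,
                 sphere_radius: float) -> None:
        self.dmap = dmap
        nz, ny, nx = dmap.grid.shape
        # linear (non-circular) correlation needs map + patch extents
        pad = patch_max_voxels + 2
        self.shape = tuple(sp_fft.next_fast_len(n + pad) for n in (nz, ny, nx))
        self._map_shape = np.array([nz, ny, nx])
        exp = np.zeros(self.shape, dtype=np.float32)
        exp[:nz, :ny, :nx] = dmap.grid
        self._f_exp = sp_fft.rfftn(exp)
        # local energy under a wrapped sphere kernel centered at index 0
        kernel = np.zeros(self.shape, dtype=np.float32)
        r_vox = max(int(round(sphere_radius / dmap.voxel_size)), 2)
        axes = [np.minimum(np.arange(n), n - np.arange(n)) for n in self.shape]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        kernel[zz**2 + yy**2 + xx**2 <= r_vox**2] = 1.0
        energy = sp_fft.irfftn(sp_fft.rfftn(exp * exp) * np.conj(
            sp_fft.rfftn(kernel)), s=self.shape)
        self._local_norm = np.sqrt(np.maximum(energy, 0.0))
        # the sphere must cover the whole model support: Cauchy-Schwarz then
        # bounds the normalized score by 1 and partial-overlap edge
        # placements cannot outrank full overlaps
        self._norm_floor = 1e-6 * float(self._local_norm.max() + 1e-30)

    def best_translation(self, density: np.ndarray, center_index: np.ndarray
                         ) -> tuple[np.ndarray, float]:
        """Best centroid target (physical Å) for a model density patch.

        ``density`` is a small [z, y, x] patch on this map's voxel lattice
        with the model centroid at fractional patch index ``center_index``;
        shift s places patch voxel p on map voxel p + s.
        """
        g = np.zeros(self.shape, dtype=np.float32)
        sz, sy, sx = density.shape
        g[:sz, :sy, :sx] = density
        cross = sp_fft.irfftn(self._f_exp * np.conj(sp_fft.rfftn(g)),
                              s=self.shape)
        g_norm = float(np.sqrt((density.astype(np.float64) ** 2).sum()))
        # normalization sphere sits at the model centroid: shift s puts it at
        # (s + center_index) mod shape
        norm_at_centroid = np.roll(
            self._local_norm,
            shift=tuple(-int(round(c)) for c in center_index),
            axis=(0, 1, 2))
        denom = norm_at_centroid * max(g_norm, 1e-9)
        score = np.divide(cross, denom, out=np.zeros_like(cross),
                          where=denom > self._norm_floor * max(g_norm, 1e-9))
        # keep only shifts whose centroid lands inside the map box
        for ax, n_map in enumerate(self._map_shape):
            s = np.arange(self.shape[ax])
            signed = np.where(s <= self.shape[ax] // 2, s, s - self.shape[ax])
            c = signed + center_index[ax]
            bad = (c < 0) | (c > n_map - 1)
            score[tuple(bad if a == ax else slice(None) for a in range(3))] = -np.inf
        shift = np.unravel_index(np.argmax(score), score.shape)
        best = float(score[shift])
        signed_shift = np.array([
            s if s <= self.shape[ax] // 2 else s - self.shape[ax]
            for ax, s in enumerate(shift)], dtype=np.float64)
        centroid_idx = signed_shift + center_index
        target = self.dmap.index_to_physical(centroid_idx)[0]
        return target, best


class SeedScanner:
    """Per-rotation FFT translation search for one chain on one map."""

    def __init__(self, chain: ChainModel, dmap: DensityMap) -> None:
        self.chain = chain
        self.com = chain.centroid
        self.scan_map = _scan_lattice(dmap, SCAN_VOXEL)
        self.voxel = self.scan_map.voxel_size
        self.centered = chain.coords - self.com
        self.sigma = self.scan_map.resolution / (np.pi * np.sqrt(2.0))
        bounding = (float(np.linalg.norm(self.centered, axis=1).max())
                    + 3.0 * self.sigma)
        # a rotation can put the full bounding diameter on any axis
        patch_max = int(np.ceil(2.0 * bounding / self.voxel)) + 3
        self.scan = _TranslationScan(self.scan_map, patch_max,
                                     sphere_radius=bounding)

    def best_pose(self, rot: Rotation) -> Pose:
        """Pose with this rotation and its FFT-optimal centroid target."""
        from .simulate import simulate_on_grid

        rc = rot.apply(self.centered)
        lo = rc.min(0) - 3.0 * self.sigma
        patch_origin = np.floor(lo / self.voxel) * self.voxel
        n = np.ceil((rc.max(0) + 3.0 * self.sigma - patch_origin) / self.voxel
                    ).astype(int) + 1
        patch = DensityMap(grid=np.zeros((n[2], n[1], n[0]), np.float32),
                           voxel_size=self.voxel, origin=patch_origin,
                           resolution=self.scan_map.resolution)
        density = simulate_on_grid(rc, self.chain.masses, patch)
        center_index = patch.physical_to_index(np.zeros(3))[0]
        target, _ = self.scan.best_translation(density, center_index)
        return Pose(rot.as_quat(), target - self.com)


def init_poses(
    chain: ChainModel,
    dmap: DensityMap,
    angular_step: float = 45.0,
    max_starts: int = MAX_STARTS_DEFAULT,
    scorer: ChainScorer | None = None,
    translation_mode: str = "fft",
    scanner: "SeedScanner | None" = None,
) -> list[Pose]:
    """Multi-start pose seeds for one chain on one (usually low-pass) map.

    Rotation seeds enumerate a deduplicated Euler-angle lattice.  For each
    rotation the translation is chosen by an exhaustive FFT cross-correlation
    scan (``translation_mode="fft"``, the default), which handles maps shared
    by several chains; ``translation_mode="centroid"`` falls back to the
    density-centroid / smoothed-local-maxima heuristic with a composite-score
    prescreen.  At most ``max_starts`` seeds (hard cap 512) are returned,
    ranked by their screening score.
    """
    rotations = euler_rotation_seeds(angular_step)
    com = chain.centroid
    cap = min(max_starts, MAX_STARTS_HARD_CAP)
    poses: list[Pose] = []
    if translation_mode == "fft":
        # per-rotation FFT-optimal translation targets (essential when the
        # map holds several chains and the density centroid lies between
        # them), alongside the density-centroid target for every rotation
        scanner = scanner or SeedScanner(chain, dmap)
        poses.extend(scanner.best_pose(rot) for rot in rotations)
        targets = [density_centroid(dmap)]
    else:
        targets = _translation_seeds(chain, dmap)
    poses.extend(
        Pose(rot.as_quat(), target - com)
        for target in targets
        for rot in rotations
    )
    if len(poses) > cap:
        scorer = scorer or ChainScorer(chain, dmap)
        scores = np.array([scorer.score_pose(p)["composite"] for p in poses])
        order = np.argsort(-scores)[:cap]
        poses = [poses[i] for i in order]
    return poses


# ---------------------------------------------------------------------------
# L-BFGS rigid-body refinement


def _pose_from_params(x: np.ndarray, start: Pose, rot_scale: float) -> Pose:
    """Pose from the optimizer chart: translation Å + rotvec/rot_scale.

    Rotation parameters are expressed in units of ``rot_scale`` (the chain's
    gyration radius): a unit step in any of the six parameters then moves
    atoms by comparable distances, without which the optimizer pours all its
    effort into the (much more sensitive) rotational directions and leaves
    the translation almost untouched for elongated chains.
    """
    delta_rot = Rotation.from_rotvec(x[3:6] / rot_scale)
    return Pose((delta_rot * start.rotation).as_quat(), start.translation + x[:3])


def refine_pose_lbfgs(
    chain: ChainModel,
    dmap: DensityMap,
    start: Pose,
    scorer: ChainScorer | None = None,
    maxiter: int = 200,
    ftol: float = 1e-5,
    gradient: str = "central",
    trans_bound: float = 15.0,
    rot_bound_deg: float = 45.0,
    center: np.ndarray | None = None,
) -> FitCandidate:
    """Locally maximize the composite score over the 6 rigid-body parameters.

    The rotation is parameterized as an axis-angle chart centered at the
    start rotation, scaled by the gyration radius so all six parameters have
    comparable sensitivity; gradients are finite differences (0.25 Å / 1°),
    central by default (``gradient="forward"`` is the cheaper one-sided
    scheme used by the coarse triage pass).  ``trans_bound`` (Å) and
    ``rot_bound_deg`` box the search around the start pose: refinement is a
    local, within-basin operation — the multi-start machinery owns the
    global search, and unbounded line searches readily hop into unrelated
    basins.  The returned candidate never scores below the start pose.
    """
    scorer = scorer or ChainScorer(chain, dmap)
    # rotations act about the chain centroid unless an explicit pivot is
    # given (domain refinement pivots about the inter-domain hinge, where a
    # hinge swing is pure rotation)
    com = chain.centroid if center is None else np.asarray(center, float)
    coords0 = chain.coords
    rot_scale = max(radius_of_gyration(coords0, weights=chain.masses), 1.0)
    if center is not None:
        rot_scale = max(rot_scale,
                        float(np.linalg.norm(coords0 - com, axis=1).max()) / 2)
    # finite-difference steps: 0.25 Å translations, 1° rotations
    steps = np.array([FD_TRANS_STEP] * 3
                     + [np.deg2rad(FD_ROT_STEP_DEG) * rot_scale] * 3)

    def value(x: np.ndarray) -> float:
        pose = _pose_from_params(x, start, rot_scale)
        return -scorer.score(pose.apply(coords0, com))["composite"]

    def value_and_grad(x: np.ndarray):
        f0 = value(x)
        grad = np.empty(6)
        for i in range(6):
            e = np.zeros(6)
            e[i] = steps[i]
            if gradient == "forward":
                grad[i] = (value(x + e) - f0) / steps[i]
            else:
                grad[i] = (value(x + e) - value(x - e)) / (2 * steps[i])
        return f0, grad

    x0 = np.zeros(6)
    start_score = scorer.score(start.apply(coords0, com))
    if not np.isfinite(start_score["composite"]):
        return FitCandidate(pose=start, composite=-np.inf, global_cc=0.0,
                            mean_local_cc=0.0, ifsc=0.0, converged=False)
    rb = np.deg2rad(rot_bound_deg) * rot_scale
    bounds = [(-trans_bound, trans_bound)] * 3 + [(-rb, rb)] * 3
    result = optimize.minimize(
        value_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-12},
    )
    refined_pose = _pose_from_params(result.x, start, rot_scale)
    refined = scorer.score(refined_pose.apply(coords0, com))
    if refined["composite"] < start_score["composite"]:
        refined_pose, refined = start, start_score  # monotone-improvement gate
    return FitCandidate(
        pose=refined_pose,
        composite=refined["composite"],
        global_cc=refined["global_cc"],
        mean_local_cc=refined["mean_local_cc"],
        ifsc=refined["ifsc"],
        converged=bool(result.success) or result.status == 1,
    )


def _coarse_chain(chain: ChainModel) -> ChainModel:
    """One representative atom per residue for the low-pass triage stage.

    At the triage resolution (≥ 15 Å) sub-residue detail contributes nothing
    to the correlation; a Cα/C3' trace quarters the splat cost.  The trace is
    shifted so its centroid coincides with the full chain's, making poses
    directly transferable between the two representations.
    """
    idx = chain.representative_atom_indices()
    coords = chain.coords[idx]
    coords = coords + (chain.centroid - coords.mean(axis=0))
    return ChainModel(
        chain_id=chain.chain_id,
        kind=chain.kind,
        residue_names=list(chain.residue_names),
        residue_seqids=chain.residue_seqids,
        atom_names=chain.atom_names[idx],
        elements=chain.elements[idx],
        coords=coords,
        atom_residue=np.arange(chain.n_residues),
        rigid=chain.rigid,
    )


def _dedup_candidates(cands: list[FitCandidate]) -> list[FitCandidate]:
    kept: list[FitCandidate] = []
    for cand in sorted(cands, key=lambda c: -c.composite):
        dup = any(
            cand.pose.translation_distance_to(k.pose) < DEDUP_TRANSLATION
            and cand.pose.rotation_angle_to(k.pose) < DEDUP_ROTATION
            for k in kept
        )
        if not dup:
            kept.append(cand)
    return kept


RETRY_ANGULAR_STEP = 30.0  # finer lattice for escalated hard cases
RETRY_THRESHOLD_DEFAULT = 0.75
RETRY_MAX_STARTS = 32


def fit_chain(
    chain: ChainModel,
    dmap: DensityMap,
    angular_step: float = 45.0,
    max_starts: int = MAX_STARTS_DEFAULT,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    maxiter: int = 200,
    coarse_iters: int = 30,
    retry_threshold: float | None = RETRY_THRESHOLD_DEFAULT,
) -> FitResult:
    """Multi-start rigid fit of one chain: refine, deduplicate, keep top 5.

    Three stages: (1) the Euler-lattice starts are prescreened with a cheap
    CC-only score against a low-pass copy of the map; (2) every surviving
    start gets a short L-BFGS pull-in on that low-pass map, whose rotational
    basin is wide enough to reach the truth basin from a coarse grid point;
    (3) the best deduplicated basins are polished to convergence on the
    full-resolution map with the full composite score.

    Hard-case escalation: when the best composite stays below
    ``retry_threshold`` (a value no acceptable fit should score under), the
    whole search is repeated once on a finer 30° rotation lattice at ~3×
    cost and the candidate lists are merged.  Elongated chains occasionally
    need this: their coarse-stage landscape carries broad ridges of
    out-of-register local optima that a 45° lattice cannot bracket.
    """
    result = _fit_chain_once(chain, dmap, angular_step, max_starts, weights,
                             maxiter, coarse_iters)
    if (retry_threshold is not None
            and result.best.composite < retry_threshold
            and angular_step > RETRY_ANGULAR_STEP):
        finer = _fit_chain_once(chain, dmap, RETRY_ANGULAR_STEP,
                                max(max_starts, RETRY_MAX_STARTS), weights,
                                maxiter, coarse_iters)
        merged = _dedup_candidates(result.candidates + finer.candidates)
        result = FitResult(chain_id=chain.chain_id, candidates=merged)
    return result


def _fit_chain_once(
    chain: ChainModel,
    dmap: DensityMap,
    angular_step: float,
    max_starts: int,
    weights: tuple[float, float, float],
    maxiter: int,
    coarse_iters: int,
) -> FitResult:
    low = lowpass_map(dmap)
    coarse_chain = _coarse_chain(chain)
    low_scorer = ChainScorer(coarse_chain, low, weights=(1.0, 0.0, 0.0))
    scorer = ChainScorer(chain, dmap, weights=weights)
    scanner = SeedScanner(coarse_chain, low)
    starts = init_poses(coarse_chain, low, angular_step=angular_step,
                        max_starts=max_starts, scorer=low_scorer,
                        scanner=scanner)
    coarse = [
        refine_pose_lbfgs(coarse_chain, low, s, scorer=low_scorer,
                          maxiter=coarse_iters, gradient="forward")
        for s in starts
    ]
    coarse = _dedup_candidates([c for c in coarse if np.isfinite(c.composite)])
    # alternate once between local refinement and the exhaustive translation
    # scan: refinement fixes the rotation, after which the scan snaps the
    # translation onto the global optimum for that orientation (local steps
    # alone move translation very slowly on blurred elongated densities)
    rescanned = []
    for cand in coarse[:TOP_K]:
        best = cand
        alt = scanner.best_pose(cand.pose.rotation)
        restart = (alt if low_scorer.score_pose(alt)["composite"]
                   > low_scorer.score_pose(best.pose)["composite"]
                   else best.pose)
        # a fresh L-BFGS leg: the first one may simply have run out of
        # iterations mid-descent, and restarting clears its curvature memory
        redo = refine_pose_lbfgs(coarse_chain, low, restart, scorer=low_scorer,
                                 maxiter=coarse_iters, gradient="forward")
        if redo.composite > best.composite:
            best = redo
        rescanned.append(best)
    rescanned = _dedup_candidates(rescanned)
    # middle rung of the resolution ladder: ~2× the native resolution pulls
    # candidates from the triage basin (several degrees / a few Å off) into
    # the narrow native basin before the expensive full-score polish
    medium = lowpass_map(dmap, resolution=2.0 * dmap.resolution,
                         voxel=max(dmap.voxel_size, 3.0))
    med_scorer = ChainScorer(chain, medium, weights=(1.0, 0.0, 0.0))
    refined_mid = [
        refine_pose_lbfgs(chain, medium, c.pose, scorer=med_scorer,
                          maxiter=max(2 * coarse_iters, 60), gradient="forward")
        for c in rescanned[:TOP_K]
    ]
    refined_mid = _dedup_candidates(refined_mid)
    # the leading basin is polished to convergence; runners-up (kept for
    # assembly-stage diversity) get a capped polish
    candidates = [
        refine_pose_lbfgs(chain, dmap, c.pose, scorer=scorer,
                          maxiter=maxiter if rank == 0 else min(25, maxiter))
        for rank, c in enumerate(refined_mid[:TOP_K])
    ]
    candidates = [c for c in candidates if np.isfinite(c.composite)]
    if not candidates:
        raise FitFailure(f"chain {chain.chain_id}: no pose with a finite score")
    return FitResult(chain_id=chain.chain_id, candidates=_dedup_candidates(candidates))


# ---------------------------------------------------------------------------
# Iterative fitting with masking


def iterative_fit_all(
    chains: list[ChainModel],
    protein_map: DensityMap,
    na_map: DensityMap | None,
    schedule: FitSchedule | None = None,
    mask_radius: float = 3.0,
    use_masking: bool = True,
    angular_step: float = 45.0,
    max_starts: int = MAX_STARTS_DEFAULT,
) -> dict[str, FitResult]:
    """Fit all chains longest-first with masking and a decaying threshold.

    A chain whose best global CC reaches the current threshold is accepted
    and its density is masked out of its kind's working map before later
    chains are fitted.  Unaccepted chains are refitted each round at a lower
    threshold; after the final round every chain has a result, those that
    never reached the floor flagged as low-confidence.
    """
    schedule = schedule or FitSchedule()
    working = {PROTEIN: protein_map.copy(),
               NA: na_map.copy() if na_map is not None else None}
    map_version = {PROTEIN: 0, NA: 0}
    order = sorted(chains, key=lambda c: -c.n_residues)
    results: dict[str, FitResult] = {}
    fitted_on_version: dict[str, int] = {}
    pending = list(order)
    for round_no, threshold in enumerate(schedule.thresholds(), start=1):
        still_pending: list[ChainModel] = []
        for chain in pending:
            wmap = working[chain.kind]
            if wmap is None or not np.any(wmap.grid > 0):
                still_pending.append(chain)
                continue
            # refit only when the working map changed since the last attempt
            # (a lower threshold alone cannot change the fit result)
            if fitted_on_version.get(chain.chain_id) == map_version[chain.kind]:
                result = results[chain.chain_id]
            else:
                try:
                    result = fit_chain(chain, wmap, angular_step=angular_step,
                                       max_starts=max_starts,
                                       retry_threshold=threshold)
                except (FitFailure, DegenerateMapError):
                    still_pending.append(chain)
                    continue
                result.rounds = round_no
                results[chain.chain_id] = result
                fitted_on_version[chain.chain_id] = map_version[chain.kind]
            if result.best.global_cc >= threshold:
                result.well_fitted = True
                if use_masking:
                    placed = chain.transformed(result.best.pose)
                    working[chain.kind] = mask_region(
                        wmap, placed.coords, radius=mask_radius)
                    map_version[chain.kind] += 1
            else:
                still_pending.append(chain)
        pending = still_pending
        if not pending:
            break
    for chain in pending:
        if chain.chain_id not in results:
            warnings.warn(
                f"chain {chain.chain_id}: no fit obtained in any round",
                stacklevel=2,
            )
        else:
            warnings.warn(
                f"chain {chain.chain_id}: best CC "
                f"{results[chain.chain_id].best.global_cc:.3f} never reached the "
                f"threshold floor {schedule.threshold_floor}; low confidence",
                stacklevel=2,
            )
    return results


# ---------------------------------------------------------------------------
# Domain-level flexible refinement


def _domain_subchain(chain: ChainModel, residues: np.ndarray) -> ChainModel:
    atom_mask = np.isin(chain.atom_residue, residues)
    res_map = {int(r): i for i, r in enumerate(residues)}
    return ChainModel(
        chain_id=f"{chain.chain_id}@dom",
        kind=chain.kind,
        residue_names=[chain.residue_names[r] for r in residues],
        residue_seqids=chain.residue_seqids[residues],
        atom_names=chain.atom_names[atom_mask],
        elements=chain.elements[atom_mask],
        coords=chain.coords[atom_mask],
        atom_residue=np.array([res_map[int(r)]
                               for r in chain.atom_residue[atom_mask]]),
    )


def _linker_gaps_ok(chain: ChainModel, coords: np.ndarray,
                    max_gap: float) -> bool:
    """Check Cα–Cα distance across every domain boundary."""
    labels = chain.domains.residue_labels
    rep = chain.representative_atom_indices()
    for i in range(chain.n_residues - 1):
        if labels[i] != labels[i + 1]:
            d = np.linalg.norm(coords[rep[i]] - coords[rep[i + 1]])
            if d >= max_gap:
                return False
    return True


def domain_refine(
    chain: ChainModel,
    dmap: DensityMap,
    pose: Pose,
    linker_max_gap: float = 8.0,
    maxiter: int = 100,
) -> ChainModel:
    """Flexible (per-domain rigid) refinement of a rigidly fitted protein.

    Starting from the whole-chain pose, each domain is refined independently
    with 6-DOF L-BFGS against the map.  A domain move is accepted only when
    the full-chain composite score improves and no inter-domain linker is
    stretched beyond ``linker_max_gap`` Å; otherwise the rigid placement is
    kept (refusing to move is a valid outcome).
    """
    if chain.kind != PROTEIN:
        raise ParameterError("domain refinement applies to protein chains only")
    placed = chain.transformed(pose)
    if chain.domains is None or chain.domains.n_domains < 2:
        return placed
    # a misoriented domain can start far outside the narrow native basin (a
    # 30 degree hinge swing displaces a domain centroid by tens of Å), so
    # each domain is pulled in down its own resolution ladder with
    # hinge-sized trust bounds before the native polish
    coarse = lowpass_map(dmap)
    medium = lowpass_map(dmap, resolution=2.0 * dmap.resolution,
                         voxel=max(dmap.voxel_size, 3.0))
    full_scorer = ChainScorer(placed, dmap)
    current = placed.coords.copy()
    best_full = full_scorer.score(current)["composite"]
    rep = placed.representative_atom_indices()
    for label in chain.domains.domain_labels():
        residues = chain.domains.domain_residues(label)
        sub = _domain_subchain(placed.with_coords(current), residues)
        # pivot at the hinge: the domain-boundary residue adjacent to the
        # rest of the chain, so a hinge swing is (nearly) pure rotation
        lo, hi = int(residues.min()), int(residues.max())
        anchor_res = lo if lo > 0 else hi
        anchor = current[rep[anchor_res]]
        pose = Pose.identity()
        for rung, bounds in ((coarse, (10.0, 60.0)), (medium, (8.0, 45.0))):
            cand = refine_pose_lbfgs(
                sub, rung, pose,
                scorer=ChainScorer(sub, rung, weights=(1.0, 0.0, 0.0)),
                maxiter=maxiter, gradient="forward",
                trans_bound=bounds[0], rot_bound_deg=bounds[1],
                center=anchor)
            pose = cand.pose
        cand = refine_pose_lbfgs(sub, dmap, pose,
                                 scorer=ChainScorer(sub, dmap),
                                 maxiter=maxiter, center=anchor)
        moved = cand.pose.apply(sub.coords, anchor)
        trial = current.copy()
        trial[np.isin(chain.atom_residue, residues)] = moved
        if not _linker_gaps_ok(placed, trial, linker_max_gap):
            continue
        trial_score = full_scorer.score(trial)["composite"]
        if trial_score > best_full:
            current = trial
            best_full = trial_score
    return placed.with_coords(current)
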