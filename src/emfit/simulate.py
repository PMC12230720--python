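"""Synthetic protein/nucleic-acid complexes and simulated density maps.

This module is the package's in-repo stand-in for experimental inputs: it
builds toy multi-chain complexes with plausible backbone geometry (ideal
α-helices, ideal B-form duplex backbones), simulates density maps from the
coordinates with an isotropic Gaussian kernel, and emits ground-truth voxel
labels and placement poses so every downstream stage can be tested without
external data.

The Gaussian kernel width is σ = resolution / (π √2) — one of several
community conventions for relating nominal resolution to real-space blur —
with amplitude proportional to atomic number.  Hydrogens are never generated:
maps at the resolutions modeled here do not resolve them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ParameterError, PlacementError
from .map_core import DensityMap
from .segmentation import LABEL_NA, LABEL_OTHER, LABEL_PROTEIN, LabelVolume
from .structure import (
    NA,
    PROTEIN,
    ChainModel,
    ComplexModel,
    Pose,
)

KERNEL_SIGMA_FACTOR = 1.0 / (np.pi * np.sqrt(2.0))  # sigma = resolution * this
LABEL_RADIUS = 3.0  # Å, proximity of a voxel to backbone atoms for labeling

__all__ = [
    "SyntheticComplexSpec",
    "make_toy_complex",
    "make_helix_chain",
    "make_duplex_chain",
    "simulate_map",
    "simulate_on_grid",
    "add_noise",
    "ground_truth_labels",
]


@dataclass
class SyntheticComplexSpec:
    """Recipe for a toy complex.

    Defaults describe the standard test condition used throughout the
    package: two helical protein chains (150 and 90 residues) bound to one
    rigid 30-bp DNA duplex, mapped at 5 Å with 1 Å voxels.  ``kinks`` maps a
    protein-chain index to ``(residue_position, hinge_angle_deg)`` to create
    two-domain chains.
    """

    protein_lengths: tuple[int, ...] = (150, 90)
    na_lengths: tuple[int, ...] = (30,)  # base pairs per duplex
    resolution: float = 5.0
    voxel_size: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    gap: float = 4.0  # minimum inter-chain heavy-atom distance, Å
    kinks: dict | None = None  # None = automatic asymmetric kinks (see below)

    def __post_init__(self) -> None:
        for n in (*self.protein_lengths, *self.na_lengths):
            if n < 10:
                raise ParameterError("chains need at least 10 residues/base pairs")


# ---------------------------------------------------------------------------
# Chain builders

# α-helix parameters: 1.5 Å rise and 100° turn per residue, Cα radius 2.3 Å
# (consecutive Cα–Cα comes out at ~3.83 Å)
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3


def _helix_ca(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TURN * t),
            _HELIX_RADIUS * np.sin(_HELIX_TURN * t),
            _HELIX_RISE * t,
        ],
        axis=1,
    )


def _backbone_from_ca(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plausible N, C, O positions from a Cα trace (ideal bond lengths)."""
    n_res = len(ca)
    prev_dir = np.empty_like(ca)
    next_dir = np.empty_like(ca)
    prev_dir[1:] = ca[:-1] - ca[1:]
    prev_dir[0] = ca[0] - ca[1]
    next_dir[:-1] = ca[1:] - ca[:-1]
    next_dir[-1] = ca[-1] - ca[-2]
    prev_dir /= np.linalg.norm(prev_dir, axis=1, keepdims=True)
    next_dir /= np.linalg.norm(next_dir, axis=1, keepdims=True)
    n_atoms = ca + 1.46 * prev_dir
    c_atoms = ca + 1.52 * next_dir
    radial = ca.copy()
    radial[:, 2] = 0
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    o_atoms = c_atoms + 1.23 * radial / norms
    return n_atoms, c_atoms, o_atoms


def make_helix_chain(
    chain_id: str,
    n_res: int,
    kink_at: int | None = None,
    kink_angle_deg: float = 0.0,
    kinks: list[tuple[int, float, tuple[float, float, float]]] | None = None,
    sequence: list[str] | None = None,
) -> ChainModel:
    """Ideal α-helical backbone chain (N, CA, C, O per residue).

    ``kink_at`` bends the helix at that residue position by
    ``kink_angle_deg`` about an axis perpendicular to the helix, producing a
    clean two-domain topology for hinge experiments.  ``kinks`` generalizes
    this to several ``(position, angle_deg, axis)`` bends, folding long
    chains into compact asymmetric shapes.
    """
    ca = _helix_ca(n_res)
    if kinks is None and kink_at is not None:
        kinks = [(kink_at, kink_angle_deg, (1.0, 0.0, 0.0))]
    for pos, angle, axis in kinks or []:
        if not 0 < pos < n_res:
            continue
        hinge = ca[pos].copy()
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle) * axis)
        # rigid rotation about the hinge Cα preserves every bond length
        ca[pos:] = hinge + rot.apply(ca[pos:] - hinge)
    n_atoms, c_atoms, o_atoms = _backbone_from_ca(ca)
    coords = np.empty((4 * n_res, 3))
    coords[0::4] = n_atoms
    coords[1::4] = ca
    coords[2::4] = c_atoms
    coords[3::4] = o_atoms
    names = np.array(["N", "CA", "C", "O"] * n_res, dtype=object)
    elements = np.array(["N", "C", "C", "O"] * n_res, dtype=object)
    res_names = sequence if sequence is not None else ["ALA"] * n_res
    return ChainModel(
        chain_id=chain_id,
        kind=PROTEIN,
        residue_names=list(res_names),
        residue_seqids=np.arange(1, n_res + 1),
        atom_names=names,
        elements=elements,
        coords=coords,
        atom_residue=np.repeat(np.arange(n_res), 4),
    )


# B-form duplex: 3.4 Å rise and 36° twist per base pair; backbone atoms laid
# out on a ~9 Å radius with small per-atom angular/axial offsets
_NA_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
_NA_TEMPLATE = (  # (radius Å, extra angle deg, extra rise Å) per backbone atom
    (9.0, 0.0, 0.0),
    (8.6, 6.0, 0.4),
    (8.2, 12.0, 0.8),
    (7.8, 18.0, 1.2),
    (7.9, 24.0, 1.7),
    (8.6, 30.0, 2.2),
)
_NA_RISE = 3.4
_NA_TWIST = 36.0
_COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG"}


def _strand_coords(n_bp: int, phase_deg: float, antiparallel: bool) -> np.ndarray:
    coords = np.empty((6 * n_bp, 3))
    for j in range(n_bp):
        base_angle = _NA_TWIST * j + phase_deg
        base_z = _NA_RISE * j
        for k, (radius, dang, dz) in enumerate(_NA_TEMPLATE):
            ang = np.deg2rad(base_angle + (-dang if antiparallel else dang))
            coords[6 * j + k] = (
                radius * np.cos(ang),
                radius * np.sin(ang),
                base_z + (-dz if antiparallel else dz),
            )
    return coords


def make_duplex_chain(chain_id: str, n_bp: int, rng: np.random.Generator) -> ChainModel:
    """Rigid double-stranded B-form DNA backbone as a single chain unit."""
    strand1 = _strand_coords(n_bp, 0.0, antiparallel=False)
    strand2 = _strand_coords(n_bp, 140.0, antiparallel=True)[::-1]
    seq1 = [str(rng.choice(["DA", "DT", "DG", "DC"])) for _ in range(n_bp)]
    seq2 = [_COMPLEMENT[s] for s in reversed(seq1)]
    coords = np.concatenate([strand1, strand2])
    n_res = 2 * n_bp
    return ChainModel(
        chain_id=chain_id,
        kind=NA,
        residue_names=seq1 + seq2,
        residue_seqids=np.arange(1, n_res + 1),
        atom_names=np.array(list(_NA_ATOMS) * n_res, dtype=object),
        elements=np.array(["P", "O", "C", "C", "C", "O"] * n_res, dtype=object),
        coords=coords,
        atom_residue=np.repeat(np.arange(n_res), 6),
        rigid=True,
    )


# ---------------------------------------------------------------------------
# Layout


def _bounding_radius(coords: np.ndarray) -> float:
    c = coords.mean(axis=0)
    return float(np.linalg.norm(coords - c, axis=1).max())


def make_toy_complex(spec: SyntheticComplexSpec) -> ComplexModel:
    """Build and place the chains of a toy complex.

    Chains are placed sequentially with random orientations at random contact
    distances from the growing assembly, rejecting layouts with any
    inter-chain heavy-atom pair closer than ``spec.gap`` (1000 attempts,
    then ``PlacementError``).  The pose that carried each chain from its
    build frame into the layout is recorded in
    ``provenance["truth_poses"]``.
    """
    rng = np.random.default_rng(spec.seed)
    built: list[ChainModel] = []
    chain_ids = [chr(ord("A") + i)
                 for i in range(len(spec.protein_lengths) + len(spec.na_lengths))]
    idx = 0
    for i, n_res in enumerate(spec.protein_lengths):
        if spec.kinks is None:
            # default: fold each protein helix at one or two asymmetric
            # off-center kinks.  A perfectly straight ideal helix is almost
            # invariant under its own screw motion and an end-over-end dyad
            # (pose recovery would be ill-posed at these resolutions), and a
            # 150-residue straight helix is a 225 Å rod unlike any real
            # chain; the bends give compact, uniquely oriented shapes closer
            # to real multi-domain proteins
            if n_res >= 100:
                kinks = [(int(0.35 * n_res), 55.0 + 10.0 * i, (1.0, 0, 0)),
                         (int(0.70 * n_res), 65.0, (0.0, 1.0, 0))]
            elif n_res >= 40:
                kinks = [(int(0.38 * n_res), 50.0 + 15.0 * i, (1.0, 0, 0))]
            else:
                kinks = []
        else:
            kink = spec.kinks.get(i)
            kinks = [(kink[0], kink[1], (1.0, 0, 0))] if kink is not None else []
        chain = make_helix_chain(chain_ids[idx], n_res, kinks=kinks)
        built.append(chain)
        idx += 1
    for n_bp in spec.na_lengths:
        built.append(make_duplex_chain(chain_ids[idx], n_bp, rng))
        idx += 1

    placed: list[ChainModel] = []
    truth_poses: dict[str, Pose] = {}
    placed_tree: cKDTree | None = None
    placed_coords: list[np.ndarray] = []
    for chain in built:
        for attempt in range(1000):
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat))
            local = rot.apply(chain.coords - chain.centroid)
            if not placed:
                candidate = local  # anchor the assembly at the origin
                translation = -chain.centroid
            else:
                # step the chain outward along a random direction until the
                # gap constraint holds: chains end up in contact rather than
                # at bounding-sphere distance (keeps elongated complexes
                # compact and the map box small)
                anchor = placed_coords_all.mean(axis=0)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                candidate = None
                for dist in np.arange(0.0, 2.0 * assembly_radius + 120.0, 2.0):
                    trial = local + anchor + direction * dist
                    if placed_tree.query(trial, k=1)[0].min() >= spec.gap:
                        candidate = trial
                        translation = anchor + direction * dist - chain.centroid
                        break
                if candidate is None:
                    continue
            pose = Pose(rot.as_quat(), translation)
            placed.append(chain.with_coords(candidate))
            truth_poses[chain.chain_id] = pose
            placed_coords.append(candidate)
            placed_coords_all = np.concatenate(placed_coords)
            assembly_radius = _bounding_radius(placed_coords_all)
            placed_tree = cKDTree(placed_coords_all)
            break
        else:
            raise PlacementError(
                f"could not place chain {chain.chain_id} with a {spec.gap} Å gap "
                "in 1000 attempts; use fewer/smaller chains or a larger gap"
            )
    return ComplexModel(chains=placed, provenance={"truth_poses": truth_poses,
                                                   "spec": spec})


# ---------------------------------------------------------------------------
# Map simulation


def _gaussian_splat(
    grid: np.ndarray,
    dmap_origin: np.ndarray,
    voxel: float,
    coords: np.ndarray,
    weights: np.ndarray,
    sigma: float,
    cutoff_sigmas: float,
) -> None:
    """Accumulate isotropic Gaussians into ``grid`` (in place), [z,y,x] order."""
    nz, ny, nx = grid.shape
    r = cutoff_sigmas * sigma
    noff = int(np.ceil(r / voxel))
    off = np.arange(-noff, noff + 1)
    dz, dy, dx = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([dz.ravel(), dy.ravel(), dx.ravel()], axis=1)  # (M, 3)
    # fractional voxel index of each atom, (z, y, x)
    frac = (coords[:, ::-1] - dmap_origin[::-1]) / voxel
    base = np.floor(frac + 0.5).astype(np.int64)  # nearest voxel to each atom
    vox = base[:, None, :] + offsets[None, :, :]  # (N, M, 3)
    delta = (vox - frac[:, None, :]) * voxel
    d2 = np.einsum("nmk,nmk->nm", delta, delta)
    vals = weights[:, None] * np.exp(-d2 / (2.0 * sigma * sigma))
    mask = (d2 <= r * r) & np.all((vox >= 0) & (vox < (nz, ny, nx)), axis=2)
    vox = vox[mask]
    flat = (vox[:, 0] * ny + vox[:, 1]) * nx + vox[:, 2]
    grid += np.bincount(flat, weights=vals[mask],
                        minlength=grid.size).reshape(grid.shape)


def simulate_on_grid(
    coords: np.ndarray,
    weights: np.ndarray,
    like: DensityMap,
    resolution: float | None = None,
    cutoff_sigmas: float = 3.0,
) -> np.ndarray:
    """Simulate model density on an existing map's lattice; returns the grid."""
    res = like.resolution if resolution is None else resolution
    sigma = res * KERNEL_SIGMA_FACTOR
    grid = np.zeros(like.grid.shape, dtype=np.float64)
    _gaussian_splat(grid, like.origin, float(like.voxel_size), coords,
                    np.asarray(weights, dtype=np.float64), sigma, cutoff_sigmas)
    return grid.astype(np.float32)


def simulate_map(
    model: ComplexModel | ChainModel,
    resolution: float = 5.0,
    voxel_size: float = 1.0,
    pad: float = 8.0,
    cutoff_sigmas: float = 3.0,
) -> DensityMap:
    """Simulate a density map from atomic coordinates.

    Each heavy atom contributes an isotropic Gaussian of width
    σ = resolution/(π √2) and amplitude equal to its atomic number; the box
    extends ``pad`` Å beyond the model on every side.  Requires
    ``resolution >= 2 * voxel_size`` (Nyquist).
    """
    if resolution < 2.0 * voxel_size:
        raise ParameterError(
            f"resolution {resolution} Å violates Nyquist for {voxel_size} Å voxels"
        )
    chains = model.chains if isinstance(model, ComplexModel) else [model]
    coords = np.concatenate([c.coords for c in chains])
    weights = np.concatenate([c.masses for c in chains])
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    origin = np.floor(lo / voxel_size) * voxel_size
    n_xyz = np.ceil((hi - origin) / voxel_size).astype(int) + 1
    dmap = DensityMap(
        grid=np.zeros((n_xyz[2], n_xyz[1], n_xyz[0]), dtype=np.float32),
        voxel_size=float(voxel_size),
        origin=origin,
        resolution=float(resolution),
    )
    dmap.grid = simulate_on_grid(coords, weights, dmap, resolution, cutoff_sigmas)
    return dmap


def add_noise(dmap: DensityMap, noise_sigma: float, seed: int) -> DensityMap:
    """Add voxel-wise Gaussian noise with σ = noise_sigma × map maximum.

    Negative values are clipped to zero (density maps are used thresholded).
    The returned map carries a recommended contour level of 2σ above the old
    one — the synthetic analogue of the noise-floor contour deposited
    alongside experimental maps.
    """
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be nonnegative")
    out = dmap.copy()
    if noise_sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    scale = noise_sigma * float(dmap.grid.max())
    if scale > 0:
        noisy = out.grid + rng.normal(0.0, scale, size=out.grid.shape)
        out.grid = np.clip(noisy, 0.0, None).astype(np.float32)
        out.contour_level = float(dmap.contour_level + 2.0 * scale)
    return out


# ---------------------------------------------------------------------------
# Segmentation training data


def make_segmentation_dataset(
    n_chunks: int,
    seed: int,
    resolution: float = 5.0,
    noise_sigma: float = 0.0,
):
    """Synthetic (density chunk, label chunk) pairs for segmenter training.

    Each source map holds one kinked helical protein (40–90 residues) and one
    B-form duplex (12–22 bp) at random relative placement, simulated at the
    given resolution on the 1 Å lattice, normalized, and labeled from the
    ground-truth geometry.  Maps are generated until at least ``n_chunks``
    non-empty 64³ chunks exist; the list is truncated to exactly ``n_chunks``.
    """
    from .map_core import normalize
    from .segmentation import prepare_training_chunks

    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < n_chunks:
        spec = SyntheticComplexSpec(
            protein_lengths=(int(rng.integers(40, 91)),),
            na_lengths=(int(rng.integers(12, 23)),),
            resolution=resolution,
            voxel_size=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        model = make_toy_complex(spec)
        dmap = simulate_map(model, resolution=resolution, voxel_size=1.0)
        if noise_sigma > 0:
            dmap = add_noise(dmap, noise_sigma, seed=int(rng.integers(0, 2**31 - 1)))
        dmap = normalize(dmap)
        labels = ground_truth_labels(model, dmap)
        pairs.extend(prepare_training_chunks(dmap, labels))
    return pairs[:n_chunks]


# ---------------------------------------------------------------------------
# Ground-truth labels


def ground_truth_labels(model: ComplexModel, dmap: DensityMap) -> LabelVolume:
    """Label map voxels by proximity to backbone atoms.

    Voxels within 3 Å of any backbone atom get the class of the nearest one
    (protein → 0, nucleic acid → 1); all remaining voxels are background (2).
    """
    prot = [c.coords[c.backbone_mask] for c in model.chains if c.kind == PROTEIN]
    na = [c.coords[c.backbone_mask] for c in model.chains if c.kind == NA]
    nz, ny, nx = dmap.grid.shape
    idx = np.argwhere(np.ones(dmap.grid.shape, dtype=bool))
    xyz = dmap.index_to_physical(idx)
    d_prot = np.full(len(xyz), np.inf)
    d_na = np.full(len(xyz), np.inf)
    if prot:
        d_prot = cKDTree(np.concatenate(prot)).query(
            xyz, k=1, distance_upper_bound=LABEL_RADIUS + 1e-9)[0]
    if na:
        d_na = cKDTree(np.concatenate(na)).query(
            xyz, k=1, distance_upper_bound=LABEL_RADIUS + 1e-9)[0]
    labels = np.full(len(xyz), LABEL_OTHER, dtype=np.int8)
    near_prot = d_prot <= LABEL_RADIUS
    near_na = d_na <= LABEL_RADIUS
    labels[near_prot] = LABEL_PROTEIN
    labels[near_na & (d_na < d_prot)] = LABEL_NA
    return LabelVolume(labels=labels.reshape(nz, ny, nx))
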