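"""Chain and complex models, rigid-body poses, and domain partitions.

A ``ChainModel`` holds one polymer chain (protein or nucleic acid) as flat
numpy arrays over heavy atoms plus per-residue bookkeeping.  A ``Pose`` is a
rigid-body transform (unit quaternion + translation) acting about the chain's
centroid; with that convention pose composition is simply quaternion
composition plus translation addition.  Structures are read and written with
gemmi (PDB and mmCIF in, PDB out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ClassificationError,
    DegenerateMapError,
    ParameterError,
    StructureFormatError,
)

PROTEIN = "protein"
NA = "na"

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "I", "DI"}

PROTEIN_BACKBONE = {"N", "CA", "C", "O"}
NA_BACKBONE = {"P", "O5'", "C5'", "C4'", "C3'", "O3'"}

# atomic numbers used as Gaussian amplitudes in map simulation and as masses
ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "MG": 12,
    "ZN": 30, "FE": 26, "MN": 25, "K": 19, "NA": 11, "CL": 17, "CA": 20,
}

__all__ = [
    "PROTEIN", "NA", "Pose", "ChainModel", "ComplexModel", "DomainPartition",
    "read_structure", "write_pdb", "classify_chain", "apply_pose",
    "radius_of_gyration", "map_radius_of_gyration", "partition_domains",
]


# ---------------------------------------------------------------------------
# Pose


@dataclass
class Pose:
    """Rigid-body transform: rotate about the chain centroid, then translate.

    ``quat`` is a unit quaternion in scipy's (x, y, z, w) order.  Applying a
    pose maps atom positions x to ``c + R (x - c) + t`` where c is the chain
    centroid at pose time; since rotation preserves the centroid, composing
    poses reduces to quaternion composition and translation addition.
    """

    quat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        q = np.asarray(self.quat, dtype=np.float64)
        n = np.linalg.norm(q)
        if not np.isfinite(n) or n == 0:
            raise ParameterError("pose quaternion must be nonzero and finite")
        self.quat = q / n
        self.translation = np.asarray(self.translation, dtype=np.float64)

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "Pose":
        """Pose from an axis-angle rotation vector (radians)."""
        return cls(Rotation.from_rotvec(np.asarray(rotvec)).as_quat(), translation)

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "Pose":
        """Pose from intrinsic z-y-z Euler angles in degrees."""
        return cls(
            Rotation.from_euler("ZYZ", np.asarray(angles_deg), degrees=True).as_quat(),
            translation,
        )

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quat)

    def compose(self, other: "Pose") -> "Pose":
        """The pose equivalent to applying ``other`` first, then ``self``."""
        return Pose(
            (self.rotation * other.rotation).as_quat(),
            self.translation + other.translation,
        )

    def inverse(self) -> "Pose":
        return Pose(self.rotation.inv().as_quat(), -self.translation)

    def apply(self, coords: np.ndarray, center: np.ndarray) -> np.ndarray:
        return center + self.rotation.apply(coords - center) + self.translation

    def rotation_angle_to(self, other: "Pose") -> float:
        """Relative rotation angle in degrees (double cover handled)."""
        return float(np.degrees((self.rotation * other.rotation.inv()).magnitude()))

    def translation_distance_to(self, other: "Pose") -> float:
        return float(np.linalg.norm(self.translation - other.translation))


# ---------------------------------------------------------------------------
# Chain / complex containers


@dataclass
class ChainModel:
    """One polymer chain as flat heavy-atom arrays plus residue bookkeeping.

    ``atom_residue[i]`` is the 0-based residue position of atom ``i``;
    ``residue_seqids`` carries the deposited (strictly increasing) numbering.
    Nucleic-acid chains (and user-declared duplex units) are always rigid.
    """

    chain_id: str
    kind: str  # PROTEIN or NA
    residue_names: list[str]
    residue_seqids: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    atom_residue: np.ndarray
    rigid: bool = False
    domains: "DomainPartition | None" = None
    source_chain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.residue_seqids = np.asarray(self.residue_seqids, dtype=np.int64)
        self.atom_residue = np.asarray(self.atom_residue, dtype=np.int64)
        if not np.all(np.isfinite(self.coords)):
            raise StructureFormatError(
                f"chain {self.chain_id}: non-finite atom coordinates"
            )
        if len(self.residue_seqids) > 1 and not np.all(
            np.diff(self.residue_seqids) > 0
        ):
            raise StructureFormatError(
                f"chain {self.chain_id}: residue numbering not strictly increasing"
            )
        if self.kind == NA:
            self.rigid = True

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER.get(e.upper(), 6) for e in self.elements],
                        dtype=np.float64)

    @property
    def backbone_mask(self) -> np.ndarray:
        names = PROTEIN_BACKBONE if self.kind == PROTEIN else NA_BACKBONE
        return np.isin(self.atom_names, list(names))

    def representative_atom_indices(self) -> np.ndarray:
        """One representative atom per residue: CA (protein) or C3' (NA).

        Falls back to the first atom of a residue when the named atom is
        missing.
        """
        name = "CA" if self.kind == PROTEIN else "C3'"
        idx = np.full(self.n_residues, -1, dtype=np.int64)
        for i in range(self.n_atoms):
            r = self.atom_residue[i]
            if idx[r] == -1 or self.atom_names[i] == name:
                if idx[r] == -1 or self.atom_names[idx[r]] != name:
                    idx[r] = i
        if np.any(idx < 0):
            raise StructureFormatError(f"chain {self.chain_id}: residue with no atoms")
        return idx

    def representative_coords(self) -> np.ndarray:
        return self.coords[self.representative_atom_indices()]

    def residue_atom_indices(self, position: int) -> np.ndarray:
        return np.nonzero(self.atom_residue == position)[0]

    def transformed(self, pose: Pose) -> "ChainModel":
        return replace(self, coords=pose.apply(self.coords, self.centroid))

    def with_coords(self, coords: np.ndarray) -> "ChainModel":
        return replace(self, coords=np.asarray(coords, dtype=np.float64))


@dataclass
class ComplexModel:
    """A set of placed chains in one physical (map) frame."""

    chains: list[ChainModel]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureFormatError(f"duplicate chain ids: {ids}")

    @property
    def all_coords(self) -> np.ndarray:
        return np.concatenate([c.coords for c in self.chains])

    @property
    def n_residues(self) -> int:
        return sum(c.n_residues for c in self.chains)

    def get_chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


@dataclass
class DomainPartition:
    """Disjoint residue-interval segments covering a chain exactly once.

    ``segments`` is a list of ``(start, stop, label)`` with 0-based inclusive
    residue positions.  Fragments shorter than ``MIN_DOMAIN`` residues are
    merged into a neighbor before construction.
    """

    segments: list[tuple[int, int, int]]
    n_residues: int

    MIN_DOMAIN = 20

    def __post_init__(self) -> None:
        covered = np.full(self.n_residues, -1, dtype=np.int64)
        for start, stop, label in self.segments:
            if start > stop or start < 0 or stop >= self.n_residues:
                raise ParameterError(f"bad domain segment ({start}, {stop})")
            if np.any(covered[start : stop + 1] != -1):
                raise ParameterError("overlapping domain segments")
            covered[start : stop + 1] = label
        if np.any(covered == -1):
            raise ParameterError("domain segments do not cover the chain")
        self.residue_labels = covered

    @property
    def n_domains(self) -> int:
        return len({label for _, _, label in self.segments})

    def domain_residues(self, label: int) -> np.ndarray:
        return np.nonzero(self.residue_labels == label)[0]

    def domain_labels(self) -> list[int]:
        return sorted({label for _, _, label in self.segments})


# ---------------------------------------------------------------------------
# Classification


def classify_chain(chain: ChainModel) -> str:
    """Assign a molecule kind from residue names (backbone atoms as fallback).

    A chain is nucleic acid when the majority of its residues are standard
    nucleotides or carry P/O5'/C1' backbone atoms.  Chains with more than 25%
    of both residue classes are rejected as ambiguous.
    """
    if chain.n_residues < 1:
        raise ParameterError("cannot classify an empty chain")
    names = [n.strip().upper() for n in chain.residue_names]
    n_aa = sum(1 for n in names if n in AMINO_ACIDS)
    n_nt = sum(1 for n in names if n in NUCLEOTIDES)
    n = chain.n_residues
    if n_aa > 0.25 * n and n_nt > 0.25 * n:
        raise ClassificationError(
            f"chain {chain.chain_id}: {n_aa} amino acids and {n_nt} nucleotides; "
            "kind is ambiguous, declare it explicitly"
        )
    if n_nt > n / 2:
        return NA
    if n_aa > n / 2:
        return PROTEIN
    # nonstandard residue names: fall back on characteristic backbone atoms
    na_bb = np.isin(chain.atom_names, ["P", "O5'", "C1'"]).sum()
    return NA if na_bb >= chain.n_residues else PROTEIN


# ---------------------------------------------------------------------------
# Geometry


def apply_pose(chain: ChainModel, pose: Pose) -> ChainModel:
    """Rigidly transform a chain (rotation about its centroid, then shift)."""
    return chain.transformed(pose)


def radius_of_gyration(coords: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted root-mean-square distance of points to their weighted centroid."""
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if len(coords) < 1:
        raise ParameterError("radius_of_gyration needs at least one point")
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, dtype=np.float64)
    w = w / w.sum()
    center = (w[:, None] * coords).sum(axis=0)
    rg2 = float((w * np.sum((coords - center) ** 2, axis=1)).sum())
    if rg2 <= 0:
        warnings.warn("all points coincident; radius of gyration is 0", stacklevel=2)
        return 0.0
    return float(np.sqrt(rg2))


def map_radius_of_gyration(dmap) -> float:
    """Density-weighted radius of gyration of a map's voxel centers (Å)."""
    vals = dmap.grid.astype(np.float64)
    mask = vals > 0
    if not np.any(mask):
        raise DegenerateMapError("map has no positive density")
    idx = np.argwhere(mask)
    xyz = dmap.index_to_physical(idx)
    return radius_of_gyration(xyz, weights=vals[mask])


def density_centroid(dmap) -> np.ndarray:
    """Density-weighted centroid of a map in physical (x, y, z) Å."""
    vals = dmap.grid.astype(np.float64)
    mask = vals > 0
    if not np.any(mask):
        raise DegenerateMapError("map has no positive density")
    idx = np.argwhere(mask)
    xyz = dmap.index_to_physical(idx)
    w = vals[mask]
    return (w[:, None] * xyz).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# Domain partitioning


def _contact_matrix(ca: np.ndarray, cutoff: float = 8.0) -> np.ndarray:
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    contact = (d < cutoff).astype(np.float64)
    np.fill_diagonal(contact, 0.0)
    return contact


def _fiedler_split(contact: np.ndarray) -> np.ndarray:
    """Boolean membership of the second-eigenvector bisection of the graph."""
    deg = contact.sum(axis=1)
    lap = np.diag(deg) - contact
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    return fiedler >= np.median(fiedler)


def _contact_density(contact: np.ndarray, part: np.ndarray) -> tuple[float, float]:
    """(inter, intra) contact density for a boolean bisection."""
    n1, n2 = int(part.sum()), int((~part).sum())
    if n1 == 0 or n2 == 0:
        return np.inf, 0.0
    e_inter = contact[np.ix_(part, ~part)].sum()
    e1 = contact[np.ix_(part, part)].sum() / 2
    e2 = contact[np.ix_(~part, ~part)].sum() / 2
    inter = e_inter / (n1 * n2)
    intra_terms = []
    if n1 > 1:
        intra_terms.append(e1 / (n1 * (n1 - 1) / 2))
    if n2 > 1:
        intra_terms.append(e2 / (n2 * (n2 - 1) / 2))
    intra = float(np.mean(intra_terms)) if intra_terms else 0.0
    return float(inter), intra


def _labels_to_segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous runs of equal labels, merging runs < MIN_DOMAIN residues."""
    runs: list[list[int]] = []  # [start, stop, label]
    for i, lab in enumerate(labels):
        if runs and runs[-1][2] == lab:
            runs[-1][1] = i
        else:
            runs.append([i, i, int(lab)])
    # absorb short runs into the larger neighbor until all are long enough
    min_len = DomainPartition.MIN_DOMAIN
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, (start, stop, _) in enumerate(runs):
            if stop - start + 1 < min_len:
                nbr = k - 1 if k > 0 else k + 1
                if 0 < k < len(runs) - 1:
                    left, right = runs[k - 1], runs[k + 1]
                    nbr = k - 1 if (left[1] - left[0]) >= (right[1] - right[0]) else k + 1
                runs[nbr][0] = min(runs[nbr][0], start)
                runs[nbr][1] = max(runs[nbr][1], stop)
                del runs[k]
                changed = True
                break
    return [(s, e, lab) for s, e, lab in runs]


def partition_domains(
    chain: ChainModel,
    boundaries: np.ndarray | list[int] | None = None,
    contact_cutoff: float = 8.0,
    min_split: int = 60,
    density_ratio: float = 0.1,
) -> DomainPartition:
    """Split a protein chain into compact domains.

    With explicit ``boundaries`` (residue sequence numbers; each starts a new
    domain) the chain is cut exactly there.  Otherwise the Cα contact graph
    (8 Å cutoff) is bisected along its Fiedler vector, recursing while both
    parts keep at least ``min_split`` residues and the inter-part contact
    density stays below ``density_ratio`` × the intra-part density.  This is a
    deliberately simple stand-in for full-featured domain parsers; explicit
    boundaries always win.
    """
    if chain.kind != PROTEIN:
        raise ParameterError("domain partitioning applies to protein chains only")
    n = chain.n_residues
    if boundaries is not None:
        seqids = chain.residue_seqids
        cuts = []
        for b in boundaries:
            pos = np.nonzero(seqids == b)[0]
            if len(pos) == 0:
                raise ParameterError(f"boundary residue {b} not in chain")
            cuts.append(int(pos[0]))
        cuts = sorted(set(c for c in cuts if c > 0))
        edges = [0, *cuts, n]
        segments = [
            (edges[i], edges[i + 1] - 1, i) for i in range(len(edges) - 1)
        ]
        return DomainPartition(segments=segments, n_residues=n)

    labels = np.zeros(n, dtype=np.int64)
    if n >= 2 * min_split:
        ca = chain.representative_coords()
        contact = _contact_matrix(ca, contact_cutoff)
        next_label = [1]

        def recurse(members: np.ndarray) -> None:
            if len(members) < 2 * min_split:
                return
            sub = contact[np.ix_(members, members)]
            part = _fiedler_split(sub)
            inter, intra = _contact_density(sub, part)
            if part.sum() < min_split or (~part).sum() < min_split:
                return
            if intra <= 0 or inter >= density_ratio * intra:
                return
            labels[members[part]] = next_label[0]
            next_label[0] += 1
            recurse(members[part])
            recurse(members[~part])

        recurse(np.arange(n))
    segments = _labels_to_segments(labels)
    return DomainPartition(segments=segments, n_residues=n)


# ---------------------------------------------------------------------------
# File I/O


def _chain_from_gemmi(gchain, declared_kind: str | None = None) -> ChainModel | None:
    residue_names: list[str] = []
    residue_seqids: list[int] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    atom_residue: list[int] = []
    unknown: set[str] = set()
    for res in gchain:
        rname = res.name.strip().upper()
        if rname in {"HOH", "WAT", "DOD"}:
            continue
        if res.seqid.icode not in ("", " "):
            raise StructureFormatError(
                f"chain {gchain.name}: insertion code '{res.seqid.icode}' at "
                f"residue {res.seqid.num} is not supported; renumber the chain"
            )
        if rname not in AMINO_ACIDS and rname not in NUCLEOTIDES:
            has_polymer_atom = any(
                a.name in ("CA", "P", "C1'") for a in res
            )
            if not has_polymer_atom:
                continue  # ligand/ion
            unknown.add(rname)
        ridx = len(residue_names)
        n_added = 0
        for atom in res:
            el = atom.element.name.upper()
            if el in ("H", "D"):
                continue
            atom_names.append(atom.name)
            elements.append(el if el else "C")
            coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
            atom_residue.append(ridx)
            n_added += 1
        if n_added:
            residue_names.append(rname)
            residue_seqids.append(res.seqid.num)
    if not residue_names:
        return None
    if unknown:
        warnings.warn(
            f"chain {gchain.name}: nonstandard residues parsed: {sorted(unknown)}",
            stacklevel=3,
        )
    chain = ChainModel(
        chain_id=gchain.name,
        kind=PROTEIN,  # provisional; classified below
        residue_names=residue_names,
        residue_seqids=np.array(residue_seqids),
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=np.array(coords),
        atom_residue=np.array(atom_residue),
    )
    kind = declared_kind or classify_chain(chain)
    return replace(chain, kind=kind, rigid=(kind == NA))


def read_structure(path, rigid_group: bool = False) -> list[ChainModel]:
    """Read chains from a PDB or mmCIF file (hydrogens and solvent dropped).

    With ``rigid_group=True`` all chains in the file are merged into a single
    rigid ``ChainModel`` — the intended way to supply a double-stranded
    nucleic acid duplex so base pairing survives assembly.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureFormatError(f"cannot read structure {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models in file")
    chains = []
    for gchain in st[0]:
        chain = _chain_from_gemmi(gchain)
        if chain is not None:
            chains.append(chain)
    if not chains:
        raise StructureFormatError(
            f"{path}: no polymer chains (only solvent/ligand records found)"
        )
    if rigid_group and len(chains) >= 1:
        return [merge_rigid_unit(chains)]
    return chains


def merge_rigid_unit(chains: list[ChainModel]) -> ChainModel:
    """Fuse several chains into one rigid unit (e.g. the strands of a duplex)."""
    kinds = {c.kind for c in chains}
    kind = NA if NA in kinds else PROTEIN
    residue_names: list[str] = []
    seqids: list[int] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    atom_residue: list[np.ndarray] = []
    offset = 0
    renumber = False
    for c in chains:
        residue_names.extend(c.residue_names)
        seqids.extend(c.residue_seqids.tolist())
        atom_names.extend(c.atom_names.tolist())
        elements.extend(c.elements.tolist())
        coords.append(c.coords)
        atom_residue.append(c.atom_residue + offset)
        offset += c.n_residues
    seq = np.array(seqids)
    if len(seq) > 1 and not np.all(np.diff(seq) > 0):
        renumber = True
        seq = np.arange(1, len(seq) + 1)
    if renumber:
        warnings.warn(
            "merged rigid unit renumbered 1..N (strand numbering overlapped)",
            stacklevel=2,
        )
    return ChainModel(
        chain_id=chains[0].chain_id,
        kind=kind,
        residue_names=residue_names,
        residue_seqids=seq,
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=np.concatenate(coords),
        atom_residue=np.concatenate(atom_residue),
        rigid=True,
        source_chain_ids=tuple(c.chain_id for c in chains),
    )


_RES_KIND_DEFAULT = {PROTEIN: "ALA", NA: "DA"}


def write_pdb(model: ComplexModel | list[ChainModel], path,
              remarks: list[str] | None = None) -> None:
    """Write chains as a PDB file, with fit scores in REMARK 3 lines."""
    chains = model.chains if isinstance(model, ComplexModel) else model
    st = gemmi.Structure()
    st.name = "emfit model"
    gmodel = gemmi.Model("1")
    for chain in chains:
        gchain = gemmi.Chain(chain.chain_id)
        for ridx in range(chain.n_residues):
            res = gemmi.Residue()
            res.name = chain.residue_names[ridx] or _RES_KIND_DEFAULT[chain.kind]
            res.seqid = gemmi.SeqId(int(chain.residue_seqids[ridx]), " ")
            for a in chain.residue_atom_indices(ridx):
                atom = gemmi.Atom()
                atom.name = str(chain.atom_names[a])
                atom.element = gemmi.Element(str(chain.elements[a]))
                atom.pos = gemmi.Position(*chain.coords[a])
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            gchain.add_residue(res)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if remarks:
        st.raw_remarks = [f"REMARK   3 {line}" for line in remarks]
    doc_opts = gemmi.PdbWriteOptions(minimal=False, numbered_ter=False)
    st.write_pdb(str(path), doc_opts)
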