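"""Model-to-map and model-to-model quality measures.

* global CC — Pearson correlation between the experimental map and a map
  simulated from the model on the same lattice, over voxels where either
  exceeds 1e-6 (scoring empty space would reward agreement about nothing).
* local / per-residue CC — the same correlation restricted to voxels within
  3 Å of the atoms of a nine-residue fragment centered at each residue.
* FSC and integrated FSC — correlation of Fourier coefficients in concentric
  frequency shells; iFSC is the trapezoidal mean over a band, by default
  1/10 Å⁻¹ up to 1/resolution.
* composite fit score — weighted sum of (global CC, mean local CC, iFSC),
  the objective of rigid-body pose refinement.
* clash score — inter-unit heavy-atom pairs closer than a cutoff, normalized
  by total atom count (kd-tree accelerated; near-linear in atoms).
* RMSD (Kabsch) and TM-score — model-vs-reference metrics.

``ChainScorer`` is the cached fast path used inside optimization loops; the
module-level functions are the convenience API and delegate to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.spatial import cKDTree

from .errors import ParameterError
from .map_core import DensityMap
from .structure import ChainModel, ComplexModel, Pose

SUPPORT_EPS = 1e-6
LOCAL_CC_RADIUS = 3.0  # Å of map support around fragment atoms
LOCAL_CC_HALF_WINDOW = 4  # nine-residue fragment: [i-4, i+4]
DEFAULT_CLASH_CUTOFF = 3.0  # Å between heavy atoms of different rigid units
DEFAULT_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
IFSC_FREQ_MIN = 0.1  # 1/Å, low-frequency end of the integration band

__all__ = [
    "ScoreReport", "ChainScorer", "global_cc", "local_cc", "per_residue_cc",
    "fsc_curve", "integrated_fsc", "composite_fit_score", "clash_score",
    "rmsd_kabsch", "kabsch_rotation", "tm_score", "tm_d0",
]


@dataclass
class ScoreReport:
    """Bundle of quality measures for one model against one map."""

    global_cc: float
    per_residue_cc: list[tuple[str, int, float]]
    fsc_curve: list[tuple[float, float]]
    ifsc: float
    clash: float
    composite: float

    def to_dict(self) -> dict:
        return {
            "global_cc": self.global_cc,
            "ifsc": self.ifsc,
            "clash": self.clash,
            "composite": self.composite,
            "per_residue_cc": [
                {"chain": c, "residue": int(r), "cc": float(v)}
                for c, r, v in self.per_residue_cc
            ],
            "fsc_curve": [{"freq": float(f), "fsc": float(v)}
                          for f, v in self.fsc_curve],
        }


# ---------------------------------------------------------------------------
# Pearson helpers


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom <= 0:
        return 0.0
    return float((a * b).sum() / denom)


def _coords_weights(model: ComplexModel | ChainModel):
    chains = model.chains if isinstance(model, ComplexModel) else [model]
    return (np.concatenate([c.coords for c in chains]),
            np.concatenate([c.masses for c in chains]))


def _simulate(model, dmap: DensityMap) -> np.ndarray:
    from .simulate import simulate_on_grid  # deferred: simulate imports nothing back

    coords, weights = _coords_weights(model)
    return simulate_on_grid(coords, weights, dmap)


# ---------------------------------------------------------------------------
# Global and local correlation


def global_cc(model: ComplexModel | ChainModel, dmap: DensityMap,
              sim_grid: np.ndarray | None = None) -> float:
    """Pearson CC between the map and the model's simulated density.

    Computed over voxels where either map exceeds ``SUPPORT_EPS``.  Returns 0
    (with a warning) when the support region has no variance.
    """
    sim = _simulate(model, dmap) if sim_grid is None else sim_grid
    exp = dmap.grid
    support = (sim > SUPPORT_EPS) | (exp > SUPPORT_EPS)
    if not np.any(support):
        warnings.warn("model and map share no support; CC set to 0", stacklevel=2)
        return 0.0
    cc = _pearson(exp[support].astype(np.float64), sim[support].astype(np.float64))
    if cc == 0.0 and np.all(exp[support] == exp[support].flat[0]):
        warnings.warn("zero-variance map region; CC set to 0", stacklevel=2)
    return cc


def per_residue_cc(chain: ChainModel, dmap: DensityMap) -> np.ndarray:
    """Local CC for every residue (nine-residue fragment window)."""
    scorer = ChainScorer(chain, dmap)
    return scorer.local_cc_all(chain.coords)


def local_cc(chain: ChainModel, dmap: DensityMap, residue_index: int) -> float:
    """Local CC of the fragment spanning residues [i-4, i+4] (clipped)."""
    if not 0 <= residue_index < chain.n_residues:
        raise ParameterError(f"residue index {residue_index} out of range")
    return float(per_residue_cc(chain, dmap)[residue_index])


# ---------------------------------------------------------------------------
# Fourier shell correlation


def _shell_bins(shape, voxel: float):
    freqs = [np.fft.fftfreq(n, d=voxel) for n in shape]
    # rfft layout on the last axis
    freqs[-1] = np.fft.rfftfreq(shape[-1], d=voxel)
    kz, ky, kx = np.meshgrid(*freqs, indexing="ij")
    kmag = np.sqrt(kx**2 + ky**2 + kz**2)
    width = 1.0 / (min(shape) * voxel)
    bins = np.round(kmag / width).astype(np.int64)
    nyquist_bin = int(np.floor(0.5 / voxel / width + 1e-9))
    # conjugate-symmetry weights so half-spectrum sums equal full-spectrum sums
    nx = shape[-1]
    wx = np.full(kx.shape[-1], 2.0)
    wx[0] = 1.0
    if nx % 2 == 0:
        wx[-1] = 1.0
    weights = np.broadcast_to(wx, kx.shape).copy()
    return bins, weights, width, nyquist_bin


def fsc_curve(map_a: DensityMap, map_b: DensityMap) -> list[tuple[float, float]]:
    """Fourier shell correlation from DC to Nyquist (shell width one voxel)."""
    if map_a.grid.shape != map_b.grid.shape:
        raise ParameterError("maps must share a grid shape")
    if abs(map_a.voxel_size - map_b.voxel_size) > 1e-9:
        raise ParameterError("maps must share a voxel size")
    fa = np.fft.rfftn(map_a.grid.astype(np.float64))
    fb = np.fft.rfftn(map_b.grid.astype(np.float64))
    bins, w, width, nyq = _shell_bins(map_a.grid.shape, map_a.voxel_size)
    return _fsc_from_transforms(fa, fb, bins, w, width, nyq)


def _fsc_from_transforms(fa, fb, bins, w, width, nyq) -> list[tuple[float, float]]:
    flat = bins.ravel()
    nb = nyq + 1
    sel = flat < nb
    cross = np.bincount(flat[sel], ((fa * np.conj(fb)).real * w).ravel()[sel],
                        minlength=nb)
    pa = np.bincount(flat[sel], ((fa.real**2 + fa.imag**2) * w).ravel()[sel],
                     minlength=nb)
    pb = np.bincount(flat[sel], ((fb.real**2 + fb.imag**2) * w).ravel()[sel],
                     minlength=nb)
    denom = np.sqrt(pa * pb)
    corr = np.divide(cross, denom, out=np.zeros_like(cross), where=denom > 0)
    return [(i * width, float(c)) for i, c in enumerate(corr)]


def integrated_fsc(curve: list[tuple[float, float]], freq_min: float,
                   freq_max: float) -> float:
    """Trapezoidal mean of an FSC curve over [freq_min, freq_max] (1/Å)."""
    if freq_min >= freq_max:
        raise ParameterError("freq_min must be below freq_max")
    freqs = np.array([f for f, _ in curve])
    vals = np.array([v for _, v in curve])
    if freq_max > freqs[-1] + 1e-9 or freq_min < freqs[0] - 1e-9:
        raise ParameterError("integration band outside the computed curve")
    grid = np.unique(np.concatenate([[freq_min, freq_max],
                                     freqs[(freqs > freq_min) & (freqs < freq_max)]]))
    interp = np.interp(grid, freqs, vals)
    return float(np.trapezoid(interp, grid) / (freq_max - freq_min))


# ---------------------------------------------------------------------------
# Composite score (with a cached fast path for optimizers)


class ChainScorer:
    """Cached composite-score evaluator for one chain against one map.

    Precomputes everything that does not depend on the pose: the experimental
    support and Fourier transform, the FSC shell bins, the Gaussian splat
    stencil, and the atom → residue-window structure of the local CC.  Calling
    :meth:`score` with transformed coordinates is then cheap enough to sit in
    a finite-difference optimization loop.
    """

    def __init__(
        self,
        chain: ChainModel,
        dmap: DensityMap,
        weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
        local_radius: float = LOCAL_CC_RADIUS,
        cutoff_sigmas: float = 3.0,
    ) -> None:
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0) or w.sum() <= 0:
            raise ParameterError("score weights must be nonnegative, sum > 0")
        self.weights = w / w.sum()
        self.chain = chain
        self.dmap = dmap
        self.exp = dmap.grid.astype(np.float64)
        self.exp_support = self.exp > SUPPORT_EPS
        self.voxel = float(dmap.voxel_size)
        self.shape = np.array(dmap.grid.shape)
        self.atom_weights = chain.masses
        self.sigma = dmap.resolution / (np.pi * np.sqrt(2.0))
        self.splat_radius = cutoff_sigmas * self.sigma
        # stencil padded by half a voxel diagonal (atoms sit off centers);
        # the exact d² cutoff below keeps the result identical to the
        # reference simulator
        self._splat_offsets = self._make_offsets(
            self.splat_radius + 0.5 * np.sqrt(3) * self.voxel)
        self._local_offsets = self._make_offsets(
            local_radius + 0.5 * np.sqrt(3) * self.voxel)
        self.local_radius = local_radius
        # zero-pad the FFT box to 5-smooth sizes (prime-sized boxes would put
        # the per-pose transform on the slow Bluestein path); both volumes are
        # padded identically so the shell correlations stay consistent
        self._fft_shape = tuple(sp_fft.next_fast_len(n) for n in dmap.grid.shape)
        exp_padded = np.zeros(self._fft_shape, dtype=np.float32)
        exp_padded[tuple(slice(0, n) for n in dmap.grid.shape)] = dmap.grid
        self._bins, self._wsym, self._width, self._nyq = _shell_bins(
            self._fft_shape, self.voxel)
        self.ifsc_band = (IFSC_FREQ_MIN, 1.0 / dmap.resolution)
        if self.ifsc_band[0] >= self.ifsc_band[1]:
            # very low-resolution maps: integrate from the first shell instead
            self.ifsc_band = (self._width, 1.0 / dmap.resolution)
        # only shells up to the top of the integration band matter: select
        # those spectrum entries once so per-pose FFT bookkeeping stays small
        band_bin = min(int(np.ceil(self.ifsc_band[1] / self._width)) + 1, self._nyq)
        self._band_bin = band_bin
        flat_bins = self._bins.ravel()
        self._sel = np.nonzero(flat_bins <= band_bin)[0]
        self._sel_bins = flat_bins[self._sel]
        self._sel_w = self._wsym.ravel()[self._sel]
        fa_sel = sp_fft.rfftn(exp_padded).ravel()[self._sel]
        self._fa_sel = fa_sel
        self._fa_power = np.bincount(
            self._sel_bins, (fa_sel.real**2 + fa_sel.imag**2) * self._sel_w,
            minlength=band_bin + 1)
        # residue windows for the local CC
        n = chain.n_residues
        h = LOCAL_CC_HALF_WINDOW
        res = chain.atom_residue
        self._n_windows = n
        # atom i contributes its voxels to windows [res-4, res+4]
        self._win_lo = np.maximum(res - h, 0)
        self._win_hi = np.minimum(res + h, n - 1)

    def _make_offsets(self, radius: float) -> np.ndarray:
        noff = int(np.ceil(radius / self.voxel))
        off = np.arange(-noff, noff + 1)
        dz, dy, dx = np.meshgrid(off, off, off, indexing="ij")
        offs = np.stack([dz.ravel(), dy.ravel(), dx.ravel()], axis=1)
        keep = (offs**2).sum(axis=1) * self.voxel**2 <= radius**2 + 1e-9
        return offs[keep]

    # -- pieces ----------------------------------------------------------

    def _atom_voxels(self, coords: np.ndarray, offsets: np.ndarray):
        """Voxel ids (raveled) around each atom plus in-bounds mask."""
        frac = (coords[:, ::-1] - self.dmap.origin[::-1]) / self.voxel
        base = np.floor(frac + 0.5).astype(np.int64)  # nearest voxel
        vox = base[:, None, :] + offsets[None, :, :]
        inb = np.all((vox >= 0) & (vox < self.shape), axis=2)
        return vox, frac, inb

    def simulate(self, coords: np.ndarray) -> np.ndarray:
        vox, frac, inb = self._atom_voxels(coords, self._splat_offsets)
        delta = (vox - frac[:, None, :]) * self.voxel
        d2 = np.einsum("nmk,nmk->nm", delta, delta)
        vals = self.atom_weights[:, None] * np.exp(-d2 / (2 * self.sigma**2))
        keep = inb & (d2 <= self.splat_radius**2)
        flat = (vox[..., 0] * self.shape[1] + vox[..., 1]) * self.shape[2] + vox[..., 2]
        n_vox = int(np.prod(self.shape))
        grid = np.bincount(flat[keep], weights=vals[keep], minlength=n_vox)
        return grid.reshape(tuple(self.shape))

    def global_cc(self, sim: np.ndarray) -> float:
        support = self.exp_support | (sim > SUPPORT_EPS)
        return _pearson(self.exp[support], sim[support])

    def local_cc_all(self, coords: np.ndarray, sim: np.ndarray | None = None
                     ) -> np.ndarray:
        """Per-residue fragment CC; residues with no map support get 0.

        A voxel belongs to window ``w`` when it lies within ``local_radius``
        of any atom of residues ``[w-4, w+4]``.  Each (voxel, residue)
        incidence opens the window interval ``[res-4, res+4]``; merging
        overlapping intervals per voxel and accumulating window sums through
        a difference array gives exact set-union support without per-window
        deduplication.
        """
        if sim is None:
            sim = self.simulate(coords)
        vox, frac, inb = self._atom_voxels(coords, self._local_offsets)
        delta = (vox - frac[:, None, :]) * self.voxel
        d2 = np.einsum("nmk,nmk->nm", delta, delta)
        keep = inb & (d2 <= self.local_radius**2 + 1e-9)
        flat = ((vox[..., 0] * self.shape[1] + vox[..., 1]) * self.shape[2]
                + vox[..., 2])
        n_vox = int(np.prod(self.shape))
        atom_ids, _ = np.nonzero(keep)
        vox_ids = flat[keep]
        res_ids = self.chain.atom_residue[atom_ids]
        h = LOCAL_CC_HALF_WINDOW
        nw = self._n_windows
        # unique (voxel, residue) incidences, sorted voxel-major
        key = np.unique(vox_ids * nw + res_ids)
        if len(key) == 0:  # chain entirely outside the map box
            return np.zeros(nw)
        kv, kr = key // nw, key % nw
        # merge per-voxel runs of residues closer than a window width
        new_run = np.empty(len(key), dtype=bool)
        new_run[0] = True
        new_run[1:] = (kv[1:] != kv[:-1]) | (kr[1:] - kr[:-1] > 2 * h)
        starts = np.nonzero(new_run)[0]
        ends = np.append(starts[1:], len(key)) - 1
        lo = np.clip(kr[starts] - h, 0, nw - 1)
        hi = np.clip(kr[ends] + h, 0, nw - 1)
        v = kv[starts]
        e = self.exp.ravel()[v]
        s = sim.ravel()[v]
        stats = np.stack([np.ones_like(e), e, s, e * e, s * s, e * s])
        diff = np.zeros((6, nw + 1))
        np.add.at(diff, (slice(None), lo), stats)
        np.add.at(diff, (slice(None), hi + 1), -stats)
        cnt, se, ss, see, sss, ses = np.cumsum(diff[:, :-1], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = ses - se * ss / np.maximum(cnt, 1)
            var_e = see - se * se / np.maximum(cnt, 1)
            var_s = sss - ss * ss / np.maximum(cnt, 1)
            cc = cov / np.sqrt(var_e * var_s)
        cc[~np.isfinite(cc)] = 0.0
        cc[cnt < 2] = 0.0
        return np.clip(cc, -1.0, 1.0)

    def ifsc(self, sim: np.ndarray) -> float:
        padded = np.zeros(self._fft_shape, dtype=np.float32)
        padded[tuple(slice(0, n) for n in sim.shape)] = sim
        fb_sel = sp_fft.rfftn(padded).ravel()[self._sel]
        nb = self._band_bin + 1
        cross = np.bincount(
            self._sel_bins,
            ((fb_sel.real * self._fa_sel.real + fb_sel.imag * self._fa_sel.imag)
             * self._sel_w),
            minlength=nb)
        pb = np.bincount(self._sel_bins,
                         (fb_sel.real**2 + fb_sel.imag**2) * self._sel_w,
                         minlength=nb)
        denom = np.sqrt(self._fa_power[:nb] * pb)
        corr = np.divide(cross, denom, out=np.zeros_like(cross),
                         where=denom > 0)
        curve = [(i * self._width, float(c)) for i, c in enumerate(corr)]
        return integrated_fsc(curve, *self.ifsc_band)

    # -- the composite ----------------------------------------------------

    def score(self, coords: np.ndarray) -> dict:
        """Composite score and components for chain atoms at ``coords``.

        Components with zero weight are skipped (reported as 0), which makes
        a CC-only scorer cheap enough for exhaustive pose triage.
        """
        sim = self.simulate(coords)
        g = self.global_cc(sim) if self.weights[0] > 0 else 0.0
        if self.weights[1] > 0:
            lcc = self.local_cc_all(coords, sim)
            l = float(lcc.mean()) if len(lcc) else 0.0
        else:
            l = 0.0
        f = self.ifsc(sim) if self.weights[2] > 0 else 0.0
        comp = float(self.weights @ np.array([g, l, f]))
        return {"composite": comp, "global_cc": g, "mean_local_cc": l, "ifsc": f}

    def score_pose(self, pose: Pose) -> dict:
        return self.score(pose.apply(self.chain.coords, self.chain.centroid))


def composite_fit_score(
    chain: ChainModel,
    dmap: DensityMap,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Weighted sum of global CC, mean local CC and iFSC (weights renormalized)."""
    return ChainScorer(chain, dmap, weights=weights).score(chain.coords)["composite"]


# ---------------------------------------------------------------------------
# Clash score


def _unit_coords(model: ComplexModel) -> tuple[np.ndarray, np.ndarray]:
    coords = np.concatenate([c.coords for c in model.chains])
    unit = np.concatenate([
        np.full(c.n_atoms, i) for i, c in enumerate(model.chains)
    ])
    return coords, unit


def clash_score(model: ComplexModel, cutoff: float = DEFAULT_CLASH_CUTOFF) -> float:
    """Inter-unit heavy-atom pairs closer than ``cutoff``, per atom.

    Each chain (a merged duplex counts as one chain) is one rigid unit; the
    count of cross-unit pairs below the cutoff is divided by the total number
    of heavy atoms.  kd-tree pair search keeps the cost near-linear.
    """
    if cutoff <= 0:
        raise ParameterError("clash cutoff must be positive")
    if len(model.chains) < 2:
        return 0.0
    coords, unit = _unit_coords(model)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    inter = unit[pairs[:, 0]] != unit[pairs[:, 1]]
    pairs = pairs[inter]
    if len(pairs) == 0:
        return 0.0
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(np.count_nonzero(d < cutoff) / len(coords))


# ---------------------------------------------------------------------------
# RMSD / Kabsch


def kabsch_rotation(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                           np.ndarray]:
    """Least-squares rotation matrix R (reflection-guarded) with centroids.

    Returns (R, centroid_a, centroid_b) such that ``(a - ca) @ R.T + cb``
    superposes a onto b.
    """
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    return r, ca, cb


def rmsd_kabsch(coords_a: np.ndarray, coords_b: np.ndarray,
                superpose: bool = True) -> float:
    """RMSD between matched point sets, optionally after optimal superposition."""
    a = np.asarray(coords_a, dtype=np.float64)
    b = np.asarray(coords_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ParameterError("coordinate arrays must be matched (N, 3)")
    if len(a) < 3 and superpose:
        if len(a) < 1:
            raise ParameterError("need at least one point")
    if superpose:
        if np.linalg.matrix_rank(a - a.mean(axis=0)) < 2:
            warnings.warn("degenerate (rank < 2) point set in superposition",
                          stacklevel=2)
        r, ca, cb = kabsch_rotation(a, b)
        a = (a - ca) @ r.T + cb
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# TM-score


def tm_d0(length: int) -> float:
    """Length-dependent distance scale d0, floored at 0.5 Å."""
    if length > 15:
        return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def _matched_representatives(model: ComplexModel | ChainModel,
                             reference: ComplexModel | ChainModel):
    if isinstance(model, ChainModel):
        model = ComplexModel(chains=[model])
    if isinstance(reference, ChainModel):
        reference = ComplexModel(chains=[reference])
    ref_len = reference.n_residues
    pairs_m, pairs_r = [], []
    for rchain in reference.chains:
        try:
            mchain = model.get_chain(rchain.chain_id)
        except KeyError:
            continue
        m_by_seqid = {int(s): i for i, s in enumerate(mchain.residue_seqids)}
        m_rep = mchain.representative_coords()
        r_rep = rchain.representative_coords()
        for i, seqid in enumerate(rchain.residue_seqids):
            j = m_by_seqid.get(int(seqid))
            if j is not None:
                pairs_r.append(r_rep[i])
                pairs_m.append(m_rep[j])
    if not pairs_m:
        raise ParameterError("no common residues between model and reference")
    return np.array(pairs_m), np.array(pairs_r), ref_len


def _tm_from_superposition(m: np.ndarray, r: np.ndarray, sub: np.ndarray,
                           d0: float, ref_len: int) -> tuple[float, np.ndarray]:
    rot, ca, cb = kabsch_rotation(m[sub], r[sub])
    m_all = (m - ca) @ rot.T + cb
    d = np.linalg.norm(m_all - r, axis=1)
    tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / ref_len)
    return tm, d


def tm_score(model: ComplexModel | ChainModel,
             reference: ComplexModel | ChainModel) -> float:
    """Template-modeling score of a model against a same-sequence reference.

    Residues are matched by chain id + residue number on representative atoms
    (Cα for protein, C3' for nucleic acid); the superposition is optimized by
    iterative fragment seeding: superpose on a fragment, keep residues within
    d0, re-superpose, iterate; the best score over all seeds wins.
    Normalization is by reference length.
    """
    m, r, ref_len = _matched_representatives(model, reference)
    n = len(m)
    d0 = tm_d0(ref_len)
    best = 0.0
    seeds: list[np.ndarray] = [np.arange(n)]
    frag_lengths = {n // 2, n // 4, n // 8, 16, 8, 4}
    for frag in sorted((f for f in frag_lengths if 4 <= f <= n), reverse=True):
        step = max(frag // 4, 1)
        for start in range(0, n - frag + 1, step):
            seeds.append(np.arange(start, start + frag))
    for seed in seeds:
        sub = seed
        prev_sub = None
        for _ in range(20):
            if len(sub) < 3:
                break
            tm, d = _tm_from_superposition(m, r, sub, d0, ref_len)
            best = max(best, tm)
            new_sub = np.nonzero(d < max(d0, 1.0) * 2.0)[0]
            if len(new_sub) < 3:
                new_sub = np.argsort(d)[: max(3, n // 4)]
            if prev_sub is not None and np.array_equal(new_sub, prev_sub):
                break
            prev_sub, sub = sub, new_sub
    return best
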