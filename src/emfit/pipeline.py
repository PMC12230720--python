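"""End-to-end orchestration: segment → fit → assemble → refine → report.

This is the programmatic equivalent of running the whole tool: it takes a
density map and per-chain models, obtains a protein/NA label volume (from a
trained segmenter, supplied labels, or the geometric fallback), fits every
chain into its segmented map, assembles the complex and refines it jointly.

Fitting and assembly run on a 2 Å working lattice (the tool's default voxel
size; a smaller value buys accuracy at a runtime cost), while segmentation
and label volumes live on the 1 Å lattice they were trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import AssemblyState, DEConfig, assemble_de, build_output, global_refine
from .errors import ParameterError
from .fitting import (
    FitResult,
    FitSchedule,
    MAX_STARTS_DEFAULT,
    domain_refine,
    iterative_fit_all,
)
from .map_core import DensityMap, normalize, resample
from .segmentation import LabelVolume, Segmenter, segment_map, split_map
from .structure import NA, PROTEIN, ChainModel, ComplexModel, partition_domains

FIT_VOXEL_DEFAULT = 2.0  # Å working lattice for fitting and assembly

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline (defaults match the tool's server-style run)."""

    fit_voxel: float = FIT_VOXEL_DEFAULT
    contour_level: float | None = None  # None: use the map's own level
    angular_step: float = 45.0
    max_starts: int = MAX_STARTS_DEFAULT
    schedule: FitSchedule = field(default_factory=FitSchedule)
    de: DEConfig = field(default_factory=DEConfig)
    lambda_clash: float = 1.0
    domain_fitting: bool = True  # advanced option 1: domain-level assembly
    iterative: bool = True  # advanced option 2: iterative masking strategy
    mask_radius: float = 3.0


@dataclass
class PipelineResult:
    model: ComplexModel
    fits: dict[str, FitResult]
    assembly: AssemblyState
    labels: LabelVolume | None


def _prepare_maps(dmap: DensityMap, labels: LabelVolume | None,
                  config: PipelineConfig):
    norm = normalize(dmap, config.contour_level)
    if labels is not None:
        protein_full, na_full = split_map(norm, labels)
        protein_map = resample(protein_full, config.fit_voxel)
        na_map = resample(na_full, config.fit_voxel)
    else:
        protein_map = resample(norm, config.fit_voxel)
        na_map = protein_map
    work_map = resample(norm, config.fit_voxel)
    return work_map, protein_map, na_map


def run_pipeline(
    chains: list[ChainModel],
    dmap: DensityMap,
    labels: LabelVolume | None = None,
    segmenter: Segmenter | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Assemble a complex from a map and individually modeled chains.

    ``labels`` (aligned to ``dmap``) win over ``segmenter``; with neither,
    protein and NA chains are fitted into the same unsegmented map.  The
    returned model is in the map's physical frame.
    """
    config = config or PipelineConfig()
    if not chains:
        raise ParameterError("no chains to assemble")
    if labels is None and segmenter is not None:
        labels = segment_map(normalize(dmap, config.contour_level), segmenter)
    work_map, protein_map, na_map = _prepare_maps(dmap, labels, config)

    has_na = any(c.kind == NA for c in chains)
    chains = list(chains)
    if config.domain_fitting:
        chains = [
            c if c.kind != PROTEIN or c.domains is not None or c.rigid
            else replace(c, domains=partition_domains(c))
            for c in chains
        ]

    schedule = config.schedule
    if not config.iterative:
        schedule = FitSchedule(
            threshold_init=schedule.threshold_floor,
            threshold_step=schedule.threshold_step,
            threshold_floor=schedule.threshold_floor,
            max_rounds=1,
        )
    fits = iterative_fit_all(
        chains,
        protein_map,
        na_map if has_na else None,
        schedule=schedule,
        mask_radius=config.mask_radius,
        use_masking=config.iterative,
        angular_step=config.angular_step,
        max_starts=config.max_starts,
    )

    # flexible (domain-level) fitting: refine the best placement of each
    # multi-domain protein and fold the result back into the chain model so
    # the assembly stage can keep treating chains as rigid
    if config.domain_fitting:
        refined_chains = []
        for chain in chains:
            result = fits.get(chain.chain_id)
            if (result is None or chain.kind != PROTEIN or chain.rigid
                    or chain.domains is None or chain.domains.n_domains < 2):
                refined_chains.append(chain)
                continue
            best_pose = result.best.pose
            flexible = domain_refine(chain, protein_map, best_pose)
            # fold the flexible result back into the chain frame so that
            # best_pose still maps the (new) chain model onto the map; the
            # rotation acts about the placed centroid of the rigid fit
            placed_center = chain.centroid + best_pose.translation
            back = best_pose.inverse().apply(flexible.coords, placed_center)
            refined_chains.append(chain.with_coords(back))
        chains = refined_chains

    state = assemble_de(chains, fits, work_map, config=config.de,
                        lambda_clash=config.lambda_clash)
    model = global_refine(state, work_map, lambda_clash=config.lambda_clash)
    return PipelineResult(model=model, fits=fits, assembly=state, labels=labels)
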