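# Methods

`emfit` assembles protein–nucleic-acid (NA) complex structures from cryo-EM
density maps, given one independently modeled structure per chain. The
pipeline has four stages: semantic segmentation of the map into protein, NA
and background voxels; multi-start rigid-body fitting of each chain into its
segmented map; domain-level flexible refinement of protein chains; and
combinatorial assembly of the retained per-chain poses followed by one joint
refinement. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Map model and preprocessing

A map is a scalar voxel grid with a physical origin, voxel size, nominal
resolution and a contour level treated as the noise floor. On input the
MAPC/MAPR/MAPS axis permutation is honored and maps are resampled
trilinearly to isotropic lattices: 1 Å for segmentation, 2 Å (the tool's
default working voxel, configurable) for fitting and assembly — a smaller
working voxel buys accuracy at roughly cubic runtime cost.

Normalization sets values below the contour level to exactly 0 and divides
by the 98th-percentile value of the surviving signal, clipping at 1. The
percentile is taken over positive surviving voxels only — including the
empty padding would make the scale depend on box size — and uses the
`higher` order statistic so that normalization is exactly idempotent.

Model density is simulated as a sum of isotropic Gaussians, one per heavy
atom, with amplitude equal to the atomic number and width
σ = resolution/(π√2); this is one of several community conventions relating
nominal resolution to real-space blur, fixed here as a single constant so
scores are reproducible. Kernels are truncated at 3σ. Hydrogens are never
simulated or scored: maps at the resolutions of interest do not resolve
them.

## Scoring

* **Global CC** — Pearson correlation between the experimental map and the
  model's simulated density over voxels where either exceeds 1e-6. Scoring
  the full box would reward agreement about empty space.
* **Per-residue (local) CC** — the same correlation restricted to voxels
  within 3 Å of the atoms of a nine-residue window centered at each residue
  (clipped at chain ends). The 3 Å support radius around fragment atoms is a
  package choice, configurable.
* **FSC / iFSC** — Fourier-shell correlation in shells one frequency-voxel
  wide; the integrated FSC is its trapezoidal mean over 0.1 Å⁻¹ to
  1/resolution by default. Volumes are zero-padded to 5-smooth FFT sizes;
  both maps are padded identically, so self-FSC is exactly 1.
* **Composite fit score** — weighted sum of global CC, mean local CC and
  iFSC, default weights (⅓, ⅓, ⅓). The weighting is exposed in
  configuration; the acceptance experiments only rely on the score ranking
  the true pose above perturbed ones, which holds for any sensible weights.
* **Clash score** — number of heavy-atom pairs closer than 3 Å between
  different rigid units (chains; a merged duplex is one unit), divided by
  the total heavy-atom count. kd-tree pair search keeps it near-linear; its
  equivalence to brute-force pair counting is asserted in the tests.
* **RMSD / TM-score** — Kabsch superposition with reflection guard;
  TM-score with d₀(L) = 1.24·(L−15)^⅓ − 1.8 (floored at 0.5), normalized by
  reference length, optimized by iterative fragment-seeded superposition and
  cross-checked against an exhaustive seed oracle in the tests.

## Segmentation

Voxels are labeled 0 (protein), 1 (NA) or 2 (background); ground truth
labels a voxel by the class of the nearest backbone atom within 3 Å
(backbone = N, CA, C, O for protein; P, O5', C5', C4', C3', O3' for NA).
The segmenter is a nested 3-D encoder-decoder with dense skip connections
over 64³ chunks cut on a stride-32 lattice. For CPU practicality the
network computes at half resolution internally: a stride-2 stem maps the
chunk to 32³, encoder widths are (w, 2w, 4w) with base width w = 16, the
top-level decoder nodes run at w/2, and the three-class logits are
upsampled back to 64³ where the class-weighted cross-entropy and all
accuracies live.

Training uses Adam from a learning rate of 5e-4, halved on a 5-epoch
validation-loss plateau down to a floor of 1e-6; the checkpoint with the
lowest validation loss is returned. Class weights default to inverse voxel
frequency on the training set. Training draws random 32³ crops of the
chunks (the network is fully convolutional, so patch training is unbiased
in expectation and ~8× cheaper per pass); validation and inference always
run on full chunks, with per-class probabilities arithmetically averaged
where chunks overlap and zero-density voxels forced to background. The
desk-scale experiment (200 chunks of kinked-helix vs B-form-duplex maps, 30
epochs) reaches ≥ 0.99 held-out voxel accuracy; the full-scale recipe (200
epochs on experimental maps) is the same code with different inputs. A
geometric fallback labeler (nearest chain class from approximate
placements) exists for exercising the downstream pipeline without training;
it is not the learned method.

## Rigid-body fitting

Each chain is fitted by multi-start local optimization of the composite
score. The landscape is the central difficulty: for an elongated chain at
5 Å the rotational basin around the true pose is a few degrees wide —
rotating a 150 Å chain by 10° moves its ends ~25 Å and decorrelates the
density — which no affordable Euler-angle enumeration can hit directly. The
fitter therefore works down a resolution ladder:

1. **Seeding.** Rotations enumerate a deduplicated z-y-z Euler lattice
   (default 45°; 90° yields the 24 rotations of the cube). For each
   rotation, a translation is chosen by an exhaustive FFT cross-correlation
   scan on a ~15 Å low-pass, 4 Å-lattice copy of the map, locally
   normalized by the map energy under a sphere covering the model (by
   Cauchy–Schwarz this bounds the score at 1 and stops partial-overlap edge
   placements from winning). The density-centroid translation is also seeded
   for every rotation. All starts are ranked by actual low-pass CC and the
   best `max_starts` (default 20, hard cap 512) survive.
2. **Coarse pull-in.** Each start is refined by bounded L-BFGS on the
   low-pass map using a one-representative-atom-per-residue chain (at 15 Å,
   sub-residue detail is invisible). After refinement fixes the rotation,
   the FFT scan is consulted once more at the refined rotation — local
   steps move translation slowly on blurred elongated densities, while the
   scan snaps it onto the global optimum for that orientation.
3. **Middle rung.** Survivors are refined against a 2×-resolution low-pass
   of the working map (full atoms, CC only), bridging the gap between the
   triage basin and the narrow native basin.
4. **Polish.** The best basin is refined to convergence on the working map
   with the full composite score; runners-up get an iteration-capped polish
   and the top five deduplicated poses (2 Å / 10° merge radius) are
   retained for assembly.

Refinement parameterizes poses as translation plus an axis-angle chart
centered at the start rotation, acting about the chain centroid. Rotation
parameters are scaled by the gyration radius so that a unit step in any of
the six parameters moves atoms comparably — without this the optimizer
pours all effort into the far-more-sensitive rotations and translation
stalls. Gradients are finite differences (0.25 Å and 1° steps; central in
the polish, one-sided in the coarse stages), convergence at |Δscore| <
1e-5 or 200 iterations, and every refinement is boxed to ±15 Å / ±45°
around its start: refinement is a within-basin operation, the multi-start
machinery owns the global search, and unbounded line searches readily hop
between basins. An accepted refinement never scores below its start.

One escalation rule guards against a failure mode specific to elongated
chains: their coarse-stage landscape carries broad ridges of out-of-register
local optima, and for some start orientations a 45° lattice brackets only
ridge points, never the true basin. When the best polished composite stays
below a value no acceptable fit should score under (0.75 by default; the
acceptance threshold itself during iterative fitting), the whole search is
repeated once on a 30° lattice at roughly 3× cost and the candidate lists
are merged. Easy cases never pay for this; hard ones are usually rescued by
the finer bracketing.

Chains are fitted longest-first. A chain whose best global CC reaches the
acceptance threshold (0.6 initially) is masked out of its kind's working
map — all heavy atoms, 3 Å radius, best candidate only — before later
chains are fitted; unplaced chains are retried as the threshold decays
(step 0.1 to a floor of 0.3, at most 4 rounds). A pending chain is refit
only when its working map has changed since its last attempt.

## Domain handling

Protein chains are partitioned into domains either at user-supplied
residue boundaries or by recursive spectral bisection of the Cα contact
graph (8 Å cutoff), splitting while both parts keep ≥ 60 residues and the
inter-part contact density is below 0.1× the intra-part density; fragments
under 20 residues merge into a neighbor. This is a deliberately simple
stand-in for full-featured domain parsers and user boundaries always win.
After rigid fitting, each domain of a multi-domain protein is refined as
its own rigid body; a domain move is accepted only if the whole-chain
composite score improves and no inter-domain linker Cα–Cα gap exceeds 8 Å.
Refusing to move is a valid outcome, so flexible fitting never degrades a
chain. NA chains (and duplexes supplied as one file) are rigid throughout.

## Assembly

One pose per chain is selected from the retained candidates by minimizing
E = −global CC(complex, map) + λ·clash with λ = 1 against the original
(unsegmented, unmasked) working map, so protein and NA placements are
judged jointly. Search spaces of ≤ 1024 combinations are enumerated
exhaustively — exact, and the test oracle; larger spaces use integer-coded
differential evolution (rand/1/bin, rounding with reflection repair,
population 40, F = 0.7, CR = 0.9, 200 generations, seeded), whose initial
population always contains the per-chain-greedy selection so DE can never
do worse than greedy. Simulated density is linear in the model, so
per-candidate grids are cached and an energy evaluation sums cached grids.

The selected complex then receives one joint bounded L-BFGS refinement over
all rigid units simultaneously — each protein domain is a 6-DOF unit, each
NA chain a single rigid body — accepted only if the energy improves.
Finite differences re-simulate only the perturbed unit. Clash is always
counted between chains, never between domains of the same chain.

## Synthetic data

The generator builds toy complexes with plausible backbone geometry:
proteins as ideal α-helical traces (rise 1.5 Å, 100°/residue, Cα radius
2.3 Å, giving 3.83 Å Cα–Cα) with N, C, O completed at ideal bond lengths,
and NA duplexes as two antiparallel B-form backbone strands (rise 3.4 Å,
twist 36°/bp, six backbone atoms per nucleotide at ~8–9 Å radius).

Protein chains are folded at one (≥ 40 residues) or two (≥ 100 residues)
asymmetric off-center kinks by default. This matters: a perfectly straight
ideal helix is almost invariant under its own screw motion and an
end-over-end dyad, so its pose is not identifiable from a 5 Å map, and a
150-residue straight helix is a 225 Å rod unlike any real chain. The kinks
(rigid rotations about a hinge Cα, preserving all bond lengths) produce
compact, uniquely oriented shapes closer to real multi-domain proteins.
Chains are placed with random orientations, stepped outward along random
directions until the minimum inter-chain heavy-atom distance reaches 4 Å,
keeping complexes compact. Placement poses are recorded as ground truth.

Gaussian voxel noise (σ expressed as a fraction of the map peak) can be
added; the noisy map then carries a recommended contour level of 2σ — the
synthetic analogue of the noise-floor contour deposited with experimental
maps — which normalization honors by default. The standard test condition
is two protein chains (150 and 90 residues) plus one rigid 30-bp duplex at
5 Å with 5% noise.

What passing these experiments shows: the score landscape, search
machinery, masking and domain logic, assembly optimizer and all
bookkeeping work end to end, with exact ground truth available at every
stage. What it does not show: robustness to the things real maps add —
non-Gaussian and structured noise, B-factor variation, local resolution
gradients, segmentation errors on real density, inaccurate predicted chain
models, and conformational heterogeneity. The segmenter trained here has
seen only synthetic helix/duplex density and is not transferable to
experimental maps without retraining.

## Determinism and degenerate inputs

All randomness flows through explicitly seeded generators; fitting and
assembly are deterministic given inputs, and identical seeds reproduce the
final PDB byte for byte. Degenerate inputs fail loudly: maps that are empty
after thresholding, mixed protein/NA chains, insertion codes, truncated
volumes, and Nyquist-violating simulation requests all raise typed errors.
All-coincident point sets and single-voxel maps return zero gyration radius
with a warning rather than an error.

## Problem sizes

The shipped experiments run on one CPU: single-chain recovery fits a
120-residue chain in ~20–40 s; the three-chain assembly completes in a few
minutes; segmenter training (200 chunks × 30 epochs) takes 6–8 minutes.
These sizes were chosen so the whole suite is a desk-scale run while every
algorithmic path is exercised at full fidelity.
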