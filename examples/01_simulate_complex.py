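"""Build a toy protein-DNA complex and simulate its density map.

Generates the package's standard synthetic condition (two kinked helical
protein chains + one rigid 30-bp duplex), simulates a 5 Å map on a 1 Å
lattice, and prints the basic geometry.  The printed gap is the smallest
heavy-atom distance between chains (the layout guarantees >= 4 Å); the
label fractions say how much of the box is protein, nucleic acid and
background under the 3 Å ground-truth rule.
"""

import numpy as np
from scipy.spatial import cKDTree

from emfit import SyntheticComplexSpec, ground_truth_labels, make_toy_complex, simulate_map

spec = SyntheticComplexSpec(seed=7)
model = make_toy_complex(spec)
dmap = simulate_map(model, resolution=spec.resolution, voxel_size=spec.voxel_size)
labels = ground_truth_labels(model, dmap)

print(f"chains: {[(c.chain_id, c.kind, c.n_residues) for c in model.chains]}")
gaps = []
for i in range(len(model.chains)):
    for j in range(i + 1, len(model.chains)):
        gaps.append(cKDTree(model.chains[i].coords)
                    .query(model.chains[j].coords)[0].min())
print(f"map grid {dmap.grid.shape} at {dmap.voxel_size} A/voxel, "
      f"min inter-chain gap {min(gaps):.2f} A")
for code, name in [(0, "protein"), (1, "nucleic acid"), (2, "background")]:
    frac = float(np.mean(labels.labels == code))
    print(f"  label {code} ({name}): {frac:.3f} of voxels")
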