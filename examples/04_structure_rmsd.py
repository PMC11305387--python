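"""Symmetry-corrected region RMSD between a model and a reference structure.

Generates a toy structure pair related by a known rigid motion with 0.3 Å
noise and flipped phenyl-ring labels, writes both as PDB, and compares them
region by region.
"""

from pathlib import Path

import dockeval as dk
from dockeval.simulate import write_pdb

out = Path("scratch_structures")
out.mkdir(exist_ok=True)

reference, model, truth = dk.gen_toy_structures(
    n_residues=30, rotation=(0.4, -0.2, 0.9), translation=(8.0, -3.0, 5.0),
    noise_sd=0.3, seed=7,
)
write_pdb(reference, out / "reference.pdb")
write_pdb(model, out / "model.pdb")

regions = dk.RegionSet(
    binding_site=[("A", i) for i in range(1, 11)],
    ranges={"helix_tail": [("A", 20, 30)]},
)
report = dk.region_report(
    dk.load_structure(out / "model.pdb"),
    dk.load_structure(out / "reference.pdb"),
    regions,
)
print(report.to_frame().to_string(index=False))
print(f"\nring labels swapped in residues: {truth['swapped_residues']}")

# Cα RMSD per region after fitting each region on its own Cα atoms; the
# binding-site row adds side-chain heavy-atom RMSD before and after symmetry
# correction — the corrected value discounts the phenyl ring flips, which
# are naming artefacts, and so sits near the simulated 0.3·√3 ≈ 0.52 Å noise
# floor while the plain value is inflated by the flipped labels.
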