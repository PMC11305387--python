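"""Prospective triage: best-score ranking, PAINS + similarity filters,
leader clustering, candidate export.

Builds a small synthetic library (with PAINS fixture molecules spiked in),
docks it "virtually" by simulating scores against 3 models, and runs the
full triage cascade.
"""

import numpy as np

import dockeval as dk
from dockeval.pipeline import PipelineConfig, run_prospective

rng = np.random.default_rng(0)
library = dk.gen_compound_library(
    dk.LibrarySimSpec(n_compounds=150, include_pains_fixtures=True, seed=0)
)
# give the synthetic records benign structures so the PAINS stage sees them
benign = ["CCO", "CCN", "CCCC", "c1ccccc1", "CCOC", "CC(C)O"]
for i, rec in enumerate(library):
    if rec.smiles is None:
        rec.smiles = benign[i % len(benign)]

scores = rng.normal(size=(len(library), 3))
matrix = dk.ScoreMatrix(
    compound_ids=[r.id for r in library],
    labels=["decoy"] * len(library),
    scores=scores,
    missing=rng.random(scores.shape) < 0.1,
)

config = PipelineConfig(
    output_dir="scratch_triage_out", top_n_input=100, top_n_clusters=20,
    tc_cluster=0.5, tc_known=0.5,
)
result = run_prospective(
    config, matrix=matrix, library=library,
    known_fps=[library[0].fingerprint],  # pretend the first compound is a known
)

print("stage survivor counts:", result["counts"])
print("first candidates:", result["candidates"][:5])

# "ranked" counts compounds with at least one successful docking; the PAINS
# stage removes the spiked interference fixtures; the similarity stage drops
# anything with Tanimoto > 0.5 to the known ligand; clustering leaves one
# best-scoring representative per chemotype, capped at top_n_clusters.
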