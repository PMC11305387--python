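# dockeval

Evaluation and triage toolkit for structure-based virtual screening
campaigns against predicted receptor structures.

When a drug-discovery team docks a multi-million-compound library against
computational models of a receptor — for example, homology models and
machine-learning-predicted structures of a G protein–coupled receptor with
no experimental structure — most of the scientific content is not in the
docking engine but in the bookkeeping around it: how model quality is
quantified against known ligands, how the prospective hit list is filtered
and clustered, how the experimental outcome is summarised, and how the
models are ultimately judged against a later experimental structure.
`dockeval` implements that layer as a reusable library:

- **Retrospective enrichment** — ROC curves over actives and
  property-matched decoys per receptor model; the adjusted semilogarithmic
  **LogAUC** (area under TPR vs log₁₀ FPR on [λ, 1], normalised to percent,
  minus the random-classifier contribution, so random = 0 and perfect
  ≈ 85.54 at λ = 10⁻³) and the **enrichment factor**
  EF_f = (actives in the top ⌈f·N⌉ / all actives) / f;
  ensemble summaries with nearest-rank percentile cuts and greedy max-min
  selection of a diverse top-model subset.
- **Property-matched decoys** — per-active nearest neighbours in an
  IQR-normalised space of MW, cLogP, HBD, HBA, net charge and rotatable
  bonds, with an ECFP4 Tanimoto ceiling against every active.
- **Prospective triage** — per-compound best score over the model ensemble
  (lower = better), PAINS substructure filter (RDKit's standard catalog or a
  user SMARTS file), strict-threshold similarity filter against known
  ligands, and rank-ordered leader (sphere-exclusion) clustering at
  Tc = 0.5 on Morgan/1024/radius-2 fingerprints, yielding one best-scoring
  candidate per chemotype.
- **Hit statistics** — hit rates with half-up integer rounding, overlap-
  adjusted hit rates, top-k ranked-list overlap, pEC50 summaries and
  fold-potency ratios 10^(pEC50_a − pEC50_b), percent pre-pulse inhibition
  [1 − prepulse/startle]·100, and K_p,brain = AUC_brain/AUC_plasma from
  trapezoidal concentration–time AUCs with homogenate dilution correction.
- **Structure comparison** — per-region Kabsch superposition and Cα RMSD,
  plus binding-site side-chain RMSD with **symmetry correction** (Phe/Tyr
  ring, Asp/Glu carboxylate, Arg guanidinium relabelings), so a phenyl ring
  flip scores 0 Å instead of ~1.5 Å.
- **Synthetic data** — seeded generators for score matrices with known
  active/decoy separations and docking-failure masks, fragment-like
  libraries (with PAINS fixtures), toy structure pairs with known rigid
  motion/noise/label swaps, and assay fixtures with known ground truth, so
  every stage is testable end to end without external downloads.

## Worked example

```python
import numpy as np
import dockeval as dk

deltas = list(np.linspace(0.2, 2.0, 10))          # graded model quality
spec = dk.ScoreSimSpec(n_models=10, n_actives=100, n_decoys=6500,
                       separation_per_model=deltas, fail_rate=0.05, seed=42)
summary = dk.evaluate_model_ensemble(dk.gen_score_matrix(spec))
print(f"{summary.median_logauc():.2f}", dk.select_models(summary, percentile=50, k=3))
```

prints

```
21.23 ['model_10', 'model_9', 'model_8']
```

— the median adjusted LogAUC of the ten models, and the three models picked
from the top half: exactly the three simulated with the largest
active/decoy separation, i.e. the enrichment metric recovers the planted
model-quality order. The same workflow is available from the shell
(`dockeval simulate|enrich|select-models|make-decoys|triage|hitstats|rmsd|run-retrospective|run-prospective`),
and `examples/` contains one short narrative script per capability.

The package also ships the tested-compound table of a published pair of
prospective screens against the trace amine–associated receptor TAAR1 (one
screen on AlphaFold models, one on homology models; 62 candidates tested,
25 confirmed agonists). `examples/05_hit_statistics.py` reproduces its
headline statistics:

```
AlphaFold-model screen: 18/30 hits = 60.0% (reported 60%), pEC50 5.1–7.5
homology-model screen: 7/32 hits = 21.9% (reported 22%), pEC50 4.9–6.5
best hit (compound 30, pEC50 7.5) is 25.1-fold more potent than Ulotaront (pEC50 6.1)
its EC50 is 0.03 uM
```

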