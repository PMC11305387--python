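# Methods

This note documents the statistical and geometric procedures implemented in
`dockeval`, the conventions they rely on, the defaults and why, and what the
synthetic-data layer does and does not emulate.

## Score convention and missing data

Docking scores are energies: **lower is better**, everywhere. A compound
that fails to dock in a model (steric clashes, no acceptable pose) has no
score in that model; this is carried as an explicit boolean mask, never as
a sentinel value. A masked compound is excluded from that model's ranking
only, so the effective database size N varies per model — mirroring real
ensemble screens, where each receptor conformation docks a different
subset of the library.

All ranking-derived quantities use one tie rule: stable sort by
(score, compound id). This matters at boundaries — the EF numerator at the
top-fraction cutoff, and leader identity in clustering — and makes every
result deterministic.

## Adjusted semilog LogAUC

Early recognition dominates practical screen utility: the difference
between a useful and a useless model lives in the first fraction of a
percent of a multi-million-compound ranking, which the ordinary AUC barely
sees. The adjusted LogAUC therefore integrates the ROC's TPR against
log₁₀ FPR on [λ, 1] (default λ = 10⁻³, exposed as a parameter), normalises
by log₁₀(1/λ), scales to percent, and subtracts the same integral of the
diagonal, (1 − λ)/(ln 10 · log₁₀(1/λ)) ≈ 14.462% at λ = 10⁻³. A random
ranking scores 0; a perfect one scores 100 − 14.462 = 85.538; the worst
possible is −14.462.

Numerics: the ROC is built with one step per ranked compound (see tie rule
above); TPR at FPR = λ is obtained by linear interpolation and points below
λ are discarded after interpolation. Each remaining segment is treated as
linear in FPR and integrated against d log₁₀ FPR in closed form,
[(y₁ − m·x₁)·ln(x₂/x₁) + m·(x₂ − x₁)]/ln 10. For a step curve this reduces
to the trapezoid rule on the log axis; for interpolated or analytic
segments it is exact — in particular the diagonal scores exactly 0 rather
than the sizeable positive artefact a log-axis trapezoid would produce.

The metric is invariant under strictly monotone transforms of the scores
(tested), since it depends on the ranking only.

## Enrichment factor

EF_f = (actives among the top ⌈f·N⌉ ranked compounds / all scored actives)
/ f, default f = 0.01. The ceiling in the cutoff guarantees a non-empty top
set for every f > 0. EF ranges over [0, 1/f], with 1 the random
expectation (verified by simulation).

## Ensemble summary, percentile cut, model selection

Per-model results aggregate into an ensemble summary with median and
arbitrary percentile statistics recomputable from the per-model list. The
percentile cut uses the **nearest-rank** convention: with n models, the
models strictly above the ⌈p/100·n⌉-th smallest LogAUC are "at the p-th
percentile", so the 98th percentile of 1000 models is exactly the top 20.

Selection of the k models for a prospective ensemble (default k = 5 from
the 98th-percentile subset): top-k by LogAUC when no structural-diversity
information is given; with a pairwise model-distance matrix (e.g.
binding-site heavy-atom RMSD between models), greedy max-min selection
seeded at the best-LogAUC model — each step adds the eligible model whose
minimum distance to the current set is largest, ties broken by higher
LogAUC then id. Greedy max-min was chosen over exact subset optimisation
because it is deterministic, O(k·n), and keeps the best-enriching model in
the set by construction; it is not guaranteed to find the globally optimal
max-min subset. The diversity measure itself is deliberately a caller
input: which notion of "diverse binding sites" is appropriate depends on
the receptor and is not fixed by the method.

## Property-matched decoys

For benchmarking, decoys should look like the actives physicochemically
(so enrichment measures molecular recognition, not property bias) while
being topologically unrelated (so they are plausibly non-binders). For
each active, in input order, the `ratio` unused pool members with the
smallest Euclidean distance in normalised property space are selected,
subject to ECFP4 Tanimoto ≤ `tc_exclude` against **all** actives and global
deduplication. Defaults:

- `ratio = 65`: reproduces the conventional ~65 decoys per ligand of
  docking benchmarks (e.g. 11,392 decoys for 173 ligands).
- Properties: MW (Da), Crippen cLogP, H-bond-donor hydrogens (N–H/O–H
  count), N+O acceptor count, net formal charge, strict rotatable bonds —
  computed with RDKit.
- Normalisation: per-property interquartile range of the pool (robust to
  outliers; degenerate zero IQRs fall back to 1), overridable.
- `tc_exclude = 0.35`: the conventional "topologically novel" threshold;
  exposed because published decoy pipelines differ and rarely state it.

Greedy per-active assignment in input order is O(|pool|·|actives|) and
reproducible; it does not globally minimise the summed property distance.

## Triage cascade

1. **Ensemble best score.** Each compound keeps the minimum score over its
   non-missing model entries; compounds missing everywhere are dropped and
   logged. The top `top_n_input` (default 40,000) proceed.
2. **PAINS.** A compound is removed iff at least one pan-assay-interference
   substructure pattern matches. The default catalog is RDKit's standard
   three-family PAINS set (480 patterns); a SMARTS file can be supplied to
   reproduce any other dialect exactly. Unparseable SMILES are quarantined
   to a rejects list with a reason, never silently dropped and never fatal.
3. **Known-ligand similarity.** Removed iff max ECFP4 Tc over the knowns is
   **strictly greater** than `tc_known` (default 0.5); a compound at
   exactly the threshold is kept. Empty knowns keep everything, with a
   warning. Tc is |A∩B|/|A∪B| on Morgan radius-2, 1024-bit fingerprints,
   with 0/0 defined as 0 (an empty fingerprint is dissimilar to
   everything, including itself).
4. **Leader clustering.** Single-pass sphere exclusion in rank order at
   `tc_cluster` (default 0.5): a compound founds a new cluster iff its Tc
   to every existing leader is below the threshold, else joins the first
   (best-ranked) leader at or above it. Leaders are therefore pairwise
   dissimilar and each cluster's leader is its best-scoring member, which
   is exactly the representative one wants for per-chemotype candidate
   picking. The leaders of the best `top_n_clusters` (default 2000)
   clusters form the candidate list.

The final human step of real campaigns — visual inspection of binding
modes within the top clusters — is intentionally not modelled; the package
exports the top-cluster leaders and annotations for that inspection.

Both filters are pure per-compound predicates, so the cascade's outcome as
a set does not depend on filter order (tested).

## Hit statistics

- Hit criterion: agonist activity with efficacy > 50% of the reference
  agonist's maximal response at the screening concentration; the
  `TestedCompound` container enforces consistency between the hit flag and
  Emax when both are present.
- Reported hit-rate percentages are rounded **half-up** to integers
  (21.875% reports as 22%), alongside the raw value.
- Overlap-adjusted hit rate: compounds found by both screens are removed
  from numerator and denominator, so the adjusted rate reflects a screen's
  unique proposals. This is the only convention computable from per-screen
  totals plus the shared-id set alone; published "adjusted" figures that
  do not state which shared compounds were hits cannot be uniquely
  recomputed under any convention.
- Top-k overlap: 100·|topK(A) ∩ topK(B)|/k, default k = 10,000; for two
  independent random orderings of N compounds the expectation is 100·k/N %
  (verified by simulation against the hypergeometric expectation).
- Potency: pEC50 = −log₁₀ EC50[M]; fold potency 10^(pEC50_a − pEC50_b);
  EC50 conversions reported in μM at 2 d.p. by default. Sanity bounds
  (3, 12) on pEC50 catch unit errors at construction.
- PPI% = [1 − prepulse/startle]·100 per intensity; mean PPI is the
  arithmetic mean over the (three) intensities.
- K_p,brain: linear-trapezoid AUC of each concentration–time series, brain
  homogenate concentrations multiplied by the dilution factor (4 for 1:3
  w/v homogenate) before integration, then AUC_brain/AUC_plasma. AUC is
  additive over grid splits and K_p is invariant to common rescaling
  (tested).

## Structure comparison

- Superposition: least-squares rigid (Kabsch) fit via
  `scipy.spatial.transform.Rotation.align_vectors`, proper rotation
  enforced; N ≥ 3 non-collinear paired atoms required.
- Regions: named selections by (chain, author residue number) — an
  explicit binding-site list, plus inclusive ranges for
  extracellular-TM/loop regions; residues are paired by identical
  numbering (or a caller-supplied map); full sequence alignment is out of
  scope. The shipped default binding-site list is the union of pocket
  residues named in experimental agonist-bound structures of the trace
  amine receptor (103, 184, 186, 194, 195, 198, 267, 268 in author
  numbering, with their Ballesteros–Weinstein labels precomputed in the
  YAML comment).
- Per-region protocol: fit on the region's own paired Cα atoms, report Cα
  RMSD; the binding-site row additionally reports side-chain heavy-atom
  RMSD in that same frame (no re-fit), plain and symmetry-corrected. A
  whole-fit mode (one shared frame from all paired Cα) is available behind
  a flag, since published side-chain RMSDs are computed under both
  conventions. Regions with fewer than 3 paired Cα are marked
  not-computable; missing residues reduce the disclosed atom counts but do
  not fail the region.
- Symmetry correction: per residue, the catalog permutation (Phe/Tyr
  CD1↔CD2 + CE1↔CE2 as one unit; Asp OD1↔OD2; Glu OE1↔OE2; Arg NH1↔NH2)
  minimising that residue's squared deviation is applied, then the global
  RMSD recomputed. Because the frame is fixed, per-residue minimisation is
  globally optimal (verified against exhaustive enumeration over all swap
  combinations); corrected ≤ plain always. Residue types outside the
  catalog are treated as having no symmetry, with a log entry. Hydrogens
  are ignored; the highest-occupancy altloc is kept; mmCIF is not
  supported.

## Synthetic data: what it emulates, and what it does not

- **Score matrices**: actives ~ Normal(−δ_m, σ), decoys ~ Normal(0, σ) per
  model m, with independent Bernoulli(fail_rate) missingness. This
  reproduces the *shape* of ensemble-screen output — graded model quality,
  per-model database sizes, failure masks — with a known ground-truth
  model ordering, which the enrichment layer provably recovers
  (Spearman ≥ 0.95 between δ rank and LogAUC rank over 50 models with 200
  actives and 13,000 decoys). It does **not** model docking-energy
  physics, score correlations between models, or the heavy left tail of
  real score distributions; passing tests show metric correctness and
  ranking recovery, not docking realism.
- **Libraries**: random fingerprints at a set-bit density of 0.08
  (roughly the on-bit fraction of folded ECFP4 fingerprints of
  fragment-sized molecules) and properties uniform over fragment-like
  bounds (MW 100–250 Da, cLogP −1–3.5). Real libraries have correlated
  bits and property covariances; tests that rely on Tanimoto geometry use
  real RDKit fingerprints where it matters (PAINS fixtures, decoy
  examples). The shipped PAINS fixtures are molecules chosen to trigger
  the shipped filter patterns — test fixtures, not claims about assay
  behaviour.
- **Toy structures**: glycine-like four-atom residues on a random 3.8 Å
  walk, every fifth residue a phenylalanine with an ideal planar ring, the
  pair related by an exact rigid motion plus isotropic Gaussian noise, ring
  labels swapped in the copy with the permutation recorded. Expected
  post-fit RMSD under noise σ is σ√3 (fit bias is negligible at ≥500
  atoms), which the tests assert. No stereochemistry, no realistic
  backbone geometry.
- **Assay fixtures**: potency tables with known hit counts, startle tables
  built from chosen PPI% values, and concentration–time curves constructed
  so the dilution-corrected brain/plasma AUC ratio is exactly 5.

All generators are deterministic given (spec, seed), byte-identically so
through their CSV/PDB serialisations.

## Problem sizes

The default test and reproduction runs use desk-scale sizes chosen to make
every check exact or tightly toleranced while completing in seconds on one
CPU: 200-compound EF instances against exhaustive counting, 50-compound
clustering against a loop oracle, 1000 replicates for the random-EF mean,
and the 50-model × 13,200-compound ensemble for separation recovery.
Campaign-scale quantities that depend on multi-million-compound libraries
and thousand-model ensembles (absolute cluster counts, top-10,000 overlap
percentages between specific screens, RMSDs to particular experimental
structures) are outside what synthetic data can reproduce; the
corresponding machinery is exercised end to end at small scale instead.

## Known limitations

- No docking, pose handling, or rescoring; scores are inputs.
- Decoy generation does not enumerate protonation states or tautomers;
  library preparation is upstream.
- The greedy selections (max-min models, per-active decoys) are
  deterministic heuristics, not global optima.
- Structure comparison assumes shared author numbering and PDB input.
- 4-parameter concentration–response fitting, behavioural-statistics
  ANOVA, and compartmental PK modelling are deliberately out of scope;
  their outputs (pEC50s, readings) are consumed as inputs.
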