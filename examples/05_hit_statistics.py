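"""Hit-rate, potency, and assay statistics on the packaged screen results.

Uses the packaged table of 62 experimentally evaluated candidates from the
two published trace-amine-receptor docking screens (machine-learning models
vs homology models) plus synthetic assay fixtures.
"""

import dockeval as dk
from dockeval.datasets import load_tested_compounds

af = load_tested_compounds("af")
hm = load_tested_compounds("hm")
ref = {t.id: t for t in load_tested_compounds("reference")}

for name, tested in (("AlphaFold-model screen", af), ("homology-model screen", hm)):
    raw, rounded = dk.hit_rate(tested)
    pot = dk.potency_summary(tested)
    print(f"{name}: {sum(t.is_hit for t in tested)}/{len(tested)} hits "
          f"= {raw:.1f}% (reported {rounded}%), "
          f"pEC50 {pot['min_pec50']:.1f}–{pot['max_pec50']:.1f}")

best = max((t for t in af if t.pec50), key=lambda t: t.pec50)
fold = dk.fold_potency(best.pec50, ref["Ulotaront"].pec50)
print(f"best hit (compound {best.id}, pEC50 {best.pec50}) is {fold:.1f}-fold "
      f"more potent than Ulotaront (pEC50 {ref['Ulotaront'].pec50})")
print(f"its EC50 is {dk.ec50_micromolar(best.pec50)} uM")

# synthetic pharmacokinetics fixture: brain/plasma AUC ratio built to be 5
fx = dk.gen_assay_fixtures(seed=0)
pk = dk.brain_penetrance(fx["pk_plasma"], fx["pk_brain"])
print(f"K_p,brain from the synthetic concentration-time curves: "
      f"{pk['kp_brain']:.2f} (ground truth {fx['ground_truth']['kp_brain']})")

# PPI% formula on the startle fixture: [1 - prepulse/startle] x 100
row = fx["startle"].iloc[1]
print(f"PPI at {row['prepulse_db']:.0f} dB prepulse: "
      f"{dk.ppi_percent(row['startle_only_mean'], row['prepulse_mean']):.0f}%")
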