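"""Property-matched decoy generation from SMILES.

Takes three small aminergic-like actives and selects, per active, the pool
candidates closest in normalised property space while topologically
dissimilar (ECFP4 Tanimoto ≤ 0.35 to every active).
"""

from dockeval import CompoundRecord, compute_properties, match_decoys
from dockeval.fingerprints import morgan_fingerprint


def record(cid, smiles):
    return CompoundRecord(
        id=cid, smiles=smiles,
        fingerprint=morgan_fingerprint(smiles),
        properties=compute_properties(smiles).as_array(),
    )


actives = [
    record("pea", "NCCc1ccccc1"),          # phenethylamine
    record("tyramine", "NCCc1ccc(O)cc1"),
    record("amphetamine", "CC(N)Cc1ccccc1"),
]
pool_smiles = [
    "CCOC(=O)C1CCCN1", "O=C(N)c1ccco1", "CCN1CCCC1=O", "OCC1CCCCO1",
    "CC(=O)NC1CCCC1", "O=S(=O)(N)c1ccsc1", "CCOCC(=O)OC", "NC(=O)C1CCC1",
    "CN1CCOCC1", "O=C1CCCN1C", "CCC(=O)OCC", "CC1CCCO1",
    "OC(=O)C1CCCC1", "CNC(=O)CCC", "CCCNC(C)=O", "COCCOC",
    "CC(C)CC(N)=O", "O=C(O)CCN", "CCCCO", "CC1CCNC1",
]
pool = [record(f"pool_{i:02d}", s) for i, s in enumerate(pool_smiles)]

decoys = match_decoys(actives, pool, ratio=4, tc_exclude=0.35)
print(decoys.to_frame().to_string(index=False, float_format="%.3f"))
print(f"\nexcluded as too similar to an active: {len(decoys.exclusion_log)}")

# Each active receives 4 decoys; property_distance is the Euclidean distance
# in (MW, cLogP, HBD, HBA, charge, rotatable bonds) space scaled by the
# pool's interquartile ranges — 0 means a perfect physicochemical twin.
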