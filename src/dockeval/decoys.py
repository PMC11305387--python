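"""Property-matched decoy generation.

For a benchmark of known actives, decoys are presumed non-binders that match
the actives' physicochemical profile (so ranking metrics measure recognition
of chemistry rather than of crude property differences) while being
topologically dissimilar (so no decoy is secretly an analogue of an active).
Matching is nearest-neighbour in a normalised property space; dissimilarity
is enforced with an ECFP4 Tanimoto ceiling against *all* actives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .records import CompoundRecord

__all__ = ["PropertyVector", "DecoySet", "compute_properties", "match_decoys",
           "PROPERTY_NAMES"]

PROPERTY_NAMES = (
    "molecular_weight",
    "clogp",
    "hbd",
    "hba",
    "net_charge",
    "rotatable_bonds",
)


@dataclass(frozen=True)
class PropertyVector:
    """The six matched physicochemical properties.

    molecular_weight in Da; clogp is the Crippen estimate; hbd counts N–H and
    O–H hydrogens; hba counts N and O acceptor atoms; net_charge is the sum
    of formal charges as written; rotatable_bonds is the standard strict
    rotatable-bond count.
    """

    molecular_weight: float
    clogp: float
    hbd: int
    hba: int
    net_charge: int
    rotatable_bonds: int

    def as_array(self) -> np.ndarray:
        return np.asarray([getattr(self, p) for p in PROPERTY_NAMES], dtype=float)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        for p in ("hbd", "hba", "rotatable_bonds"):
            if getattr(self, p) < 0:
                raise ValueError(f"{p} must be non-negative")


def compute_properties(smiles: str) -> PropertyVector:
    """Property vector of a molecule from its SMILES.

    Raises ``ValueError`` carrying the input string if RDKit cannot parse or
    sanitize it.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return PropertyVector(
        molecular_weight=float(Descriptors.MolWt(mol)),
        clogp=float(Crippen.MolLogP(mol)),
        hbd=int(Lipinski.NHOHCount(mol)),
        hba=int(Lipinski.NOCount(mol)),
        net_charge=int(Chem.GetFormalCharge(mol)),
        rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
    )


@dataclass
class DecoySet:
    """Chosen decoys per active plus a log of every rejected candidate."""

    per_active: dict[str, list[tuple[str, float]]]  # active id -> [(decoy id, dist)]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def decoy_ids(self) -> list[str]:
        out: list[str] = []
        for picks in self.per_active.values():
            out.extend(d for d, _ in picks)
        return out

    def to_frame(self):
        import pandas as pd

        rows = [
            {"active_id": a, "decoy_id": d, "property_distance": dist}
            for a, picks in self.per_active.items()
            for d, dist in picks
        ]
        return pd.DataFrame(rows)


def _property_scales(pool_props: np.ndarray) -> np.ndarray:
    """Per-property interquartile range over the pool; robust, never zero."""
    q75, q25 = np.percentile(pool_props, [75, 25], axis=0)
    iqr = q75 - q25
    iqr[iqr <= 0] = 1.0
    return iqr


def match_decoys(
    actives: list[CompoundRecord],
    pool: list[CompoundRecord],
    ratio: int = 65,
    tc_exclude: float = 0.35,
    property_scales: np.ndarray | None = None,
) -> DecoySet:
    """Pick ``ratio`` property-matched decoys per active from a candidate pool.

    For each active, in input order, the ``ratio`` not-yet-used pool members
    with the smallest normalised Euclidean property distance are taken,
    subject to the candidate's ECFP4 Tanimoto to *every* active being
    ≤ ``tc_exclude``. Properties are scaled by the pool interquartile range
    unless explicit ``property_scales`` are given. Deterministic: distance
    ties break by candidate id.

    The default ratio of 65 reproduces the conventional benchmark shape of
    roughly 65 decoys per ligand (e.g. 11,392 decoys for 173 ligands).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if not actives:
        raise ValueError("no actives supplied")
    if not (0.0 <= tc_exclude <= 1.0):
        raise ValueError("tc_exclude must be in [0, 1]")

    act_fps = np.stack([a.fingerprint for a in actives])
    pool_props = np.stack([c.properties for c in pool])
    scales = (
        np.asarray(property_scales, dtype=float)
        if property_scales is not None
        else _property_scales(pool_props)
    )

    from .fingerprints import tanimoto_matrix

    pool_fps = np.stack([c.fingerprint for c in pool])
    max_tc = tanimoto_matrix(pool_fps, act_fps).max(axis=1)

    exclusion_log: list[tuple[str, str]] = []
    feasible_idx = []
    for i, rec in enumerate(pool):
        if max_tc[i] > tc_exclude:
            exclusion_log.append(
                (rec.id, f"Tc {max_tc[i]:.3f} > {tc_exclude} to an active")
            )
        else:
            feasible_idx.append(i)

    need = ratio * len(actives)
    if len(feasible_idx) < need:
        raise ValueError(
            f"pool exhausted: {len(feasible_idx)} feasible candidates after "
            f"similarity exclusion, need {need} ({ratio} × {len(actives)} actives)"
        )

    feasible_idx = np.asarray(feasible_idx, dtype=int)
    used = np.zeros(len(pool), dtype=bool)
    per_active: dict[str, list[tuple[str, float]]] = {}
    for a_i, active in enumerate(actives):
        diffs = (pool_props[feasible_idx] - active.properties[None, :]) / scales
        dists = np.sqrt((diffs**2).sum(axis=1))
        order = sorted(
            range(len(feasible_idx)),
            key=lambda j: (dists[j], pool[feasible_idx[j]].id),
        )
        picks: list[tuple[str, float]] = []
        for j in order:
            gi = feasible_idx[j]
            if used[gi]:
                continue
            used[gi] = True
            picks.append((pool[gi].id, float(dists[j])))
            if len(picks) == ratio:
                break
        if len(picks) < ratio:
            raise ValueError(
                f"pool exhausted for active {active.id!r}: got {len(picks)} "
                f"of {ratio} decoys"
            )
        per_active[active.id] = picks
    return DecoySet(per_active=per_active, exclusion_log=exclusion_log)
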