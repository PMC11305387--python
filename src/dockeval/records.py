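"""Compound library records and .smi / properties-CSV IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CompoundRecord:
    """One library member.

    ``fingerprint`` is a fixed-length boolean bit vector (ECFP4 for real
    molecules, synthetic bits for simulated libraries); ``properties`` is the
    six-component physicochemical vector in the order defined by
    :data:`dockeval.decoys.PROPERTY_NAMES`. ``smiles`` is optional: simulated
    libraries carry fingerprints and properties without structures.
    """

    id: str
    fingerprint: np.ndarray
    properties: np.ndarray
    smiles: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fingerprint = np.asarray(self.fingerprint, dtype=bool)
        self.properties = np.asarray(self.properties, dtype=float)


def write_smi(records: list[CompoundRecord], path: str | Path) -> None:
    """SMILES<TAB>id, one per line; records without SMILES are skipped."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.smiles is not None:
                fh.write(f"{rec.smiles}\t{rec.id}\n")


def read_smi(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file into (smiles, id) pairs; missing ids are numbered."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"cmpd_{i + 1}"
            out.append((smiles, cid))
    return out


def write_properties_csv(records: list[CompoundRecord], path: str | Path) -> None:
    from .decoys import PROPERTY_NAMES

    rows = []
    for rec in records:
        row = {"compound_id": rec.id}
        row.update(dict(zip(PROPERTY_NAMES, rec.properties)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
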