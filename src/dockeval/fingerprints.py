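"""Binary fingerprints and Tanimoto similarity.

Fingerprints are represented as 1-D uint8/bool numpy arrays of fixed length
(default 1024 bits). ECFP4 fingerprints of real molecules are generated with
RDKit's Morgan generator (radius 2) and converted to the same representation,
so synthetic and chemistry-derived fingerprints flow through identical code.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

DEFAULT_N_BITS = 1024

_morgan_gens: dict[int, object] = {}


def _morgan_generator(n_bits: int):
    gen = _morgan_gens.get(n_bits)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        _morgan_gens[n_bits] = gen
    return gen


def morgan_fingerprint(smiles: str, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """ECFP4 (Morgan radius-2) fingerprint folded to ``n_bits``, as a bool array.

    Raises ``ValueError`` for SMILES RDKit cannot parse/sanitize.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    bv = _morgan_generator(n_bits).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over bit vectors.

    The degenerate 0/0 case (both fingerprints empty) is defined as 0, so an
    all-zero fingerprint is maximally dissimilar to everything including
    itself.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between the rows of two fingerprint stacks.

    Vectorised; rows are bit vectors. Returns shape (len(a), len(b)).
    """
    a = np.asarray(fps_a, dtype=bool)
    b = np.asarray(fps_b, dtype=bool)
    inter = a.astype(np.int32) @ b.T.astype(np.int32)
    pop_a = a.sum(axis=1, dtype=np.int32)
    pop_b = b.sum(axis=1, dtype=np.int32)
    union = pop_a[:, None] + pop_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / union, 0.0)
    return tc
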