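"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the data shapes a virtual-screening
campaign produces: per-model docking-score tables in which actives are
shifted toward better (lower) scores by a tunable separation and a tunable
fraction of compounds fails to dock; fragment-like compound libraries with
property vectors and fingerprints; toy 3-D structure pairs related by a
rigid motion plus noise, with a symmetric side-chain atom group whose labels
are swapped; and small assay fixtures (potency tables, startle readings,
concentration–time curves) with known ground-truth parameters.

Everything is driven by an explicit integer seed and is bit-reproducible:
the same spec and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hitstats import AssaySeries
from .records import CompoundRecord
from .scorematrix import ACTIVE, DECOY, ScoreMatrix
from .structure import Residue, Structure

__all__ = [
    "ScoreSimSpec",
    "LibrarySimSpec",
    "PAINS_FIXTURES",
    "gen_score_matrix",
    "gen_compound_library",
    "gen_toy_structures",
    "gen_assay_fixtures",
    "write_pdb",
]

# Small molecules that match the shipped PAINS catalog (catechols, quinones,
# rhodanines, phenolic hydrazones). They are *test fixtures* chosen to
# trigger the filter patterns, not claims about real PAINS chemistry.
PAINS_FIXTURES: list[tuple[str, str]] = [
    ("pains_catechol", "Oc1ccccc1O"),
    ("pains_quinone", "O=C1C=CC(=O)C=C1"),
    ("pains_rhodanine", "O=C1CSC(=S)N1"),
    ("pains_ene_rhodanine", "O=C1C(=Cc2ccccc2)SC(=S)N1"),
    ("pains_hzone_phenol", "Oc1ccccc1/C=N/Nc1ccccc1"),
]

# Fragment-like default property bounds (LogP < 3.5, MW < 250 Da), matching
# the library-construction criteria of fragment screens.
DEFAULT_PROPERTY_RANGES: dict[str, tuple[float, float]] = {
    "molecular_weight": (100.0, 250.0),
    "clogp": (-1.0, 3.5),
    "hbd": (0, 3),
    "hba": (0, 6),
    "net_charge": (-1, 1),
    "rotatable_bonds": (0, 5),
}

_COUNT_PROPERTIES = {"hbd", "hba", "net_charge", "rotatable_bonds"}


# ------------------------------------------------------------ score matrices


@dataclass
class ScoreSimSpec:
    """Simulation spec for an actives/decoys docking-score matrix.

    ``separation_per_model`` holds the per-model score shift δ_m (score
    units) by which actives are moved toward better scores; ``fail_rate`` is
    the probability that any given compound fails to dock in any given model
    (failures are independent), emulating the sizeable docking-failure
    fraction of real screens.
    """

    n_models: int
    n_actives: int
    n_decoys: int
    separation_per_model: list[float]
    noise_sd: float = 1.0
    fail_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models: must be >= 1")
        if self.n_actives < 1:
            raise ValueError("n_actives: must be >= 1")
        if self.n_decoys < 1:
            raise ValueError("n_decoys: must be >= 1")
        if len(self.separation_per_model) != self.n_models:
            raise ValueError(
                "separation_per_model: length must equal n_models "
                f"({len(self.separation_per_model)} != {self.n_models})"
            )
        if not (0.0 <= self.fail_rate < 1.0):
            raise ValueError("fail_rate: must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd: must be positive")


def gen_score_matrix(spec: ScoreSimSpec) -> ScoreMatrix:
    """Simulate a compound × model score matrix with known separations.

    Actives score Normal(−δ_m, noise_sd) in model m, decoys Normal(0,
    noise_sd); lower = better, so larger δ_m means the model separates
    actives better. Entries are masked missing independently with
    probability ``fail_rate``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_actives + spec.n_decoys
    delta = np.asarray(spec.separation_per_model, dtype=float)
    base = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_models))
    shift = np.zeros((n, 1))
    shift[: spec.n_actives, 0] = 1.0
    scores = base - shift * delta[None, :]
    missing = rng.random(size=scores.shape) < spec.fail_rate
    ids = [f"act_{i + 1:05d}" for i in range(spec.n_actives)] + [
        f"dec_{i + 1:05d}" for i in range(spec.n_decoys)
    ]
    labels = [ACTIVE] * spec.n_actives + [DECOY] * spec.n_decoys
    return ScoreMatrix(
        compound_ids=ids,
        labels=labels,
        scores=scores,
        missing=missing,
        model_ids=[f"model_{j + 1}" for j in range(spec.n_models)],
    )


# ------------------------------------------------------------- libraries


@dataclass
class LibrarySimSpec:
    """Simulation spec for a fragment-like compound library."""

    n_compounds: int
    fingerprint_bits: int = 1024
    bit_density: float = 0.08
    property_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTY_RANGES)
    )
    include_pains_fixtures: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 0:
            raise ValueError("n_compounds: must be >= 0")
        if self.fingerprint_bits < 1:
            raise ValueError("fingerprint_bits: must be >= 1")
        if not (0.0 <= self.bit_density <= 1.0):
            raise ValueError("bit_density: must be in [0, 1]")
        for name, (lo, hi) in self.property_ranges.items():
            if hi < lo:
                raise ValueError(f"property_ranges[{name}]: high < low")


def gen_compound_library(spec: LibrarySimSpec) -> list[CompoundRecord]:
    """Simulate a library of compound records with fingerprints and properties.

    Count-valued properties are drawn uniformly over the integer range,
    continuous ones uniformly over the real range. When
    ``include_pains_fixtures`` is set, the documented PAINS fixture molecules
    are appended with their real ECFP4 fingerprints and computed properties,
    flagged via ``extra["pains_fixture"] = True``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    from .decoys import PROPERTY_NAMES

    records: list[CompoundRecord] = []
    fps = rng.random(size=(spec.n_compounds, spec.fingerprint_bits)) < spec.bit_density
    for i in range(spec.n_compounds):
        props = []
        for name in PROPERTY_NAMES:
            lo, hi = spec.property_ranges[name]
            if name in _COUNT_PROPERTIES:
                props.append(float(rng.integers(int(lo), int(hi) + 1)))
            else:
                props.append(float(rng.uniform(lo, hi)))
        records.append(
            CompoundRecord(
                id=f"lib_{i + 1:06d}",
                fingerprint=fps[i],
                properties=np.asarray(props),
            )
        )
    if spec.include_pains_fixtures:
        from .decoys import compute_properties
        from .fingerprints import morgan_fingerprint

        for name, smiles in PAINS_FIXTURES:
            records.append(
                CompoundRecord(
                    id=name,
                    smiles=smiles,
                    fingerprint=morgan_fingerprint(smiles, spec.fingerprint_bits),
                    properties=compute_properties(smiles).as_array(),
                    extra={"pains_fixture": True},
                )
            )
    return records


# ------------------------------------------------------------- toy structures


def _ideal_phe_ring(origin: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Ideal planar phenyl ring (bond 1.39 Å) attached at CB, random orientation.

    The CG–CZ axis is the ring's 2-fold symmetry axis: rotating 180° about it
    maps CD1↔CD2 and CE1↔CE2 exactly, so a label swap of those pairs is a
    pure nomenclature change.
    """
    r = 1.39
    angles = np.deg2rad([90.0, 30.0, -30.0, -90.0, 150.0, 210.0])
    names = ["CG", "CD1", "CE1", "CZ", "CD2", "CE2"]
    local = np.stack(
        [np.cos(angles) * r, np.sin(angles) * r, np.zeros(6)], axis=1
    )
    # shift so CG sits at the attachment point; random proper rotation
    local -= local[0]
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    coords = local @ rot.T + origin
    atoms = {name: coords[i] for i, name in enumerate(names)}
    atoms["CB"] = origin + (origin - atoms["CZ"]) / np.linalg.norm(origin - atoms["CZ"]) * 1.5
    return atoms


def gen_toy_structures(
    n_residues: int,
    rotation: tuple[float, float, float] = (0.3, -0.2, 0.5),
    translation: tuple[float, float, float] = (5.0, -3.0, 2.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    swap_symmetric_labels: bool = True,
) -> tuple[Structure, Structure, dict]:
    """A structure pair related by a known rigid motion plus isotropic noise.

    The first structure is a random coil of glycine-like residues (N, CA, C,
    O) with every fifth residue (and at least one) a phenylalanine carrying
    an ideal symmetric ring. The second structure is the rigid motion of the
    first (Euler angles ``rotation`` in radians, then ``translation``) with
    Normal(0, noise_sd) noise per coordinate; if ``swap_symmetric_labels``,
    the CD1/CD2 and CE1/CE2 labels of every phenylalanine are exchanged in
    the copy — geometry untouched, names permuted — and the ground-truth
    permutation is recorded.

    Returns ``(reference, moved, ground_truth)`` where ground_truth holds the
    rotation matrix, translation, noise level, and swapped residue keys.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    residues_a: list[Residue] = []
    pos = np.zeros(3)
    for i in range(n_residues):
        step = rng.normal(0, 1, size=3)
        step = step / np.linalg.norm(step) * 3.8
        pos = pos + step
        is_phe = i % 5 == 0
        atoms = {
            "N": pos + rng.normal(0, 0.2, 3) + np.array([-1.2, 0.3, 0.0]),
            "CA": pos.copy(),
            "C": pos + rng.normal(0, 0.2, 3) + np.array([1.3, 0.2, 0.0]),
            "O": pos + rng.normal(0, 0.2, 3) + np.array([2.0, 1.2, 0.1]),
        }
        if is_phe:
            ring_origin = pos + np.array([0.0, 1.8, 0.9])
            atoms.update(_ideal_phe_ring(ring_origin, rng))
        residues_a.append(
            Residue(chain="A", seqid=i + 1, name="PHE" if is_phe else "GLY",
                    atoms=atoms)
        )

    rot = Rotation.from_euler("xyz", rotation).as_matrix()
    trans = np.asarray(translation, dtype=float)
    swapped_keys: list[tuple[str, int]] = []
    residues_b: list[Residue] = []
    for res in residues_a:
        atoms_b = {
            name: xyz @ rot.T + trans + rng.normal(0, noise_sd, 3)
            for name, xyz in res.atoms.items()
        }
        if swap_symmetric_labels and res.name == "PHE":
            for a, b in (("CD1", "CD2"), ("CE1", "CE2")):
                atoms_b[a], atoms_b[b] = atoms_b[b], atoms_b[a]
            swapped_keys.append(res.key())
        residues_b.append(
            Residue(chain=res.chain, seqid=res.seqid, name=res.name, atoms=atoms_b)
        )
    ground_truth = {
        "rotation_matrix": rot,
        "translation": trans,
        "noise_sd": noise_sd,
        "swapped_residues": swapped_keys,
        "swap_pairs": [("CD1", "CD2"), ("CE1", "CE2")],
    }
    return Structure(residues_a), Structure(residues_b), ground_truth


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal PDB file (single model, author numbering preserved)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        chain = chains.get(res.chain)
        if chain is None:
            chain = gemmi.Chain(res.chain)
            chains[res.chain] = chain
        g_res = gemmi.Residue()
        g_res.name = res.name
        g_res.seqid = gemmi.SeqId(res.seqid, " ")
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            g_res.add_atom(atom)
        chain.add_residue(g_res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ------------------------------------------------------------- assay fixtures


def gen_assay_fixtures(seed: int = 0) -> dict:
    """Small assay tables with known ground truth for the statistics layer.

    Returns a dict with:

    - ``potency``: per-compound pEC50/Emax table (two screens, known hits),
    - ``startle``: startle-only and pre-pulse means at three intensities with
      the true PPI% per row,
    - ``pk_plasma`` / ``pk_brain``: :class:`AssaySeries` built so that the
      dilution-corrected brain AUC is exactly 5 × the plasma AUC,
    - ``ground_truth``: the parameters the tables were built from.
    """
    rng = np.random.default_rng(seed)

    n_af, hits_af = 10, 6
    n_hm, hits_hm = 8, 2
    rows = []
    for screen, n, hits in (("af", n_af, hits_af), ("hm", n_hm, hits_hm)):
        for i in range(n):
            is_hit = i < hits
            emax = float(rng.uniform(55, 110)) if is_hit else float(rng.uniform(5, 45))
            pec50 = float(rng.uniform(4.5, 7.5)) if is_hit else np.nan
            rows.append(
                {
                    "id": f"{screen}_{i + 1:02d}",
                    "origin": screen,
                    "is_hit": is_hit,
                    "pec50": round(pec50, 2) if is_hit else np.nan,
                    "emax_percent": round(emax, 1),
                }
            )
    potency = pd.DataFrame(rows)

    intensities = [68, 71, 77]
    startle = 100.0
    true_ppi = [30.0, 60.0, 90.0]
    startle_tbl = pd.DataFrame(
        {
            "prepulse_db": intensities,
            "startle_only_mean": [startle] * 3,
            "prepulse_mean": [startle * (1 - p / 100.0) for p in true_ppi],
            "true_ppi_percent": true_ppi,
        }
    )

    times = np.array([5.0, 30.0, 60.0, 120.0, 360.0])
    plasma_conc = np.array([850.0, 600.0, 300.0, 80.0, 5.0])
    kp_true = 5.0
    dilution = 4.0
    pk_plasma = AssaySeries(times, plasma_conc, matrix="plasma")
    # homogenate values chosen so dilution-corrected brain = kp_true × plasma
    pk_brain = AssaySeries(
        times, plasma_conc * kp_true / dilution, matrix="brain",
        dilution_factor=dilution,
    )

    return {
        "potency": potency,
        "startle": startle_tbl,
        "pk_plasma": pk_plasma,
        "pk_brain": pk_brain,
        "ground_truth": {
            "hit_rate_af_percent": 100.0 * hits_af / n_af,
            "hit_rate_hm_percent": 100.0 * hits_hm / n_hm,
            "true_ppi_percent": true_ppi,
            "kp_brain": kp_true,
        },
    }
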