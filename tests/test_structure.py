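"""Kabsch superposition, symmetry-corrected RMSD, region reports, PDB IO."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import dockeval as dk
from dockeval.simulate import write_pdb
from dockeval.structure import (
    SYMMETRIC_ATOM_SWAPS,
    Residue,
    Structure,
    apply_transform,
    rmsd_symmetric,
)


def test_kabsch_identity():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    rot, trans, rmsd = dk.kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-6)
    np.testing.assert_allclose(trans, 0.0, atol=1e-6)


def test_kabsch_recovers_rigid_motion():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(15, 3))
    true_rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
    moved = pts @ true_rot.T + np.array([3.0, -2.0, 8.0])
    rot, trans, rmsd = dk.kabsch_superpose(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-8)
    np.testing.assert_allclose(apply_transform(moved, rot, trans), pts, atol=1e-8)
    assert np.linalg.det(rot) == pytest.approx(1.0)


def rotation_search_oracle(a, b):
    """Independent optimum: numerical search over Euler angles + centroid shift."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def cost(angles):
        m = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt(((b0 @ m.T - a0) ** 2).sum() / len(a0))

    best = np.inf
    for start in itertools.product([-2.0, 0.0, 2.0], repeat=3):
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def test_kabsch_matches_rotation_search_oracle():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(10, 3))
    b = a + rng.normal(0, 0.3, size=(10, 3))
    _, _, rmsd = dk.kabsch_superpose(a, b)
    assert rmsd == pytest.approx(rotation_search_oracle(a, b), abs=1e-3)


def test_kabsch_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="3"):
        dk.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        dk.kabsch_superpose(line, line)


# --------------------------------------------------------- symmetry correction


def _phe_pair(flip=True):
    """A PHE residue and a copy with ring labels flipped (geometry identical)."""
    ref, moved, _ = dk.gen_toy_structures(
        1, rotation=(0, 0, 0), translation=(0, 0, 0), noise_sd=0.0, seed=6,
        swap_symmetric_labels=flip,
    )
    return ref.residues[0], moved.residues[0]


def test_ring_flip_scores_zero_after_correction():
    pair = _phe_pair(flip=True)
    plain, corrected, n = rmsd_symmetric([pair])
    assert plain > 0.5
    assert corrected == pytest.approx(0.0, abs=1e-9)
    assert n == len(pair[0].atoms)


def test_no_symmetric_atoms_corrected_equals_plain(rng):
    atoms_a = {"N": rng.normal(size=3), "CA": rng.normal(size=3),
               "C": rng.normal(size=3)}
    atoms_b = {k: v + rng.normal(0, 0.5, 3) for k, v in atoms_a.items()}
    pair = (Residue("A", 1, "GLY", atoms_a), Residue("A", 1, "GLY", atoms_b))
    plain, corrected, _ = rmsd_symmetric([pair])
    assert corrected == pytest.approx(plain)


def exhaustive_permutation_oracle(pairs):
    """Global minimum over every combination of catalog swaps (≤ 2^k)."""
    per_res_options = []
    names_list = []
    for res_a, res_b in pairs:
        names = [n for n in res_a.atoms if n in res_b.atoms]
        names_list.append(names)
        swaps = SYMMETRIC_ATOM_SWAPS.get(res_a.name, [])
        swaps = [g for g in swaps if all(a in names and b in names for a, b in g)]
        options = []
        for mask in range(1 << len(swaps)):
            mapping = {n: n for n in names}
            for g, group in enumerate(swaps):
                if mask & (1 << g):
                    for x, y in group:
                        mapping[x], mapping[y] = mapping[y], mapping[x]
            options.append(mapping)
        per_res_options.append(options)
    best = np.inf
    n_atoms = sum(len(n) for n in names_list)
    for combo in itertools.product(*per_res_options):
        ssd = 0.0
        for (res_a, res_b), mapping, names in zip(pairs, combo, names_list):
            xa = np.stack([res_a.atoms[n] for n in names])
            xb = np.stack([res_b.atoms[mapping[n]] for n in names])
            ssd += ((xa - xb) ** 2).sum()
        best = min(best, ssd)
    return float(np.sqrt(best / n_atoms))


def test_symmetry_correction_matches_exhaustive_minimum(rng):
    pairs = []
    for i, resname in enumerate(["PHE", "ASP", "GLU", "ARG", "TYR", "GLY"]):
        template = {
            "PHE": ["CA", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
            "TYR": ["CA", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
            "ASP": ["CA", "CB", "CG", "OD1", "OD2"],
            "GLU": ["CA", "CB", "CG", "CD", "OE1", "OE2"],
            "ARG": ["CA", "CZ", "NH1", "NH2"],
            "GLY": ["N", "CA", "C"],
        }[resname]
        atoms_a = {n: rng.normal(size=3) for n in template}
        atoms_b = {n: atoms_a[n] + rng.normal(0, 0.8, 3) for n in template}
        pairs.append(
            (Residue("A", i, resname, atoms_a), Residue("A", i, resname, atoms_b))
        )
    plain, corrected, _ = rmsd_symmetric(pairs)
    assert corrected == pytest.approx(exhaustive_permutation_oracle(pairs), abs=1e-12)
    assert corrected <= plain + 1e-12


def test_corrected_never_exceeds_plain(rng):
    for seed in range(5):
        ref, moved, _ = dk.gen_toy_structures(6, noise_sd=0.5, seed=seed)
        pairs = list(zip(ref.residues, moved.residues))
        plain, corrected, _ = rmsd_symmetric(pairs)
        assert corrected <= plain + 1e-12


# ------------------------------------------------------------- region report


def _toy_regions(n_residues):
    return dk.RegionSet(
        binding_site=[("A", i) for i in range(1, min(n_residues, 6) + 1)],
        ranges={"tail": [("A", max(1, n_residues - 4), n_residues)]},
    )


def test_region_report_identity_is_zero():
    ref, _, _ = dk.gen_toy_structures(12, noise_sd=0.0, seed=9)
    report = dk.region_report(ref, ref, _toy_regions(12))
    for row in report.rows:
        assert row["computable"]
        assert row["ca_rmsd"] == pytest.approx(0.0, abs=1e-6)
        if row["region"] == "binding_site":
            assert row["sidechain_rmsd_plain"] == pytest.approx(0.0, abs=1e-6)


def test_region_report_recovers_generator_noise():
    sigma = 0.3
    ref, moved, _ = dk.gen_toy_structures(
        60, noise_sd=sigma, seed=10, swap_symmetric_labels=False
    )
    regions = dk.RegionSet(ranges={"all": [("A", 1, 60)]})
    report = dk.region_report(moved, ref, regions)
    row = report.rows[0]
    # Cα RMSD of two noisy copies ≈ σ√3·√2 is wrong here: only the moved copy
    # is noisy, so expect ≈ σ√3 within Monte-Carlo tolerance at 60 residues.
    assert row["ca_rmsd"] == pytest.approx(sigma * np.sqrt(3.0), rel=0.2)


def test_region_report_symmetry_corrected_sidechains():
    ref, moved, _ = dk.gen_toy_structures(10, noise_sd=0.0, seed=11)
    regions = dk.RegionSet(binding_site=[("A", i) for i in range(1, 11)])
    report = dk.region_report(moved, ref, regions)
    row = report.rows[0]
    assert row["sidechain_rmsd_plain"] > 0.1  # flipped ring labels
    assert row["sidechain_rmsd_symcorr"] == pytest.approx(0.0, abs=1e-6)
    assert row["sidechain_rmsd_symcorr"] <= row["sidechain_rmsd_plain"]


def test_region_report_discloses_missing_residues():
    ref, moved, _ = dk.gen_toy_structures(12, noise_sd=0.0, seed=12)
    truncated = Structure([r for r in ref.residues if r.seqid != 3])
    regions = _toy_regions(12)
    report = dk.region_report(moved, truncated, regions)
    bs = next(r for r in report.rows if r["region"] == "binding_site")
    assert bs["n_residues_paired"] == bs["n_residues_selected"] - 1
    assert bs["computable"]


def test_region_below_three_pairs_not_computable():
    ref, moved, _ = dk.gen_toy_structures(4, noise_sd=0.0, seed=13)
    regions = dk.RegionSet(ranges={"tiny": [("A", 1, 2)]})
    report = dk.region_report(moved, ref, regions)
    assert report.rows[0]["computable"] is False


def test_whole_fit_mode_runs_and_differs_from_region_fit():
    ref, moved, _ = dk.gen_toy_structures(20, noise_sd=0.4, seed=14,
                                          swap_symmetric_labels=False)
    regions = dk.RegionSet(
        ranges={"head": [("A", 1, 8)], "tail": [("A", 13, 20)]}
    )
    per_region = dk.region_report(moved, ref, regions)
    whole = dk.region_report(moved, ref, regions, whole_fit=True)
    for row_r, row_w in zip(per_region.rows, whole.rows):
        # a per-region fit can never be worse than the shared frame
        assert row_r["ca_rmsd"] <= row_w["ca_rmsd"] + 1e-9


def test_pdb_round_trip(tmp_path):
    ref, _, _ = dk.gen_toy_structures(6, noise_sd=0.0, seed=15)
    path = tmp_path / "toy.pdb"
    write_pdb(ref, path)
    loaded = dk.load_structure(path)
    assert len(loaded.residues) == 6
    orig = ref.residue_map()
    for res in loaded.residues:
        for name, xyz in res.atoms.items():
            np.testing.assert_allclose(xyz, orig[res.key()].atoms[name], atol=1e-3)


def test_rigid_motion_invariance_of_report():
    ref, moved, _ = dk.gen_toy_structures(15, noise_sd=0.2, seed=16,
                                          swap_symmetric_labels=False)
    regions = dk.RegionSet(ranges={"all": [("A", 1, 15)]})
    base = dk.region_report(moved, ref, regions).rows[0]["ca_rmsd"]
    rot = Rotation.from_euler("xyz", [1.0, 0.2, -0.7]).as_matrix()
    shifted = Structure([
        Residue(r.chain, r.seqid, r.name,
                {n: x @ rot.T + np.array([10.0, -5.0, 2.0])
                 for n, x in r.atoms.items()})
        for r in moved.residues
    ])
    again = dk.region_report(shifted, ref, regions).rows[0]["ca_rmsd"]
    assert again == pytest.approx(base, abs=1e-8)
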