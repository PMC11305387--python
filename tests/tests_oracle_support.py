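"""Shared independent oracles used by more than one test module."""

import itertools

import numpy as np

from dockeval.structure import SYMMETRIC_ATOM_SWAPS


def exhaustive_symmetry_oracle(pairs):
    """Global RMSD minimum over every combination of catalog atom swaps.

    Enumerates the full product of per-residue swap masks (≤ 2^k), entirely
    independent of the per-residue minimisation in the implementation.
    """
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
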