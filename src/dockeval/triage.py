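"""Prospective-screen triage: ensemble ranking, filters, leader clustering.

After docking a large library against a small ensemble of receptor models,
the triage cascade mirrors standard practice in large-library docking
campaigns: rank every compound by its best (lowest) score over the ensemble,
take the top slice, remove pan-assay interference (PAINS) substructures and
compounds too similar to known ligands, then cluster the survivors by ECFP4
Tanimoto with rank-ordered leader (sphere-exclusion) clustering so each
chemotype is represented once, by its best-scoring member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import FilterCatalog

from .enrichment import rank_order
from .fingerprints import tanimoto, tanimoto_matrix
from .scorematrix import ScoreMatrix

__all__ = [
    "RankedList",
    "ClusterSet",
    "ensemble_best_score",
    "filter_pains",
    "filter_known_similarity",
    "cluster_select",
    "load_pains_catalog",
]


@dataclass
class RankedList:
    """Library compounds ordered by ensemble best score (1-based ranks)."""

    compound_ids: list[str]          # in rank order, best first
    best_scores: np.ndarray          # aligned with compound_ids
    best_model_ids: list[str]
    dropped_ids: list[str] = field(default_factory=list)  # missing in all models

    def __post_init__(self) -> None:
        self.best_scores = np.asarray(self.best_scores, dtype=float)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.compound_ids) + 1)

    def head(self, n: int) -> "RankedList":
        return RankedList(
            compound_ids=self.compound_ids[:n],
            best_scores=self.best_scores[:n],
            best_model_ids=self.best_model_ids[:n],
            dropped_ids=list(self.dropped_ids),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": self.ranks,
                "compound_id": self.compound_ids,
                "best_score": self.best_scores,
                "best_model": self.best_model_ids,
            }
        )


def ensemble_best_score(matrix: ScoreMatrix) -> RankedList:
    """Rank compounds by their best score over the model ensemble.

    Per compound: the minimum score over non-missing entries (each molecule
    keeps the most favourable docking energy any ensemble member gave it).
    Compounds missing in every model are dropped and logged. Ties break by
    compound id (stable rule).
    """
    if matrix.n_compounds == 0 or matrix.n_models == 0:
        raise ValueError("empty score matrix")
    present = ~matrix.missing
    any_present = present.any(axis=1)
    dropped = [c for c, ok in zip(matrix.compound_ids, any_present) if not ok]

    scores = np.where(present, matrix.scores, np.inf)
    best = scores.min(axis=1)
    best_col = scores.argmin(axis=1)

    keep = np.flatnonzero(any_present)
    ids_kept = [matrix.compound_ids[i] for i in keep]
    order = rank_order(best[keep], ids_kept)
    return RankedList(
        compound_ids=[ids_kept[i] for i in order],
        best_scores=best[keep][order],
        best_model_ids=[matrix.model_ids[best_col[keep[i]]] for i in order],
        dropped_ids=dropped,
    )


# ---------------------------------------------------------------- PAINS


def load_pains_catalog(smarts_path: str | Path | None = None):
    """PAINS substructure catalog.

    Default: RDKit's built-in three-family PAINS catalog (480 patterns). A
    custom SMARTS file (lines of ``SMARTS<TAB>name`` or ``SMARTS name``)
    overrides it, so any catalog dialect can be reproduced exactly.
    Returns a list of (name, query molecule) pairs.
    """
    if smarts_path is None:
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        return ("rdkit", FilterCatalog.FilterCatalog(params))
    entries = []
    with open(smarts_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smarts = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"pattern_{i + 1}"
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"bad SMARTS on line {i + 1}: {smarts!r}")
            entries.append((name, query))
    if not entries:
        raise ValueError(f"empty SMARTS catalog: {smarts_path}")
    return ("smarts", entries)


def _match_pains(catalog, mol) -> str | None:
    kind, entries = catalog
    if kind == "rdkit":
        entry = entries.GetFirstMatch(mol)
        return entry.GetDescription() if entry is not None else None
    for name, query in entries:
        if mol.HasSubstructMatch(query):
            return name
    return None


def filter_pains(
    smiles_by_id: list[tuple[str, str]],
    catalog=None,
) -> tuple[list[str], list[tuple[str, str]], list[tuple[str, str]]]:
    """Split (id, SMILES) pairs on PAINS substructure matches.

    Returns ``(kept_ids, flagged, rejects)`` where ``flagged`` pairs each
    removed id with the name of the first matching pattern and ``rejects``
    holds unparseable inputs with a reason (quarantined, never raised).
    Both lists preserve input order.
    """
    if catalog is None:
        catalog = load_pains_catalog()
    kept: list[str] = []
    flagged: list[tuple[str, str]] = []
    rejects: list[tuple[str, str]] = []
    for cid, smiles in smiles_by_id:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            rejects.append((cid, f"unparseable SMILES: {smiles!r}"))
            continue
        name = _match_pains(catalog, mol)
        if name is None:
            kept.append(cid)
        else:
            flagged.append((cid, name))
    return kept, flagged, rejects


def filter_known_similarity(
    fps_by_id: list[tuple[str, np.ndarray]],
    known_fps: list[np.ndarray],
    tc_max: float = 0.5,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Exclude compounds too similar to known ligands.

    A compound is excluded iff its maximum ECFP4 Tanimoto over the knowns is
    *strictly greater* than ``tc_max``; a compound at exactly the threshold
    is kept. With an empty knowns list everything is kept (a warning is
    logged). Returns (kept ids, [(excluded id, max Tc)]).
    """
    if not known_fps:
        import logging

        logging.getLogger(__name__).warning(
            "no known ligands supplied: similarity filter keeps everything"
        )
        return [cid for cid, _ in fps_by_id], []
    kept: list[str] = []
    excluded: list[tuple[str, float]] = []
    if fps_by_id:
        fps = np.stack([fp for _, fp in fps_by_id])
        max_tc = tanimoto_matrix(fps, np.stack(known_fps)).max(axis=1)
    else:
        max_tc = np.empty(0)
    for (cid, _), tc in zip(fps_by_id, max_tc):
        if tc > tc_max:
            excluded.append((cid, float(tc)))
        else:
            kept.append(cid)
    return kept, excluded


# ---------------------------------------------------------------- clustering


@dataclass
class ClusterSet:
    """Rank-ordered leader clustering result.

    Clusters partition the input; each cluster's leader is its best-ranked
    member and the cluster's rank is the leader's rank.
    """

    leaders: list[str]                    # in cluster-rank order
    members: dict[str, list[str]]         # leader id -> member ids (leader first)

    @property
    def n_clusters(self) -> int:
        return len(self.leaders)

    def to_frame(self):
        import pandas as pd

        rows = []
        for c_rank, leader in enumerate(self.leaders, start=1):
            for member in self.members[leader]:
                rows.append(
                    {"cluster_rank": c_rank, "leader": leader, "member": member}
                )
        return pd.DataFrame(rows)


def leader_cluster(
    ids_in_rank_order: list[str],
    fps: np.ndarray,
    tc_threshold: float = 0.5,
) -> ClusterSet:
    """Leader (sphere-exclusion) clustering in rank order.

    Walking the list best-first, a compound founds a new cluster iff its
    Tanimoto to *every* existing leader is < ``tc_threshold``; otherwise it
    joins the first (best-ranked) leader with Tc ≥ threshold. Leaders are
    therefore pairwise Tc < threshold and every member has Tc ≥ threshold to
    its leader.
    """
    fps = np.asarray(fps, dtype=bool)
    leaders: list[str] = []
    leader_rows: list[int] = []
    members: dict[str, list[str]] = {}
    for i, cid in enumerate(ids_in_rank_order):
        assigned = False
        if leader_rows:
            tcs = tanimoto_matrix(fps[i][None, :], fps[leader_rows])[0]
            hit = np.flatnonzero(tcs >= tc_threshold)
            if hit.size:
                members[leaders[hit[0]]].append(cid)
                assigned = True
        if not assigned:
            leaders.append(cid)
            leader_rows.append(i)
            members[cid] = [cid]
    return ClusterSet(leaders=leaders, members=members)


def cluster_select(
    ranked: RankedList,
    fps_by_id: dict[str, np.ndarray],
    tc_threshold: float = 0.5,
    top_n_input: int = 40000,
    top_n_clusters: int = 2000,
) -> tuple[ClusterSet, list[str]]:
    """Cluster the top of a ranked list and return the top cluster leaders.

    The ``top_n_input`` best-ranked compounds (the full list, with a log
    message, if shorter) are leader-clustered at ``tc_threshold``; the
    leaders of the ``top_n_clusters`` best-ranked clusters are returned as
    the candidate list, one representative per chemotype.
    """
    if not ranked.compound_ids:
        raise ValueError("ranked list is empty")
    if top_n_input > len(ranked.compound_ids):
        import logging

        logging.getLogger(__name__).info(
            "top_n_input %d exceeds list length %d: using full list",
            top_n_input,
            len(ranked.compound_ids),
        )
    head = ranked.head(top_n_input)
    fps = np.stack([fps_by_id[cid] for cid in head.compound_ids])
    clusters = leader_cluster(head.compound_ids, fps, tc_threshold)
    candidates = clusters.leaders[:top_n_clusters]
    return clusters, candidates
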