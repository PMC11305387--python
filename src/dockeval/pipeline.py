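"""The two end-to-end workflows: retrospective evaluation and prospective triage.

``run_retrospective`` scores an actives/decoys matrix per model, summarises
the ensemble, and selects the models for the prospective screen.
``run_prospective`` ranks a library by ensemble best score, runs the filter
cascade (PAINS, known-ligand similarity), clusters the survivors, and emits
the candidate list plus per-stage survivor counts. Every run writes a
manifest (config hash, seed, package version) so identical configs give
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enrichment import evaluate_model_ensemble, select_models
from .scorematrix import ScoreMatrix
from .triage import (
    cluster_select,
    ensemble_best_score,
    filter_known_similarity,
    filter_pains,
    load_pains_catalog,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_retrospective", "run_prospective"]


@dataclass
class PipelineConfig:
    """All paths and thresholds for the two workflows.

    Serialises losslessly to/from YAML; the manifest records the SHA-256 of
    the canonical serialisation.
    """

    scores_csv: str = ""
    library_smi: str = ""
    knowns_smi: str = ""
    diversity_csv: str = ""
    pains_smarts: str = ""
    output_dir: str = "dockeval_out"
    lambda_low: float = 0.001
    fractions: tuple[float, ...] = (0.01,)
    percentile: float = 98.0
    k_models: int = 5
    tc_cluster: float = 0.5
    tc_known: float = 0.5
    tc_exclude: float = 0.35
    ratio: int = 65
    top_n_input: int = 40000
    top_n_clusters: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.lambda_low < 1):
            raise ValueError("lambda_low out of (0, 1)")
        for f in self.fractions:
            if not (0 < f <= 1):
                raise ValueError("fractions out of (0, 1]")
        if not (0 <= self.percentile < 100):
            raise ValueError("percentile out of [0, 100)")
        for name in ("tc_cluster", "tc_known", "tc_exclude"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} out of [0, 1]")
        if self.k_models < 1 or self.ratio < 1:
            raise ValueError("k_models and ratio must be >= 1")
        if self.top_n_input < 1 or self.top_n_clusters < 1:
            raise ValueError("top_n_input and top_n_clusters must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _write_manifest(config: PipelineConfig, out: Path, stage: str, inputs: dict) -> None:
    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "dockeval_version": __version__,
        "inputs": inputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_retrospective(config: PipelineConfig, matrix: ScoreMatrix | None = None) -> dict:
    """Per-model metrics, ensemble percentile summary, and model selection.

    Returns a dict with the EnsembleSummary, the selected model ids, and the
    output paths written. A diversity matrix CSV (square, model × model) is
    optional; without one the selection is top-k by LogAUC.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix = ScoreMatrix.from_csv(config.scores_csv)

    try:
        summary = evaluate_model_ensemble(
            matrix, lambda_low=config.lambda_low, fractions=config.fractions
        )
    except ValueError as exc:
        raise ValueError(f"stage=enrichment: {exc}") from exc

    diversity = None
    if config.diversity_csv:
        import pandas as pd

        df = pd.read_csv(config.diversity_csv, index_col=0)
        df = df.loc[matrix.model_ids, matrix.model_ids]
        diversity = df.to_numpy(dtype=float)
    try:
        selected = select_models(
            summary,
            percentile=config.percentile,
            k=config.k_models,
            diversity_matrix=diversity,
            model_ids=matrix.model_ids,
        )
    except ValueError as exc:
        raise ValueError(f"stage=select_models: {exc}") from exc

    metrics = summary.to_frame()
    metrics.to_csv(out / "model_metrics.csv", index=False)
    report = {
        "median_logauc": summary.median_logauc(),
        "median_ef": {f"{f:g}": summary.median_ef(f) for f in config.fractions},
        "percentile": config.percentile,
        "selected_models": selected,
        "n_models": len(summary.results),
    }
    with open(out / "ensemble_summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_manifest(config, out, "retrospective", {"scores_csv": config.scores_csv})
    return {"summary": summary, "selected_models": selected, "output_dir": str(out)}


def run_prospective(
    config: PipelineConfig,
    matrix: ScoreMatrix | None = None,
    library: list | None = None,
    known_fps: list | None = None,
) -> dict:
    """Rank, filter, cluster; returns candidates and per-stage counts.

    ``library`` is a list of CompoundRecord (fingerprints required, SMILES
    optional — the PAINS stage only applies to records with SMILES, since a
    substructure filter needs a structure); ``known_fps`` is a list of
    fingerprints of known ligands.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix = ScoreMatrix.from_csv(config.scores_csv)
    if library is None:
        raise ValueError("stage=input: a compound library is required")

    by_id = {rec.id: rec for rec in library}

    try:
        ranked = ensemble_best_score(matrix)
    except ValueError as exc:
        raise ValueError(f"stage=ranking: {exc}") from exc
    ranked = ranked.head(min(config.top_n_input, len(ranked.compound_ids)))
    counts = {"ranked": len(ranked.compound_ids)}

    # PAINS filter on compounds that carry structures
    with_smiles = [
        (cid, by_id[cid].smiles)
        for cid in ranked.compound_ids
        if by_id[cid].smiles is not None
    ]
    catalog = load_pains_catalog(config.pains_smarts or None)
    kept_ids, flagged, rejects = filter_pains(with_smiles, catalog)
    pains_removed = {cid for cid, _ in flagged} | {cid for cid, _ in rejects}
    survivors = [c for c in ranked.compound_ids if c not in pains_removed]
    counts["after_pains"] = len(survivors)

    # known-ligand similarity filter
    fps_by_id = [(cid, by_id[cid].fingerprint) for cid in survivors]
    kept2, excluded = filter_known_similarity(
        fps_by_id, known_fps or [], tc_max=config.tc_known
    )
    counts["after_known_similarity"] = len(kept2)

    keep_set = set(kept2)
    keep_rows = [i for i, c in enumerate(ranked.compound_ids) if c in keep_set]
    from .triage import RankedList

    filtered_ranked = RankedList(
        compound_ids=[ranked.compound_ids[i] for i in keep_rows],
        best_scores=ranked.best_scores[keep_rows],
        best_model_ids=[ranked.best_model_ids[i] for i in keep_rows],
        dropped_ids=ranked.dropped_ids,
    )
    if not filtered_ranked.compound_ids:
        clusters, candidates = None, []
        counts["clusters"] = 0
    else:
        clusters, candidates = cluster_select(
            filtered_ranked,
            {cid: by_id[cid].fingerprint for cid in filtered_ranked.compound_ids},
            tc_threshold=config.tc_cluster,
            top_n_input=len(filtered_ranked.compound_ids),
            top_n_clusters=config.top_n_clusters,
        )
        counts["clusters"] = clusters.n_clusters
    counts["candidates"] = len(candidates)

    # artifacts
    ranked.to_frame().to_csv(out / "ranked.csv", index=False)
    if clusters is not None:
        clusters.to_frame().to_csv(out / "clusters.csv", index=False)
    with open(out / "filter_log.tsv", "w") as fh:
        for cid, name in flagged:
            fh.write(f"{cid}\tpains\t{name}\n")
        for cid, reason in rejects:
            fh.write(f"{cid}\treject\t{reason}\n")
        for cid, tc in excluded:
            fh.write(f"{cid}\tknown_similarity\t{tc:.3f}\n")
    with open(out / "candidates.smi", "w") as fh:
        for cid in candidates:
            rec = by_id[cid]
            fh.write(f"{rec.smiles or ''}\t{cid}\n")
    with open(out / "stage_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    _write_manifest(config, out, "prospective", {"scores_csv": config.scores_csv})
    return {
        "candidates": candidates,
        "clusters": clusters,
        "counts": counts,
        "ranked": filtered_ranked,
        "output_dir": str(out),
    }
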