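"""Compound × model docking-score tables.

Convention used throughout the package: **lower score = better** (docking
energies). Missing scores — compounds that failed to dock in a particular
receptor model — are carried in an explicit boolean mask, never as sentinel
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ACTIVE = "active"
DECOY = "decoy"


@dataclass
class ScoreMatrix:
    """Docking scores for a compound set against one or more receptor models.

    Attributes
    ----------
    compound_ids:
        Unique compound identifiers, one per row.
    labels:
        Per-compound label, ``"active"`` or ``"decoy"``. Prospective
        libraries with no benchmark labels use ``"decoy"`` throughout; the
        labels are only consulted by the enrichment metrics.
    scores:
        Float array of shape (n_compounds, n_models); entries under the
        missing mask are undefined and must not be read.
    missing:
        Boolean array, same shape; True where the compound failed to dock.
    model_ids:
        Column identifiers.
    """

    compound_ids: list[str]
    labels: list[str]
    scores: np.ndarray
    missing: np.ndarray
    model_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim == 1:
            self.scores = self.scores[:, None]
        if self.missing is None:
            self.missing = np.zeros_like(self.scores, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not self.model_ids:
            self.model_ids = [f"model_{j + 1}" for j in range(self.scores.shape[1])]
        n, m = self.scores.shape
        if len(self.compound_ids) != n:
            raise ValueError("compound_ids length does not match score rows")
        if len(self.labels) != n:
            raise ValueError("labels length does not match score rows")
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape does not match scores")
        if len(self.model_ids) != m:
            raise ValueError("model_ids length does not match score columns")
        if len(set(self.compound_ids)) != n:
            raise ValueError("compound ids are not unique")
        bad = set(self.labels) - {ACTIVE, DECOY}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def n_compounds(self) -> int:
        return self.scores.shape[0]

    @property
    def n_models(self) -> int:
        return self.scores.shape[1]

    @property
    def is_active(self) -> np.ndarray:
        return np.fromiter((l == ACTIVE for l in self.labels), dtype=bool,
                           count=self.n_compounds)

    def restrict_models(self, model_ids: list[str]) -> "ScoreMatrix":
        """Sub-matrix keeping only the given model columns, in the given order."""
        idx = [self.model_ids.index(m) for m in model_ids]
        return ScoreMatrix(
            compound_ids=list(self.compound_ids),
            labels=list(self.labels),
            scores=self.scores[:, idx].copy(),
            missing=self.missing[:, idx].copy(),
            model_ids=list(model_ids),
        )

    def column(self, model_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(scores, missing) for one model column."""
        j = self.model_ids.index(model_id)
        return self.scores[:, j], self.missing[:, j]

    # ---- CSV dialect: compound_id, label, model_1..model_k; empty = missing

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            np.where(self.missing, np.nan, self.scores),
            columns=self.model_ids,
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "compound_id", self.compound_ids)
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, dtype={"compound_id": str})
        model_ids = [c for c in df.columns if c not in ("compound_id", "label")]
        scores = df[model_ids].to_numpy(dtype=float)
        missing = np.isnan(scores)
        return cls(
            compound_ids=df["compound_id"].tolist(),
            labels=df["label"].tolist(),
            scores=np.nan_to_num(scores),
            missing=missing,
            model_ids=model_ids,
        )
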