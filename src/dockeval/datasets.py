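"""Packaged reference tables.

``load_tested_compounds`` returns the experimentally evaluated candidates of
the two published prospective screens against the trace amine receptor: one
row per tested compound with screen origin ("af" = machine-learning model
ensemble, "hm" = homology-model ensemble), hit call (agonist with efficacy
> 50% of the reference agonist maximum at 20 μM), and pEC50/Emax where the
compound was a confirmed agonist. Per-compound identities of the non-hits
were not published; they appear as anonymous placeholder rows so that the
published totals (30 and 32 tested) are preserved. Reference agonists (the
endogenous agonist β-PEA and the clinical-stage agonist Ulotaront) carry
origin "reference" and are excluded from hit-rate arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .hitstats import TestedCompound

__all__ = ["load_tested_compounds", "tested_compounds_frame", "default_regions_path"]


def tested_compounds_frame() -> pd.DataFrame:
    with resources.files("dockeval.data").joinpath("tested_compounds.csv").open() as fh:
        return pd.read_csv(fh, dtype={"id": str})


def load_tested_compounds(origin: str | None = None) -> list[TestedCompound]:
    """Tested compounds, optionally restricted to one screen origin."""
    df = tested_compounds_frame()
    if origin is not None:
        df = df[df["origin"] == origin]
    out = []
    for _, row in df.iterrows():
        out.append(
            TestedCompound(
                id=row["id"],
                origin=row["origin"],
                is_hit=bool(row["is_hit"]),
                pec50=None if pd.isna(row["pec50"]) else float(row["pec50"]),
                emax_percent=(
                    None if pd.isna(row["emax_percent"]) else float(row["emax_percent"])
                ),
            )
        )
    return out


def default_regions_path() -> str:
    return str(resources.files("dockeval.data").joinpath("binding_site_regions.yaml"))
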