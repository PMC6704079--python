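"""CSV formats and validated readers.

All tables are UTF-8 comma-separated CSV with '.' decimals. Files written
by the pipeline carry provenance as leading ``#``-comment lines (package
version, rng seed, config hash); readers skip them transparently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pathway import PathwaySpec

__all__ = [
    "RAW_MEASUREMENT_COLUMNS",
    "write_table",
    "read_table",
    "read_measurements",
]

RAW_MEASUREMENT_COLUMNS = (
    "strain",
    "replicate",
    "time_min",
    "metabolite",
    "m_index",
    "intensity",
    "istd_area",
    "biomass_gdcw",
)


def write_table(df: pd.DataFrame, path: str | Path, provenance: Mapping[str, object] | None = None) -> None:
    """Write a CSV with optional '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_measurements(path: str | Path, pathway: PathwaySpec | None = None) -> pd.DataFrame:
    """Read and validate a raw measurement table.

    Checks the documented header, non-negative intensities, duplicate
    (sample, metabolite, m_index) keys and per-spectrum completeness of
    the isotopologue ladder; with a pathway, unknown metabolites and
    carbon-count mismatches are rejected with the offending row numbers
    (1-based, data rows).
    """
    df = read_table(path)
    missing = set(RAW_MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    negative = df.index[df["intensity"] < 0].tolist()
    if negative:
        raise ValueError(f"negative intensities at rows {[i + 1 for i in negative]}")
    key_cols = ["strain", "replicate", "time_min", "metabolite", "m_index"]
    dupes = df.index[df.duplicated(key_cols)].tolist()
    if dupes:
        raise ValueError(f"duplicate (sample, metabolite, m_index) keys at rows {[i + 1 for i in dupes]}")
    if pathway is not None:
        known = {p.name for p in pathway.pools} | {m.name for m in pathway.metabolites}
        bad = df.index[~df["metabolite"].isin(known)].tolist()
        if bad:
            names = sorted(df.loc[bad, "metabolite"].unique())
            raise ValueError(f"unknown metabolites {names} at rows {[i + 1 for i in bad]}")
    for key, group in df.groupby(["strain", "replicate", "time_min", "metabolite"]):
        idx = np.sort(group["m_index"].to_numpy())
        n = int(idx.max())
        expected = np.arange(n + 1)
        if not np.array_equal(idx, expected):
            gaps = sorted(int(g) for g in set(expected) - set(idx))
            label = tuple(v.item() if hasattr(v, "item") else v for v in key)
            raise ValueError(
                f"incomplete isotopologue ladder for {label}: missing m_index {gaps}"
            )
    return df
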