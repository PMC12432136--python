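"""Readers and writers for the tidy interchange formats.

All on-disk formats are diffable text: tidy long CSV for tables, JSON for
models, marker sets and manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = (
    "subject_id", "study", "timepoint", "age", "sex", "group",
    "ga_weeks", "region", "measure", "value",
)
OPTIONAL_COLUMNS = ("age_unit", "ses", "piri", "cognition")
VALID_SEX = {"M", "F"}
VALID_GROUP = {"term", "preterm"}
POSITIVE_MEASURES = {"CTh", "SA"}


def read_morphometry(path) -> pd.DataFrame:
    """Read and validate a tidy morphometry table (CSV or TSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    bad_sex = set(df["sex"].dropna().unique()) - VALID_SEX
    if bad_sex:
        raise ValueError(f"invalid sex value(s): {sorted(bad_sex)} (expected M or F)")
    bad_group = set(df["group"].dropna().unique()) - VALID_GROUP
    if bad_group:
        raise ValueError(f"invalid group value(s): {sorted(bad_group)}")

    key = ["subject_id", "timepoint", "region", "measure"]
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = df.loc[dup, key].head(5).to_dict(orient="records")
        raise ValueError(f"duplicate (subject, timepoint, region, measure) rows, e.g. {rows}")

    nonpos = df["measure"].isin(POSITIVE_MEASURES) & ~(df["value"] > 0)
    if nonpos.any():
        idx = list(df.index[nonpos][:10])
        raise ValueError(f"non-positive CTh/SA values at rows {idx}")
    return df


def read_expression(path) -> pd.DataFrame:
    """Gene x region expression matrix; first column is the gene id."""
    return pd.read_csv(path, index_col=0)


def read_marker_sets(path) -> dict:
    with open(path) as fh:
        sets = json.load(fh)
    if not isinstance(sets, dict) or not all(isinstance(v, list) for v in sets.values()):
        raise ValueError("marker sets must be a JSON object {cell_type: [gene ids]}")
    return sets


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
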