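"""Reading and writing subject-level cohort + methylation tables.

Input is a delimited text file (comma or tab, "." decimal point, UTF-8)
with a header row.  A schema mapping can rename arbitrary column headers
onto the canonical variable names; by default headers are taken as
canonical already.  Methylation columns are recognised by locus name;
missing methylation cells stay missing (recorded in the panel mask),
while exposures must be complete.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ALL_LOCI, CohortTable, MethylationPanel


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_schema(path) -> dict:
    """Load a YAML/JSON schema: {columns: {file header: canonical name}}."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def load_cohort(path, schema: dict | None = None,
                loci: list | None = None) -> tuple:
    """Load and validate a cohort file into typed tables.

    Returns ``(CohortTable, MethylationPanel)``.  ``schema`` may carry a
    ``columns`` mapping of file headers to canonical names and an
    optional ``subject_id`` column name (defaults to ``subject_id`` or,
    failing that, the row number).
    """
    path = Path(path)
    schema = schema or {}
    df = pd.read_csv(path, sep=_sep_for(path), decimal=".", encoding="utf-8")
    renames = schema.get("columns", {})
    df = df.rename(columns=renames)
    id_col = schema.get("subject_id", "subject_id")
    if id_col in df.columns:
        df = df.set_index(id_col)
    else:
        df.index = pd.Index([f"S{i+1:04d}" for i in range(len(df))],
                            name="subject_id")
    if "sex" not in df.columns:
        raise ValueError("missing required column 'sex'")
    known_loci = list(loci) if loci is not None else ALL_LOCI
    meth_cols = [c for c in df.columns if c in known_loci]
    if not meth_cols:
        raise ValueError("no methylation columns found in header")
    exposure_cols = [c for c in df.columns
                     if c not in meth_cols and c != "sex"]
    if not exposure_cols:
        raise ValueError("no exposure columns found in header")

    sex = df["sex"].astype(str).str.strip().str.lower()
    sex = sex.replace({"m": "male", "f": "female"})
    bad = sorted(set(sex.unique()) - {"male", "female"})
    if bad:
        raise ValueError(f"unrecognized sex label(s): {bad}")

    exposures = df[exposure_cols].apply(pd.to_numeric, errors="coerce")
    for col in exposure_cols:
        if exposures[col].isna().any():
            row = exposures.index[exposures[col].isna()][0]
            raise ValueError(
                f"non-numeric or missing exposure {col!r} at subject {row!r}")

    cohort = CohortTable(pd.concat([sex.rename("sex"), exposures], axis=1))
    meth = df[meth_cols].apply(pd.to_numeric, errors="coerce")
    panel = MethylationPanel(meth)
    return cohort, panel


def write_cohort(cohort: CohortTable, panel: MethylationPanel, path,
                 float_format: str = "%.6g") -> None:
    """Write the exact dialect :func:`load_cohort` reads (round-trip safe)."""
    path = Path(path)
    joined = pd.concat([cohort.data, panel.values], axis=1)
    joined.to_csv(path, sep=_sep_for(path), index=True,
                  index_label="subject_id", float_format=float_format)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
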