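"""Cohort table I/O with schema validation.

Cohort tables are plain CSV/TSV (delimiter inferred from the extension) with
one row per subject and a documented header: identifiers (``subject_id``,
``site_id``, ``group``), baseline and follow-up SIPS-N items
(``sips_n?_t0`` / ``sips_n?_t1``), the 68 ROI gyrification columns,
``icv`` and the two follow-up Global Functioning scores.  Generator
metadata travels as a JSON sidecar next to the table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ROI_COLUMNS
from .outcomes import SIPS_N_ITEMS

ID_COLUMNS = ("subject_id", "site_id", "group")
ORDINAL_COLUMNS = tuple(
    [f"sips_{i.lower()}_t0" for i in SIPS_N_ITEMS]
    + ["sips_n5_t0"]
    + [f"sips_{i.lower()}_t1" for i in SIPS_N_ITEMS]
)
GF_COLUMNS = ("gf_social_t1", "gf_role_t1")
REQUIRED_COLUMNS = ID_COLUMNS + ORDINAL_COLUMNS + tuple(ROI_COLUMNS) + ("icv",) + GF_COLUMNS


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the documented schema."""


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def validate_cohort(table: pd.DataFrame) -> None:
    """Check the documented schema; raise :class:`CohortSchemaError` with
    row/column coordinates on violation."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    dupes = table["subject_id"][table["subject_id"].duplicated()].tolist()
    if dupes:
        raise CohortSchemaError(f"duplicate subject_id(s): {sorted(set(dupes))}")
    numeric = list(ORDINAL_COLUMNS) + list(ROI_COLUMNS) + ["icv"] + list(GF_COLUMNS)
    for col in numeric:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[values.isna()].tolist()
        if bad:
            raise CohortSchemaError(f"non-numeric or missing entries in {col!r} at rows {bad[:5]}")
    for col in ORDINAL_COLUMNS:
        v = table[col].to_numpy()
        bad = np.flatnonzero((v < 0) | (v > 6))
        if bad.size:
            raise CohortSchemaError(f"{col!r} outside 0..6 at rows {bad[:5].tolist()}")
    for col in GF_COLUMNS:
        v = table[col].to_numpy()
        bad = np.flatnonzero((v < 1) | (v > 10))
        if bad.size:
            raise CohortSchemaError(f"{col!r} outside 1..10 at rows {bad[:5].tolist()}")
    if np.any(table["icv"].to_numpy() <= 0):
        raise CohortSchemaError("icv must be strictly positive")


def read_cohort(path: str | Path, validate: bool = True) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_delimiter(path))
    if validate:
        validate_cohort(table)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a cohort table (CSV/TSV by extension) and an optional JSON
    metadata sidecar (``<stem>.meta.json``).  Floats use shortest-repr
    formatting, so a write/read round trip reproduces values exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_delimiter(path), index=False)
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_metadata(path: str | Path) -> dict:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    return json.loads(sidecar.read_text())
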