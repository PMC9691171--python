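"""Reading and writing the long-format panel interchange file.

The interchange format is delimited text (comma), one row per person-year,
header mandatory, missing values as empty fields.  Required columns:
``person_id``, ``year``, ``weight``, ``q1``, ``q2`` and the covariate
columns; extra columns are preserved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import COVARIATE_COLUMNS

__all__ = ["PanelSchemaError", "REQUIRED_COLUMNS", "read_panel", "write_panel",
           "validate_panel"]

log = logging.getLogger("needsel")

REQUIRED_COLUMNS = ["person_id", "year", "weight", "q1", "q2"] + COVARIATE_COLUMNS


class PanelSchemaError(ValueError):
    pass


def validate_panel(panel: pd.DataFrame) -> list[str]:
    """Hard schema checks (raise) plus soft consistency flags (returned).

    Raises on: missing required columns, duplicated (person_id, year) keys,
    non-positive weights.  Returns human-readable flags for records that are
    merely suspicious, e.g. a reason code present although no unmet need was
    reported (q2 is only meaningful when q1 = 1).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelSchemaError(f"panel file missing required columns: {missing}")
    dup = panel.duplicated(subset=["person_id", "year"], keep=False)
    if dup.any():
        offenders = panel.loc[dup, ["person_id", "year"]].drop_duplicates()
        raise PanelSchemaError(
            "duplicate (person_id, year) rows: "
            + ", ".join(f"({r.person_id}, {r.year})" for r in offenders.itertuples()))
    w = pd.to_numeric(panel["weight"], errors="coerce")
    if (w <= 0).any() or w.isna().any():
        raise PanelSchemaError("weights must be positive and non-missing")
    flags = []
    stray = panel["q2"].notna() & (pd.to_numeric(panel["q1"], errors="coerce") != 1)
    if stray.any():
        flags.append(f"{int(stray.sum())} record(s) carry a q2 reason code "
                     "although q1 != 1; q2 is only meaningful for unmet needs")
    for f in flags:
        log.warning(f)
    return flags


def read_panel(path) -> pd.DataFrame:
    """Read and validate a panel file; returns typed records."""
    panel = pd.read_csv(path)
    validate_panel(panel)
    panel["year"] = panel["year"].astype(int)
    panel["weight"] = panel["weight"].astype(float)
    for c in ("q1", "q2"):
        panel[c] = pd.to_numeric(panel[c], errors="raise").astype(float)
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel file (comma-delimited, empty fields for missing)."""
    validate_panel(panel)
    panel.to_csv(path, index=False)
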