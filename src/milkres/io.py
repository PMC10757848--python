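"""CSV schemas and input validation.

All pipeline tables are plain CSV.  Column dictionaries:

* test-day records — ``animal_id`` (int), ``dim`` (int, ≥1),
  ``yield_kg`` (float), ``test_date`` (ISO date), ``env`` (zone label)
* cow metadata — ``animal_id``, ``birth_date``, ``first_calving_date``,
  ``afc_months``, ``taurine_fraction``, ``breed_group``, ``env``,
  ``exit_date`` (optional), ``exit_code`` (optional), ``n_lactations``
* pedigree — ``animal``, ``sire``, ``dam`` (ints; 0 = unknown parent)
* true values — ``animal_id`` plus one column per simulated trait
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "read_records",
    "read_meta",
    "read_pedigree",
    "write_tables",
    "validate_inputs",
]

RECORD_COLUMNS = ["animal_id", "dim", "yield_kg"]
META_COLUMNS = ["animal_id", "birth_date", "first_calving_date", "afc_months",
                "taurine_fraction", "env"]
PEDIGREE_COLUMNS = ["animal", "sire", "dam"]


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["animal_id"] = df["animal_id"].astype(np.int64)
    df["dim"] = df["dim"].astype(np.int64)
    df["yield_kg"] = df["yield_kg"].astype(float)
    return df


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["birth_date", "first_calving_date"])
    if "exit_date" in df.columns:
        df["exit_date"] = pd.to_datetime(df["exit_date"], errors="coerce")
    df["animal_id"] = df["animal_id"].astype(np.int64)
    return df


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path)
    return Pedigree.from_frame(df)


def write_tables(out_dir, **tables) -> dict[str, str]:
    """Write each keyword table to ``<out_dir>/<name>.csv``; returns the
    mapping name → path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        if df is None:
            continue
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def _check_columns(df: pd.DataFrame, required: list[str], label: str, errors: list[str]):
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{label}: missing columns {missing}")
    return not missing


def validate_inputs(
    records_path=None, meta_path=None, pedigree_path=None
) -> list[str]:
    """Schema-check the input CSVs before any computation.

    Errors are collected (not fail-fast) and returned as a list of
    messages; an empty list means all supplied inputs validate.
    Checks: required columns, numeric parses (naming row and column),
    code domains, pedigree sortability/cycles.
    """
    errors: list[str] = []
    records = meta = None
    if records_path is not None:
        try:
            records = pd.read_csv(records_path)
        except Exception as e:
            errors.append(f"records: unreadable ({e})")
        if records is not None and _check_columns(records, RECORD_COLUMNS, "records", errors):
            for col in ("animal_id", "dim", "yield_kg"):
                bad = pd.to_numeric(records[col], errors="coerce").isna() & records[col].notna()
                for i in records.index[bad][:5]:
                    errors.append(f"records: non-numeric {col!r} at row {i}: {records.loc[i, col]!r}")
            dim = pd.to_numeric(records["dim"], errors="coerce")
            if (dim < 1).any():
                errors.append(f"records: {(dim < 1).sum()} rows with dim < 1")
    if meta_path is not None:
        try:
            meta = pd.read_csv(meta_path)
        except Exception as e:
            errors.append(f"meta: unreadable ({e})")
        if meta is not None and _check_columns(meta, META_COLUMNS, "meta", errors):
            frac = pd.to_numeric(meta["taurine_fraction"], errors="coerce")
            out = (frac < 0) | (frac > 1)
            if out.any():
                errors.append(f"meta: {out.sum()} taurine fractions outside [0,1]")
            for col in ("birth_date", "first_calving_date"):
                bad = pd.to_datetime(meta[col], errors="coerce").isna() & meta[col].notna()
                if bad.any():
                    errors.append(f"meta: unparseable {col} in rows {list(meta.index[bad][:5])}")
    if records is not None and meta is not None and "animal_id" in records and "animal_id" in meta:
        orphans = set(records["animal_id"]) - set(meta["animal_id"])
        if orphans:
            errors.append(f"records: {len(orphans)} animal ids missing from meta, e.g. {sorted(orphans)[:5]}")
    if pedigree_path is not None:
        try:
            ped_df = pd.read_csv(pedigree_path)
        except Exception as e:
            ped_df = None
            errors.append(f"pedigree: unreadable ({e})")
        if ped_df is not None and _check_columns(ped_df, PEDIGREE_COLUMNS, "pedigree", errors):
            try:
                Pedigree.from_frame(ped_df)
            except PedigreeError as e:
                errors.append(f"pedigree: {e}")
    return errors
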