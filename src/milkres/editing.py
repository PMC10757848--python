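"""Data-quality edits and classification for test-day milk records.

Rules applied, in order: yield bounds (0.5–45 kg) → DIM cap (400 d) →
cow-level windows (age at first calving 21–60 months, birth year
1980–2019) → minimum 10 surviving records per cow → year-season
contemporary groups of at least 5 cows.  Cows are classified into breed
groups by taurine fraction and into climatic seasons by the per-zone
month calendar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EditConfig",
    "DEFAULT_SEASON_CALENDAR",
    "SEASONS",
    "apply_record_filters",
    "assign_breed_group",
    "assign_season",
    "build_year_season_groups",
]

SEASONS = ("dry1", "green1", "dry2", "green2")

#: month (1–12) → season, per agroecological zone: semi-arid arable
#: (SAA), semi-arid pasture (SAP) and semi-humid (SH).
DEFAULT_SEASON_CALENDAR: dict[str, dict[int, str]] = {
    "SAA": {1: "dry1", 2: "dry1", 3: "green1", 4: "green1", 5: "dry2", 6: "dry2",
            7: "dry2", 8: "dry2", 9: "dry2", 10: "dry2", 11: "green2", 12: "green2"},
    "SAP": {1: "dry1", 2: "dry1", 3: "green1", 4: "green1", 5: "green1", 6: "green1",
            7: "dry2", 8: "dry2", 9: "dry2", 10: "green2", 11: "green2", 12: "green2"},
    "SH": {12: "dry1", 1: "dry1", 2: "dry1", 3: "dry1", 4: "green1", 5: "green1",
           6: "green1", 7: "dry2", 8: "dry2", 9: "dry2", 10: "green2", 11: "green2"},
}


@dataclass
class EditConfig:
    """Thresholds of the data-quality rules; defaults are the study's."""

    yield_min: float = 0.5
    yield_max: float = 45.0
    dim_max: int = 400
    min_records: int = 10
    afc_min_months: int = 21
    afc_max_months: int = 60
    birth_year_min: int = 1980
    birth_year_max: int = 2019
    min_ys_group: int = 5
    season_calendar: dict = field(default_factory=lambda: DEFAULT_SEASON_CALENDAR)


def assign_breed_group(taurine_fraction: float) -> str:
    """Breed group from taurine (Bos taurus) fraction.

    ≤ 0.5 → BG1 (zebu-dominated crosses); > 0.5–0.875 → BG2;
    > 0.875–1 → BG3 (near-pure taurine).
    """
    f = float(taurine_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"taurine fraction must be in [0,1], got {f}")
    if f <= 0.5:
        return "BG1"
    if f <= 0.875:
        return "BG2"
    return "BG3"


def assign_season(env: str, calendar_month: int, calendar: dict | None = None) -> str:
    """Climatic season of a zone for a calendar month (1–12)."""
    calendar = calendar or DEFAULT_SEASON_CALENDAR
    if env not in calendar:
        raise ValueError(f"unknown environment {env!r}; known: {sorted(calendar)}")
    month = int(calendar_month)
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1–12, got {calendar_month}")
    return calendar[env][month]


def validate_calendar(calendar: dict) -> None:
    """Every month maps to exactly one season; all four seasons occur."""
    for env, months in calendar.items():
        if sorted(months) != list(range(1, 13)):
            raise ValueError(f"{env}: calendar must cover months 1–12 exactly")
        if set(months.values()) != set(SEASONS):
            raise ValueError(f"{env}: all four seasons must occur")


def apply_record_filters(
    records: pd.DataFrame, meta: pd.DataFrame, config: EditConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply the record- and cow-level quality edits.

    Parameters
    ----------
    records
        Test-day records (``animal_id``, ``dim``, ``yield_kg``, …).
    meta
        Cow metadata with ``animal_id``, ``birth_date``,
        ``first_calving_date`` and ``afc_months``.

    Returns
    -------
    (filtered records, filtered meta, edit log) — the edit log counts
    removals per rule in application order; its record counts sum to the
    row difference.

    Raises
    ------
    ValueError
        If records reference animals absent from ``meta``.
    """
    cfg = config or EditConfig()
    orphans = set(records["animal_id"]) - set(meta["animal_id"])
    if orphans:
        raise ValueError(f"records reference unknown animal ids: {sorted(orphans)[:10]}")

    log: dict[str, int] = {}
    rec = records

    ok = (rec["yield_kg"] >= cfg.yield_min) & (rec["yield_kg"] <= cfg.yield_max)
    log["records_yield_bounds"] = int((~ok).sum())
    rec = rec[ok]

    ok = (rec["dim"] >= 1) & (rec["dim"] <= cfg.dim_max)
    log["records_dim_cap"] = int((~ok).sum())
    rec = rec[ok]

    m = meta
    cow_ok = (
        (m["afc_months"] >= cfg.afc_min_months)
        & (m["afc_months"] <= cfg.afc_max_months)
        & (pd.to_datetime(m["birth_date"]).dt.year >= cfg.birth_year_min)
        & (pd.to_datetime(m["birth_date"]).dt.year <= cfg.birth_year_max)
    )
    dropped_cows = set(m.loc[~cow_ok, "animal_id"])
    log["cows_afc_birthyear"] = len(dropped_cows)
    n_before = len(rec)
    rec = rec[~rec["animal_id"].isin(dropped_cows)]
    log["records_of_dropped_cows"] = n_before - len(rec)
    m = m[cow_ok]

    counts = rec.groupby("animal_id").size()
    few = set(counts[counts < cfg.min_records].index) | (
        set(m["animal_id"]) - set(counts.index)
    )
    log["cows_min_records"] = len(few)
    n_before = len(rec)
    rec = rec[~rec["animal_id"].isin(few)]
    log["records_of_min_record_cows"] = n_before - len(rec)
    m = m[~m["animal_id"].isin(few)]

    return rec.reset_index(drop=True), m.reset_index(drop=True), log


def build_year_season_groups(
    meta: pd.DataFrame,
    calendar: dict | None = None,
    min_group_size: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Year-season contemporary groups from the first-calving date.

    The group label is ``<calving year>-<season of calving month>`` in
    the cow's own zone.  Cows in groups with fewer than
    ``min_group_size`` members are flagged ``ys_excluded``.

    Returns (meta with ``ys`` and ``ys_excluded`` columns, group census).
    """
    calendar = calendar or DEFAULT_SEASON_CALENDAR
    m = meta.copy()
    calving = pd.to_datetime(m["first_calving_date"])
    seasons = [
        assign_season(env, month, calendar)
        for env, month in zip(m["env"], calving.dt.month)
    ]
    m["ys"] = [f"{y}-{s}" for y, s in zip(calving.dt.year, seasons)]
    census = m.groupby("ys").size().rename("n").reset_index()
    small = set(census.loc[census["n"] < min_group_size, "ys"])
    m["ys_excluded"] = m["ys"].isin(small)
    return m, census
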