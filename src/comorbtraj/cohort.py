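"""Cohort construction from claims tables.

Incident Alzheimer's disease (AD) cases are persons with at least two AD
claims (ICD-9 331.0 / ICD-10 G30.x) on separate days, the first at age >= 50,
and continuous enrollment covering the five years before that first claim.
Enrollment is "continuous" after coverage spells separated by at most 62 days
are merged.  Eligible controls for a case are AD-free in the case's five-year
window and continuously enrolled over it; the control inherits the case's
index date.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STUDY_START = pd.Timestamp("2000-01-01")
STUDY_END = pd.Timestamp("2016-12-31")
MAX_GAP_DAYS = 62
LOOKBACK_YEARS = 5

#: AD definition: code prefixes per coding system (dot-insensitive).
DEFAULT_AD_CODES: dict[str, tuple[str, ...]] = {"icd9": ("331.0",), "icd10": ("G30",)}


def _norm(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def is_ad_claim(
    codes: pd.Series, systems: pd.Series, ad_codes: Mapping[str, Sequence[str]] | None = None
) -> np.ndarray:
    """Boolean mask of claims matching the AD code set (prefix, dot-insensitive)."""
    ad_codes = ad_codes or DEFAULT_AD_CODES
    norm_codes = codes.map(_norm)
    out = np.zeros(len(codes), dtype=bool)
    for system, prefixes in ad_codes.items():
        sys_mask = systems.str.lower().to_numpy() == system.lower()
        if not sys_mask.any():
            continue
        hit = np.zeros(len(codes), dtype=bool)
        for prefix in prefixes:
            hit |= norm_codes.str.startswith(_norm(prefix)).to_numpy()
        out |= sys_mask & hit
    return out


def merge_enrollment(
    spans: Iterable[tuple[pd.Timestamp, pd.Timestamp]],
    max_gap_days: int = MAX_GAP_DAYS,
    study_start: pd.Timestamp = STUDY_START,
    study_end: pd.Timestamp = STUDY_END,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Merge one person's coverage spells, bridging gaps of <= ``max_gap_days``.

    Spans are inclusive [start, end] dates.  The gap between consecutive spans
    is ``next.start - prev.end - 1`` days, so spans separated by exactly
    ``max_gap_days`` uncovered days still merge.  Overlapping spans are
    unioned.  Output spans are clipped to the study window and sorted.
    """
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    clipped = []
    for start, end in spans:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start > end:
            raise ValueError(f"span start {start} after end {end}")
        start, end = max(start, study_start), min(end, study_end)
        if start <= end:
            clipped.append((start, end))
    if not clipped:
        return []
    clipped.sort()
    merged = [clipped[0]]
    for start, end in clipped[1:]:
        prev_start, prev_end = merged[-1]
        gap = (start - prev_end).days - 1
        if gap <= max_gap_days:
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


def merge_enrollment_by_person(
    spells: pd.DataFrame,
    max_gap_days: int = MAX_GAP_DAYS,
    study_start: pd.Timestamp = STUDY_START,
    study_end: pd.Timestamp = STUDY_END,
) -> pd.DataFrame:
    """Apply :func:`merge_enrollment` per person; returns (person_id, start, end) rows."""
    rows = []
    for pid, grp in spells.groupby("person_id", sort=False):
        for start, end in merge_enrollment(
            zip(grp["spell_start"], grp["spell_end"]), max_gap_days, study_start, study_end
        ):
            rows.append((pid, start, end))
    return pd.DataFrame(rows, columns=["person_id", "start", "end"])


def _covers(merged_spans: pd.DataFrame, lo: pd.Timestamp, hi: pd.Timestamp) -> pd.Index:
    """Person ids with one merged span containing [lo, hi]."""
    mask = (merged_spans["start"] <= lo) & (merged_spans["end"] >= hi)
    return pd.Index(merged_spans.loc[mask, "person_id"].unique())


def identify_cases(
    claims: pd.DataFrame,
    persons: pd.DataFrame,
    spells: pd.DataFrame | None = None,
    merged_spans: pd.DataFrame | None = None,
    ad_codes: Mapping[str, Sequence[str]] | None = None,
    lookback_years: int = LOOKBACK_YEARS,
    max_gap_days: int = MAX_GAP_DAYS,
    min_age: int = 50,
    study_start: pd.Timestamp = STUDY_START,
    study_end: pd.Timestamp = STUDY_END,
) -> pd.DataFrame:
    """Incident AD cases with their index dates.

    A case needs >= 2 AD claims on distinct service dates, age >= ``min_age``
    at the first AD claim (index year minus birth year), and a merged
    enrollment span covering ``[index - lookback_years, index]``.  The index
    date is the first AD claim date.  Persons with AD claims but no birth
    year are excluded with a warning.
    """
    if merged_spans is None:
        if spells is None:
            raise ValueError("provide spells or merged_spans")
        merged_spans = merge_enrollment_by_person(spells, max_gap_days, study_start, study_end)

    ad = claims.loc[is_ad_claim(claims["dx_code"], claims["code_system"], ad_codes)]
    birth_year = persons.set_index("person_id")["birth_year"]
    span_groups = dict(iter(merged_spans.groupby("person_id", sort=False)))

    rows = []
    for pid, grp in ad.groupby("person_id", sort=False):
        dates = pd.DatetimeIndex(grp["service_date"].unique()).sort_values()
        if len(dates) < 2:
            continue
        index_date = dates[0]
        by = birth_year.get(pid)
        if by is None or pd.isna(by):
            logger.warning("person %s has AD claims but no birth year; excluded", pid)
            continue
        if index_date.year - int(by) < min_age:
            continue
        lo = index_date - pd.DateOffset(years=lookback_years)
        spans = span_groups.get(pid)
        if spans is None or not ((spans["start"] <= lo) & (spans["end"] >= index_date)).any():
            continue
        rows.append((pid, index_date))
    cases = pd.DataFrame(rows, columns=["person_id", "index_date"])
    cases["status"] = "case"
    return cases.sort_values(["index_date", "person_id"]).reset_index(drop=True)


def eligible_controls(
    index_date: pd.Timestamp,
    persons: pd.DataFrame,
    claims: pd.DataFrame,
    merged_spans: pd.DataFrame,
    case_ids: Iterable[str],
    ad_codes: Mapping[str, Sequence[str]] | None = None,
    lookback_years: int = LOOKBACK_YEARS,
) -> list:
    """Person ids eligible as controls for a case with the given index date."""
    pools = control_pools(
        pd.DataFrame({"person_id": ["_"], "index_date": [pd.Timestamp(index_date)]}),
        persons, claims, merged_spans, case_ids, ad_codes, lookback_years,
    )
    return pools["_"]


def control_pools(
    cases: pd.DataFrame,
    persons: pd.DataFrame,
    claims: pd.DataFrame,
    merged_spans: pd.DataFrame,
    case_ids: Iterable[str] | None = None,
    ad_codes: Mapping[str, Sequence[str]] | None = None,
    lookback_years: int = LOOKBACK_YEARS,
) -> dict:
    """Eligible-control pool per case: AD-free in the case's window, covered over it.

    Anyone who is ever a case is excluded from every pool (a case cannot serve
    as another case's control, even pre-diagnosis).
    """
    case_ids = set(case_ids if case_ids is not None else cases["person_id"])
    ad = claims.loc[is_ad_claim(claims["dx_code"], claims["code_system"], ad_codes)]
    ad_pid = ad["person_id"].to_numpy()
    ad_date = ad["service_date"].to_numpy()

    pools: dict = {}
    for pid, index_date in zip(cases["person_id"], cases["index_date"]):
        lo = index_date - pd.DateOffset(years=lookback_years)
        covered = _covers(merged_spans, lo, index_date)
        in_window = (ad_date >= np.datetime64(lo)) & (ad_date <= np.datetime64(index_date))
        excluded = set(ad_pid[in_window]) | case_ids | {pid}
        pools[pid] = [p for p in covered if p not in excluded]
    return pools
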