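"""1:1 exact matching of cases to randomly drawn eligible controls.

Each case is matched, without replacement, to a control sharing all six
matching variables: sex, year of birth, insurance plan type, relationship to
plan holder, employment industry, and region.  Cases are processed in a fixed
order (index date, then person id) so the greedy without-replacement draw is
reproducible given the seed; selection within a case's exact-key pool is
uniform.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATCH_COLUMNS = ("sex", "birth_year", "plan_type", "relationship", "industry", "region")


def match_keys(persons: pd.DataFrame) -> dict:
    """person_id -> tuple of the six matching variables (None if any is missing)."""
    keys = {}
    for row in persons.itertuples(index=False):
        values = tuple(getattr(row, c) for c in MATCH_COLUMNS)
        keys[row.person_id] = None if any(pd.isna(v) for v in values) else values
    return keys


def match_controls(
    cases: pd.DataFrame,
    pools: Mapping[str, Sequence],
    persons: pd.DataFrame,
    seed: int,
) -> tuple[pd.DataFrame, list]:
    """Greedy randomized 1:1 exact matching without replacement.

    Returns a pairs table (pair_id, case_id, control_id, index_date) and the
    list of unmatched case ids (exhausted or missing-key pools).
    """
    keys = match_keys(persons)
    ordered = cases.sort_values(["index_date", "person_id"], kind="stable")
    rng = np.random.default_rng(seed)
    used: set = set()
    rows, unmatched = [], []
    for case_id, index_date in zip(ordered["person_id"], ordered["index_date"]):
        case_key = keys.get(case_id)
        if case_key is None:
            logger.warning("case %s has missing matching variables; unmatched", case_id)
            unmatched.append(case_id)
            continue
        candidates = sorted(
            pid for pid in pools.get(case_id, ())
            if pid not in used and keys.get(pid) == case_key
        )
        if not candidates:
            unmatched.append(case_id)
            continue
        control_id = candidates[rng.integers(len(candidates))]
        used.add(control_id)
        rows.append((case_id, control_id, index_date))
    if unmatched:
        logger.warning("%d cases could not be matched and are dropped", len(unmatched))
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "index_date"])
    pairs.insert(0, "pair_id", [f"pair{i:06d}" for i in range(len(pairs))])
    return pairs, unmatched


def matched_members(pairs: pd.DataFrame) -> pd.DataFrame:
    """Long cohort table (person_id, status, pair_id, index_date) from matched pairs."""
    cases = pairs.rename(columns={"case_id": "person_id"})[["person_id", "pair_id", "index_date"]]
    cases["status"] = "case"
    controls = pairs.rename(columns={"control_id": "person_id"})[
        ["person_id", "pair_id", "index_date"]
    ]
    controls["status"] = "control"
    out = pd.concat([cases, controls], ignore_index=True)
    return out[["person_id", "status", "pair_id", "index_date"]]
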