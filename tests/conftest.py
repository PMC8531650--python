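import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from comorbtraj import (
    DEFAULT_ARCHETYPES,
    PrevalencePanel,
    SimConfig,
    control_pools,
    identify_cases,
    match_controls,
    matched_members,
    merge_enrollment_by_person,
    simulate_claims,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: The five default archetypes thinned to 3 comorbidities each, for fast tests.
SMALL_ARCHETYPES = tuple(
    dataclasses.replace(a, n_comorbidities=3) for a in DEFAULT_ARCHETYPES
)


@pytest.fixture(scope="session")
def claims_world():
    """A small but complete synthetic claims world shared across tests."""
    config = SimConfig(n_pairs=150, seed=11, archetypes=SMALL_ARCHETYPES)
    persons, spells, claims, truth = simulate_claims(config)
    return {"config": config, "persons": persons, "spells": spells,
            "claims": claims, "truth": truth}


@pytest.fixture(scope="session")
def matched_world(claims_world):
    """Cohort + matching run on the shared claims world."""
    w = claims_world
    merged = merge_enrollment_by_person(w["spells"])
    cases = identify_cases(w["claims"], w["persons"], merged_spans=merged)
    pools = control_pools(cases, w["persons"], w["claims"], merged)
    pairs, unmatched = match_controls(cases, pools, w["persons"], seed=23)
    return {**w, "merged_spans": merged, "cases": cases, "pools": pools,
            "pairs": pairs, "unmatched": unmatched,
            "members": matched_members(pairs)}


def panel_from_counts(counts: dict, n_per_group: int) -> PrevalencePanel:
    """Panel with given per-group any-interval presence counts (placed at k=1).

    ``counts`` maps category label -> (n_cases_present, n_controls_present).
    """
    n = 2 * n_per_group
    labels = list(counts)
    indicators = np.zeros((n, len(labels), 5), dtype=np.uint8)
    for j, label in enumerate(labels):
        n_case, n_ctrl = counts[label]
        indicators[:n_case, j, 0] = 1
        indicators[n_per_group : n_per_group + n_ctrl, j, 0] = 1
    members = pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "status": ["case"] * n_per_group + ["control"] * n_per_group,
            "pair_id": [f"pair{i % n_per_group}" for i in range(n)],
            "index_date": pd.Timestamp("2010-06-15"),
        }
    )
    return PrevalencePanel(members=members, comorbidities=labels, indicators=indicators)
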