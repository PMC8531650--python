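"""Seeded synthetic claims-world data with planted trajectory archetypes.

The generator emulates the structure an administrative-claims cohort study
relies on: persons with demographics and gappy enrollment spells, incident
AD cases (two 331.0/G30.x claims on separate days at age >= 50 with five
years of continuous pre-index coverage), an eligible AD-free control pool,
and per-comorbidity yearly presence following a logit-linear trajectory law

    logit p = eta + alpha*[case] + beta*(t - t_bar) + gamma*[case]*(t - t_bar)

with t = 6 - k over the five yearly pre-index intervals and t_bar = 3.
Comorbidities are drawn from five archetypes that mirror the kinds of
clusters the downstream multivariate analysis should separate: rapidly
diverging high-prevalence conditions, diverging low-prevalence conditions,
moderately diverging conditions, a null archetype, and an elevated-but-
stable archetype.  The generator returns a ground-truth table so recovery
can be tested.

Yearly outcomes within a person are independent by default; a Gaussian-
copula option induces exchangeable within-person dependence for robustness
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .codes import CATEGORY_DECODES, PrevalencePanel

PROB_EPS = 1e-6


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted comorbidity-trajectory template.

    ``eta``/``alpha``/``beta``/``gamma`` are the logit-scale baseline,
    case-vs-control offset at mean time, shared per-year slope, and
    case-specific extra slope.  Each comorbidity drawn from the archetype
    receives independent Gaussian jitter (sd ``jitter_sd``) on every
    parameter.
    """

    name: str
    eta: float
    alpha: float
    beta: float
    gamma: float
    n_comorbidities: int
    jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_comorbidities < 0:
            raise ValueError("n_comorbidities must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


#: Default archetypes: sizes mirror the five clusters the analysis is meant
#: to separate (18/19/22/65/51 comorbidities).
DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("rapidly-diverging", eta=-1.4, alpha=1.2, beta=0.06, gamma=0.40,
                  n_comorbidities=18),
    ArchetypeSpec("low-prevalence-diverging", eta=-2.6, alpha=0.3, beta=0.04, gamma=0.28,
                  n_comorbidities=19),
    ArchetypeSpec("moderately-diverging", eta=-2.0, alpha=0.8, beta=0.03, gamma=0.16,
                  n_comorbidities=22),
    ArchetypeSpec("null", eta=-1.0, alpha=0.0, beta=-0.02, gamma=0.0,
                  n_comorbidities=65),
    ArchetypeSpec("elevated-stable", eta=-0.6, alpha=0.45, beta=0.02, gamma=0.0,
                  n_comorbidities=51),
)


@dataclass(frozen=True)
class GapModel:
    """Enrollment-gap behaviour for eligible persons (gaps never break eligibility)."""

    probability: float = 0.3
    min_gap_days: int = 1
    max_gap_days: int = 62


def _check_probs(name: str, probs: Mapping[str, float]) -> None:
    total = float(sum(probs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic claims world."""

    n_pairs: int = 1000
    archetypes: tuple[ArchetypeSpec, ...] = DEFAULT_ARCHETYPES
    seed: int = 0
    study_start: pd.Timestamp = pd.Timestamp("2000-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2016-12-31")
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.5912, "M": 0.4088})
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {"North-Central": 0.454, "South": 0.292, "West": 0.144,
                                 "Northeast": 0.108, "Unknown": 0.002})
    plan_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Comprehensive": 0.569, "PPO": 0.325, "HMO": 0.060,
                                 "POS": 0.032, "Other": 0.007, "Missing": 0.007})
    relationship_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Employee": 0.818, "Spouse/Other": 0.182})
    industry_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Manufacturing": 0.427, "Transportation/Utilities": 0.181,
                                 "Services": 0.111, "Other/Missing": 0.281})
    gap_model: GapModel = field(default_factory=GapModel)
    controls_per_case: int = 2
    within_person_corr: float = 0.0     # Gaussian-copula exchangeable dependence
    n_intervals: int = 5

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not 0.0 <= self.within_person_corr < 1.0:
            raise ValueError("within_person_corr must be in [0, 1)")
        for name in ("sex", "region", "plan", "relationship", "industry"):
            _check_probs(name, getattr(self, f"{name}_probs"))


def _category_labels(n: int) -> list[str]:
    """Distinct three-digit numeric categories; 331 (the AD code) is reserved."""
    pool = [f"{i:03d}" for i in range(100, 1000) if i != 331]
    if n > len(pool):
        raise ValueError(f"cannot allocate {n} distinct categories")
    return pool[:n]


def draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-comorbidity jittered parameters and archetype assignment.

    Raises if any implied yearly probability leaves (1e-6, 1 - 1e-6) for
    either group after jitter.
    """
    rows = []
    for arch in config.archetypes:
        base = np.array([arch.eta, arch.alpha, arch.beta, arch.gamma])
        jitter = rng.normal(0.0, arch.jitter_sd, size=(arch.n_comorbidities, 4))
        for params in base + jitter:
            rows.append((arch.name, *params))
    truth = pd.DataFrame(rows, columns=["archetype", "eta", "alpha", "beta", "gamma"])
    truth.insert(0, "comorbidity", _category_labels(len(truth)))

    tc = np.arange(1, config.n_intervals + 1) - (config.n_intervals + 1) / 2.0
    for ad in (0.0, 1.0):
        logit = (truth["eta"].to_numpy()[:, None]
                 + ad * truth["alpha"].to_numpy()[:, None]
                 + np.outer(truth["beta"].to_numpy() + ad * truth["gamma"].to_numpy(), tc))
        p = expit(logit)
        if ((p <= PROB_EPS) | (p >= 1 - PROB_EPS)).any():
            raise ValueError("archetype parameters imply probabilities outside (1e-6, 1-1e-6)")
    return truth


def _trajectory_probs(truth: pd.DataFrame, n_intervals: int) -> dict[float, np.ndarray]:
    """Yearly presence probabilities per group; axis 1 ordered k = 1..n_intervals."""
    k = np.arange(1, n_intervals + 1)
    t = n_intervals + 1 - k                     # t increases toward the index date
    tc = t - t.mean()
    out = {}
    for ad in (0.0, 1.0):
        logit = (truth["eta"].to_numpy()[:, None]
                 + ad * truth["alpha"].to_numpy()[:, None]
                 + np.outer(truth["beta"].to_numpy() + ad * truth["gamma"].to_numpy(), tc))
        out[ad] = expit(logit)
    return out


def _draw_indicators(
    p: np.ndarray, n_persons: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_persons, n_comorb, K) Bernoulli draws; optional exchangeable copula."""
    n_comorb, K = p.shape
    out = np.empty((n_persons, n_comorb, K), dtype=np.uint8)
    for c in range(n_comorb):          # chunked to bound memory
        if rho > 0:
            z = (np.sqrt(rho) * rng.standard_normal((n_persons, 1))
                 + np.sqrt(1 - rho) * rng.standard_normal((n_persons, K)))
            out[:, c, :] = z < norm.ppf(p[c])[None, :]
        else:
            out[:, c, :] = rng.random((n_persons, K)) < p[c][None, :]
    return out


def _random_index_dates(n: int, config: SimConfig, rng: np.random.Generator) -> pd.DatetimeIndex:
    lo = config.study_start + pd.DateOffset(years=5) + pd.Timedelta(days=120)
    hi = config.study_end - pd.Timedelta(days=210)
    offsets = rng.integers(0, (hi - lo).days + 1, size=n)
    return pd.DatetimeIndex([lo + pd.Timedelta(days=int(d)) for d in offsets])


def simulate_panel(config: SimConfig) -> tuple[PrevalencePanel, pd.DataFrame]:
    """Directly generate a matched prevalence panel plus its ground truth.

    This bypasses claims synthesis: yearly presence indicators are drawn
    straight from the trajectory law for ``n_pairs`` cases and ``n_pairs``
    matched controls.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_truth(config, rng)
    probs = _trajectory_probs(truth, config.n_intervals)
    n = config.n_pairs

    index_dates = _random_index_dates(n, config, rng)
    case_ind = _draw_indicators(probs[1.0], n, config.within_person_corr, rng)
    ctrl_ind = _draw_indicators(probs[0.0], n, config.within_person_corr, rng)

    members = pd.DataFrame(
        {
            "person_id": [f"C{i:06d}" for i in range(n)] + [f"N{i:06d}" for i in range(n)],
            "status": ["case"] * n + ["control"] * n,
            "pair_id": [f"pair{i:06d}" for i in range(n)] * 2,
            "index_date": index_dates.append(index_dates),
        }
    )
    panel = PrevalencePanel(
        members=members,
        comorbidities=list(truth["comorbidity"]),
        indicators=np.concatenate([case_ind, ctrl_ind], axis=0),
        decode={c: CATEGORY_DECODES.get(c, "") for c in truth["comorbidity"]},
    )
    return panel, truth


# ---------------------------------------------------------------------------
# claims-world synthesis


def _sample_categorical(
    probs: Mapping[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    keys = list(probs)
    return rng.choice(keys, size=n, p=np.array([probs[k] for k in keys]) / sum(probs.values()))


def _maybe_split_spell(
    start: pd.Timestamp, end: pd.Timestamp, gap: GapModel, rng: np.random.Generator
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Split a spell by one allowed gap (<= 62 days) with the configured probability."""
    span_days = (end - start).days
    if span_days < 120 or rng.random() >= gap.probability:
        return [(start, end)]
    gap_len = int(rng.integers(gap.min_gap_days, gap.max_gap_days + 1))
    cut = int(rng.integers(30, span_days - gap_len - 30))
    first_end = start + pd.Timedelta(days=cut)
    second_start = first_end + pd.Timedelta(days=gap_len + 1)
    return [(start, first_end), (second_start, end)]


def _ad_code(date: pd.Timestamp, flavor: int) -> tuple[str, str]:
    if date >= pd.Timestamp("2015-10-01"):
        return (f"G30.{flavor % 2}", "icd10")
    return ("331.0", "icd9")


def simulate_claims(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (persons, spells, claims, truth) tables.

    Produces ``n_pairs`` constructible AD cases, ``controls_per_case``
    eligible AD-free persons cloning each case's matching key (so exact 1:1
    matching always succeeds), and a handful of distractor persons that the
    cohort rules must reject: a would-be case whose lookback contains a
    70+ day coverage gap, a person with a single AD claim, and an AD-free
    person with under five years of pre-index coverage.  Comorbidity claims
    are placed so the yearly panel rebuilt from them follows the planted
    trajectory law.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_truth(config, rng)
    probs = _trajectory_probs(truth, config.n_intervals)
    n = config.n_pairs
    gap = config.gap_model

    index_dates = _random_index_dates(n, config, rng)
    ages = np.clip(np.round(rng.normal(82, 8, size=n)), 52, 100).astype(int)

    persons_rows, spell_rows, claim_rows = [], [], []

    demo = {
        "sex": _sample_categorical(config.sex_probs, n, rng),
        "region": _sample_categorical(config.region_probs, n, rng),
        "plan_type": _sample_categorical(config.plan_probs, n, rng),
        "relationship": _sample_categorical(config.relationship_probs, n, rng),
        "industry": _sample_categorical(config.industry_probs, n, rng),
    }

    def add_person(pid, sex, birth_year, region, plan, rel, ind):
        persons_rows.append((pid, sex, birth_year, region, plan, rel, ind))

    def add_coverage(pid, start, end, allow_gap=True):
        spells = _maybe_split_spell(start, end, gap, rng) if allow_gap else [(start, end)]
        for s, e in spells:
            spell_rows.append((pid, s, e))

    # cases and their matched-key control candidates
    eligible_ids: list[str] = []
    eligible_is_case: list[bool] = []
    eligible_index: list[pd.Timestamp] = []
    for i in range(n):
        idx = index_dates[i]
        birth_year = idx.year - ages[i]
        case_id = f"C{i:06d}"
        add_person(case_id, demo["sex"][i], birth_year, demo["region"][i],
                   demo["plan_type"][i], demo["relationship"][i], demo["industry"][i])
        cov_start = idx - pd.DateOffset(years=5) - pd.Timedelta(days=int(rng.integers(60, 400)))
        cov_end = idx + pd.Timedelta(days=int(rng.integers(200, 400)))
        add_coverage(case_id, cov_start, cov_end)
        second = idx + pd.Timedelta(days=int(rng.integers(10, 180)))
        for j, date in enumerate((idx, second)):
            code, system = _ad_code(date, i + j)
            claim_rows.append((case_id, date, code, system))
        eligible_ids.append(case_id)
        eligible_is_case.append(True)
        eligible_index.append(idx)

        for c in range(config.controls_per_case):
            ctrl_id = f"N{i:06d}_{c}"
            add_person(ctrl_id, demo["sex"][i], birth_year, demo["region"][i],
                       demo["plan_type"][i], demo["relationship"][i], demo["industry"][i])
            cov_start = idx - pd.DateOffset(years=5) - pd.Timedelta(days=int(rng.integers(60, 400)))
            cov_end = idx + pd.Timedelta(days=int(rng.integers(30, 200)))
            add_coverage(ctrl_id, cov_start, cov_end)
            eligible_ids.append(ctrl_id)
            eligible_is_case.append(False)
            eligible_index.append(idx)

    # distractors the cohort rules must reject
    n_distract = max(3, n // 20)
    for d in range(n_distract):
        idx = index_dates[d % n]
        pid = f"X{d:06d}"
        birth_year = idx.year - int(ages[d % n])
        add_person(pid, demo["sex"][d % n], birth_year, demo["region"][d % n],
                   demo["plan_type"][d % n], demo["relationship"][d % n],
                   demo["industry"][d % n])
        kind = d % 3
        if kind == 0:
            # would-be case: qualifying AD claims but a 70+ day gap in the lookback
            gap_len = int(rng.integers(70, 121))
            break_at = idx - pd.DateOffset(years=2)
            spell_rows.append((pid, idx - pd.DateOffset(years=6), break_at))
            spell_rows.append(
                (pid, break_at + pd.Timedelta(days=gap_len + 1), idx + pd.Timedelta(days=250)))
            second = idx + pd.Timedelta(days=int(rng.integers(10, 180)))
            for j, date in enumerate((idx, second)):
                code, system = _ad_code(date, d + j)
                claim_rows.append((pid, date, code, system))
        elif kind == 1:
            # a single AD claim only
            add_coverage(pid, idx - pd.DateOffset(years=6), idx + pd.Timedelta(days=250),
                         allow_gap=False)
            code, system = _ad_code(idx, d)
            claim_rows.append((pid, idx, code, system))
        else:
            # AD-free, but coverage starts only 4 years before index
            add_coverage(pid, idx - pd.DateOffset(years=4), idx + pd.Timedelta(days=250),
                         allow_gap=False)

    # comorbidity claims for every eligible person, following the trajectory law
    k_low = np.floor(np.arange(config.n_intervals) * 365.25).astype(int) + 1
    k_high = np.floor(np.arange(1, config.n_intervals + 1) * 365.25).astype(int)
    eligible_is_case = np.array(eligible_is_case)
    index_arr = pd.DatetimeIndex(eligible_index)
    for group, p_group in ((True, probs[1.0]), (False, probs[0.0])):
        sel = np.where(eligible_is_case == group)[0]
        if not len(sel):
            continue
        ind = _draw_indicators(p_group, len(sel), config.within_person_corr, rng)
        who, which, kk = np.nonzero(ind)
        offsets = rng.integers(k_low[kk], k_high[kk] + 1)
        dates = index_arr[sel[who]] - pd.to_timedelta(offsets, unit="D")
        cats = truth["comorbidity"].to_numpy()[which]
        for pid_i, cat, date in zip(sel[who], cats, dates):
            claim_rows.append((eligible_ids[pid_i], date, f"{cat}.0", "icd9"))

    persons = pd.DataFrame(
        persons_rows,
        columns=["person_id", "sex", "birth_year", "region", "plan_type",
                 "relationship", "industry"],
    )
    spells = pd.DataFrame(spell_rows, columns=["person_id", "spell_start", "spell_end"])
    claims = pd.DataFrame(
        claim_rows, columns=["person_id", "service_date", "dx_code", "code_system"]
    )
    claims["service_date"] = pd.to_datetime(claims["service_date"])
    return persons, spells, claims, truth
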