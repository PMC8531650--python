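"""Diagnosis-code normalization and yearly prevalence panels.

Claims carry ICD-9-CM or ICD-10-CM diagnosis codes.  For analysis every code
is reduced to an ICD-9 three-digit category (four characters for E-codes,
which would otherwise all collapse onto "E"); ICD-10 codes are first mapped
to ICD-9 through a configurable prefix map.  Presence of a category is then
scored once per yearly interval before each member's index date, and
categories below a pooled five-year occurrence threshold are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: Minimal bundled ICD-10 -> ICD-9 prefix map covering the codes that appear
#: in the synthetic data and the package's own examples.  Real analyses supply
#: a full mapping file via :meth:`CodeMap.from_file`.
DEFAULT_ICD10_TO_ICD9: dict[str, str] = {
    "G30": "331.0",   # Alzheimer's disease
    "I10": "401.9",   # essential hypertension
    "E78": "272.4",   # disorders of lipoid metabolism
    "F32": "311",     # depressive disorder NEC
    "F41": "300.0",   # anxiety states
    "H25": "366.1",   # senile cataract
    "I48": "427.3",   # atrial fibrillation
    "I50": "428.0",   # heart failure
    "J43": "492.8",   # emphysema
    "N18": "585.9",   # chronic kidney disease
}

#: Decode text for three-digit categories named in the cluster descriptions.
CATEGORY_DECODES: dict[str, str] = {
    "290": "senile and presenile organic psychotic conditions",
    "293": "transient mental disorders due to conditions classified elsewhere",
    "294": "persistent mental disorders due to conditions classified elsewhere",
    "296": "episodic mood disorders",
    "298": "other nonorganic psychoses",
    "300": "anxiety, dissociative and somatoform disorders",
    "311": "depressive disorder, not elsewhere classified",
    "272": "disorders of lipoid metabolism",
    "276": "disorders of fluid, electrolyte, and acid-base balance",
    "331": "other cerebral degenerations",
    "348": "other conditions of brain",
    "366": "cataract",
    "401": "essential hypertension",
    "427": "cardiac dysrhythmias",
    "428": "heart failure",
    "486": "pneumonia, organism unspecified",
    "492": "emphysema",
    "585": "chronic kidney disease",
    "715": "osteoarthrosis and allied disorders",
    "719": "other and unspecified disorders of joint",
    "780": "general symptoms",
    "786": "symptoms involving respiratory system and other chest symptoms",
    "V15": "other personal history presenting hazards to health",
    "V57": "care involving use of rehabilitation procedures",
}


def _normalize(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeMap:
    """ICD-10 -> ICD-9 mapping with longest-prefix-match semantics."""

    entries: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ICD10_TO_ICD9))

    def __post_init__(self) -> None:
        normalized = {_normalize(k): str(v).strip() for k, v in self.entries.items()}
        for target in normalized.values():
            if not _is_valid_icd9(target):
                raise ValueError(f"CodeMap target {target!r} is not a valid ICD-9 code")
        object.__setattr__(self, "entries", normalized)

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None) -> "CodeMap":
        """Read a two-column delimited file (icd10, icd9); '#' starts a comment."""
        entries: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split(sep) if sep else line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise ValueError(f"CodeMap line {line!r} does not have two columns")
            entries[parts[0]] = parts[1]
        return cls(entries)

    def lookup(self, icd10_code: str) -> str | None:
        """Longest-prefix match of ``icd10_code`` against the map; None if unmapped."""
        norm = _normalize(icd10_code)
        for length in range(len(norm), 0, -1):
            target = self.entries.get(norm[:length])
            if target is not None:
                return target
        return None


def _is_valid_icd9(code: str) -> bool:
    norm = _normalize(code)
    if not norm:
        return False
    if norm[0] == "E":
        return len(norm) >= 4 and norm[1:4].isdigit()
    if norm[0] == "V":
        return len(norm) >= 3 and norm[1:3].isdigit()
    return len(norm) >= 3 and norm[:3].isdigit()


def icd9_category(code: str) -> str:
    """Three-digit ICD-9 category of ``code`` (four characters for E-codes)."""
    norm = _normalize(code)
    if not _is_valid_icd9(norm):
        raise ValueError(f"{code!r} is not a valid ICD-9 code")
    return norm[:4] if norm[0] == "E" else norm[:3]


def to_icd9_category(code: str, system: str, code_map: CodeMap | None = None) -> str | None:
    """Map a diagnosis code to its ICD-9 three-digit category.

    ICD-9 codes are truncated directly.  ICD-10 codes are first translated via
    ``code_map`` (longest-prefix match) and then truncated; an unmapped ICD-10
    code returns None so the caller can record it and skip the claim.
    """
    if not str(code).strip():
        raise ValueError("empty diagnosis code")
    system = system.lower()
    if system == "icd9":
        return icd9_category(code)
    if system == "icd10":
        code_map = code_map or CodeMap()
        target = code_map.lookup(code)
        return None if target is None else icd9_category(target)
    raise ValueError(f"unknown code system {system!r}")


YEAR_CONVENTION = (
    "interval k in 1..5 covers (index - k*365.25 d, index - (k-1)*365.25 d]; "
    "claims dated on the index date are excluded"
)


@dataclass
class PrevalencePanel:
    """Member x comorbidity x yearly-interval presence indicators.

    ``indicators[m, c, k-1]`` is 1 iff member ``m`` has at least one claim of
    category ``c`` in interval ``k`` (k = 1 is the year immediately before the
    index date).
    """

    members: pd.DataFrame          # person_id, status, pair_id, index_date
    comorbidities: list[str]
    indicators: np.ndarray         # (n_members, n_comorbidities, n_intervals) uint8
    decode: dict[str, str] = field(default_factory=dict)
    year_convention: str = YEAR_CONVENTION
    unmapped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n, c, k = self.indicators.shape
        if n != len(self.members) or c != len(self.comorbidities):
            raise ValueError("indicator array shape does not match members/comorbidities")
        if not np.isin(self.indicators, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        for label in self.comorbidities:
            if not _is_valid_icd9(label) or len(label) not in (3, 4):
                raise ValueError(f"invalid comorbidity category label {label!r}")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_intervals(self) -> int:
        return self.indicators.shape[2]

    @property
    def is_case(self) -> np.ndarray:
        return (self.members["status"].to_numpy() == "case")

    def occurrence(self) -> np.ndarray:
        """(n_members, n_comorbidities) any-interval presence."""
        return self.indicators.any(axis=2)

    def pooled_prevalence(self) -> np.ndarray:
        """Five-year occurrence fraction per comorbidity, cases+controls pooled."""
        return self.occurrence().mean(axis=0)

    def subset(self, labels: Iterable[str]) -> "PrevalencePanel":
        labels = list(labels)
        idx = [self.comorbidities.index(l) for l in labels]
        return replace(
            self,
            comorbidities=labels,
            indicators=self.indicators[:, idx, :],
            decode={l: self.decode.get(l, "") for l in labels},
        )


def build_yearly_panel(
    claims: pd.DataFrame,
    members: pd.DataFrame,
    code_map: CodeMap | None = None,
    n_intervals: int = 5,
) -> PrevalencePanel:
    """Score category presence per member and yearly pre-index interval.

    Interval ``k`` covers ``(index - k*365.25 d, index - (k-1)*365.25 d]``;
    claims on the index date itself are excluded (pre-diagnosis semantics),
    claims outside all intervals are ignored.
    """
    code_map = code_map or CodeMap()
    members = members.reset_index(drop=True)

    merged = claims.merge(members[["person_id", "index_date"]], on="person_id", how="inner")
    merged["service_date"] = pd.to_datetime(merged["service_date"])
    merged["index_date"] = pd.to_datetime(merged["index_date"])
    delta = (merged["index_date"] - merged["service_date"]).dt.days.to_numpy()
    in_window = (delta > 0) & (delta <= n_intervals * DAYS_PER_YEAR)
    merged = merged.loc[in_window].copy()
    k = np.ceil(delta[in_window] / DAYS_PER_YEAR).astype(int)

    # categorize each distinct (code, system) once
    uniq = merged[["dx_code", "code_system"]].drop_duplicates()
    cat_of: dict[tuple[str, str], str | None] = {}
    unmapped_counts: dict[str, int] = {}
    for code, system in uniq.itertuples(index=False):
        cat_of[(code, system)] = to_icd9_category(code, system, code_map)
    cats = np.array(
        [cat_of[(c, s)] or "" for c, s in zip(merged["dx_code"], merged["code_system"])],
        dtype=object,
    )
    skipped = cats == ""
    if skipped.any():
        bad = merged.loc[skipped, "dx_code"].value_counts()
        unmapped_counts = bad.to_dict()
        logger.warning("skipping %d claims with unmapped ICD-10 codes", int(skipped.sum()))
    unmapped = pd.DataFrame(
        {"dx_code": list(unmapped_counts), "n_claims": list(unmapped_counts.values())}
    )

    keep = ~skipped
    cats, k = cats[keep], k[keep]
    pidx = merged.loc[keep, "person_id"].map(
        pd.Series(np.arange(len(members)), index=members["person_id"])
    ).to_numpy()

    comorbidities = sorted(set(cats))
    col = {label: i for i, label in enumerate(comorbidities)}
    indicators = np.zeros((len(members), len(comorbidities), n_intervals), dtype=np.uint8)
    if len(cats):
        cidx = np.array([col[c] for c in cats])
        indicators[pidx, cidx, k - 1] = 1

    decode = {c: CATEGORY_DECODES.get(c, "") for c in comorbidities}
    return PrevalencePanel(
        members=members,
        comorbidities=comorbidities,
        indicators=indicators,
        decode=decode,
        unmapped=unmapped,
    )


def _pct(count: int, n: int, decimals: int = 1) -> float:
    """Percentage rounded half-up, computed exactly from integer counts."""
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(int(count)) * 100 / Decimal(int(n))).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_filter(
    panel: PrevalencePanel, threshold: float = 0.05
) -> tuple[PrevalencePanel, pd.DataFrame]:
    """Drop comorbidities with pooled 5-year occurrence below ``threshold``.

    Returns the filtered panel and a prevalence table (overall / case /
    control percentages, rounded half-up to one decimal, plus the raw
    fractions) sorted by descending overall prevalence.  The ``>=`` boundary
    keeps a comorbidity at exactly the threshold.
    """
    occ = panel.occurrence()
    case = panel.is_case
    n, n_case, n_ctrl = len(case), int(case.sum()), int((~case).sum())
    count_all = occ.sum(axis=0).astype(int)
    count_case = occ[case].sum(axis=0).astype(int)
    count_ctrl = occ[~case].sum(axis=0).astype(int)

    rows = []
    for i, label in enumerate(panel.comorbidities):
        rows.append(
            {
                "category": label,
                "decode": panel.decode.get(label, ""),
                "overall_pct": _pct(count_all[i], n),
                "case_pct": _pct(count_case[i], n_case) if n_case else float("nan"),
                "control_pct": _pct(count_ctrl[i], n_ctrl) if n_ctrl else float("nan"),
                "overall_frac": count_all[i] / n,
                "case_frac": count_case[i] / n_case if n_case else float("nan"),
                "control_frac": count_ctrl[i] / n_ctrl if n_ctrl else float("nan"),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "category", "decode", "overall_pct", "case_pct", "control_pct",
            "overall_frac", "case_frac", "control_frac",
        ],
    )
    kept_mask = table["overall_frac"].to_numpy() >= threshold
    kept = [c for c, keep in zip(panel.comorbidities, kept_mask) if keep]
    table = table.sort_values("overall_frac", ascending=False, kind="stable").reset_index(drop=True)
    return panel.subset(kept), table
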