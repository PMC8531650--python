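"""End-to-end orchestration: simulate -> cohort -> match -> panel -> fit -> cluster.

``run_pipeline`` executes every stage, writes each stage's output as
delimited text plus a JSON manifest with seeds and attrition counts
(persons screened, cases found, cases matched, comorbidities before/after
the prevalence filter, comorbidities converged), and is idempotent given
the seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cluster import cluster_summary
from .codes import CodeMap, build_yearly_panel, prevalence_filter
from .gee import ModelSpec
from .matching import MATCH_COLUMNS, match_controls, matched_members
from .model import TrajectoryGEE
from .simulate import SimConfig, simulate_claims

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and original error."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original

    def record(self) -> dict:
        return {"stage": self.stage, "error": type(self.original).__name__,
                "message": str(self.original)}


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str | Path
    sim: SimConfig | None = None
    input_dir: str | Path | None = None        # persons.tsv / spells.tsv / claims.tsv
    code_map_file: str | Path | None = None
    lookback_years: int = 5
    max_gap_days: int = 62
    match_seed: int = 0
    threshold: float = 0.05
    model: ModelSpec = field(default_factory=ModelSpec)
    k: int = 5
    standardize: bool = True
    signed_logp: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("provide exactly one input mode: sim or input_dir")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _pct2(count: int, n: int) -> float:
    return float((Decimal(int(count)) * 100 / Decimal(int(n)))
                 .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def demographic_table(members: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Overall / case / control summary of the matching variables and age.

    Categorical variables are reported as percentages (half-up, 2 decimals);
    age at index (index year minus birth year) as mean (SD).  With exact
    matching the case and control columns are identical.
    """
    merged = members.merge(persons, on="person_id", how="left")
    groups = {
        "overall": merged,
        "cases": merged[merged["status"] == "case"],
        "controls": merged[merged["status"] == "control"],
    }
    rows = []
    for var in ("sex", "region", "plan_type", "relationship", "industry"):
        for level in sorted(merged[var].dropna().unique()):
            row = {"variable": var, "level": str(level)}
            for gname, g in groups.items():
                row[gname] = _pct2(int((g[var] == level).sum()), len(g)) if len(g) else np.nan
            rows.append(row)
    age_row = {"variable": "age_at_index", "level": "mean (SD)"}
    for gname, g in groups.items():
        age = g["index_date"].dt.year - g["birth_year"]
        age_row[gname] = f"{age.mean():.2f} ({age.std(ddof=1):.2f})" if len(g) else ""
    rows.append(age_row)
    return pd.DataFrame(rows, columns=["variable", "level", "overall", "cases", "controls"])


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write stage outputs under ``config.out_dir``, return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seeds": {"match": config.match_seed}, "counts": {}}
    counts = manifest["counts"]

    def stage(name: str, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            err = StageError(name, exc)
            (out / "error.json").write_text(json.dumps(err.record(), indent=2))
            raise err from exc

    # --- input tables
    if config.sim is not None:
        manifest["seeds"]["simulate"] = config.sim.seed

        def _simulate():
            persons, spells, claims, truth = simulate_claims(config.sim)
            _write(persons, out / "persons.tsv")
            _write(spells, out / "spells.tsv")
            _write(claims, out / "claims.tsv")
            _write(truth, out / "truth.tsv")
            return persons, spells, claims

        persons, spells, claims = stage("simulate", _simulate)
    else:
        def _load():
            d = Path(config.input_dir)
            persons = pd.read_csv(d / "persons.tsv", sep="\t")
            spells = pd.read_csv(d / "spells.tsv", sep="\t",
                                 parse_dates=["spell_start", "spell_end"])
            claims = pd.read_csv(d / "claims.tsv", sep="\t", parse_dates=["service_date"])
            return persons, spells, claims

        persons, spells, claims = stage("load", _load)
    spells = spells.assign(spell_start=pd.to_datetime(spells["spell_start"]),
                           spell_end=pd.to_datetime(spells["spell_end"]))
    claims = claims.assign(service_date=pd.to_datetime(claims["service_date"]))
    counts["persons_screened"] = int(len(persons))

    # --- cohort
    def _cohort():
        merged_spans = cohort_mod.merge_enrollment_by_person(
            spells, config.max_gap_days)
        cases = cohort_mod.identify_cases(
            claims, persons, merged_spans=merged_spans,
            lookback_years=config.lookback_years, max_gap_days=config.max_gap_days)
        pools = cohort_mod.control_pools(
            cases, persons, claims, merged_spans,
            lookback_years=config.lookback_years)
        _write(cases, out / "cases.tsv")
        return cases, pools

    cases, pools = stage("cohort", _cohort)
    counts["cases_found"] = int(len(cases))

    # --- matching
    def _match():
        pairs, unmatched = match_controls(cases, pools, persons, config.match_seed)
        _write(pairs, out / "pairs.tsv")
        return pairs, unmatched

    pairs, unmatched = stage("match", _match)
    counts["cases_matched"] = int(len(pairs))
    counts["cases_unmatched"] = int(len(unmatched))
    counts["members_total"] = int(2 * len(pairs))
    members = matched_members(pairs)

    # --- panel
    def _panel():
        code_map = (CodeMap.from_file(config.code_map_file)
                    if config.code_map_file else CodeMap())
        panel = build_yearly_panel(claims, members, code_map)
        filtered, prevalence = prevalence_filter(panel, config.threshold)
        _write(prevalence, out / "prevalence.tsv")
        return filtered, prevalence

    panel, prevalence = stage("panel", _panel)
    counts["comorbidities_total"] = int(len(prevalence))
    counts["comorbidities_retained"] = int(len(panel.comorbidities))

    _write(demographic_table(members, persons), out / "demographics.tsv")

    if len(panel.comorbidities) == 0:
        counts["comorbidities_converged"] = 0
        empty_cols = {
            "fits": ["comorbidity", "eta", "alpha", "beta", "gamma", "converged"],
            "odds_ratios": ["comorbidity", "or_alpha", "or_gamma"],
            "metrics": ["comorbidity"],
            "labels": ["comorbidity", "cluster"],
            "cluster_summary": ["cluster", "n_comorbidities"],
        }
        for name, cols in empty_cols.items():
            _write(pd.DataFrame(columns=cols), out / f"{name}.tsv")
        manifest["status"] = "ok (no comorbidities retained)"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # --- GEE fits
    def _fit():
        results = TrajectoryGEE(panel, spec=config.model).fit()
        _write(results.frame(), out / "fits.tsv")
        _write(results.odds_ratios(), out / "odds_ratios.tsv")
        return results

    results = stage("fit", _fit)
    counts["comorbidities_converged"] = int(len(results.converged_fits))

    # --- clustering
    def _cluster():
        n_conv = len(results.converged_fits)
        if n_conv < max(2, config.k):
            logger.warning("only %d converged fits; skipping clustering", n_conv)
            for name, cols in (("metrics", ["comorbidity"]),
                               ("labels", ["comorbidity", "cluster"]),
                               ("cluster_summary", ["cluster", "n_comorbidities"])):
                _write(pd.DataFrame(columns=cols), out / f"{name}.tsv")
            return None
        res = results.cluster(
            k=config.k, standardize=config.standardize, signed_logp=config.signed_logp)
        _write(res.metric_matrix.frame(), out / "metrics.tsv")
        _write(res.label_frame(), out / "labels.tsv")
        _write(pd.DataFrame(res.linkage, columns=["child_a", "child_b", "height", "size"]),
               out / "linkage.tsv")
        pcs = pd.DataFrame(res.pc_scores,
                           columns=[f"PC{i+1}" for i in range(res.pc_scores.shape[1])])
        pcs.insert(0, "comorbidity", res.comorbidities)
        _write(pcs, out / "pc_scores.tsv")
        _write(pd.DataFrame({"pc": [f"PC{i+1}" for i in range(len(res.variance_explained))],
                             "variance_fraction": res.variance_explained}),
               out / "pc_variance.tsv")
        _write(cluster_summary(res, results.converged_fits, prevalence),
               out / "cluster_summary.tsv")
        return res

    clustering = stage("cluster", _cluster)
    if clustering is not None:
        manifest["counts"]["clusters"] = int(clustering.k)
        manifest["cluster_sizes"] = {
            str(cid): int((clustering.labels == cid).sum())
            for cid in np.unique(clustering.labels)
        }
        manifest["pc_variance_fractions"] = [float(v) for v in clustering.variance_explained]

    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
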