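"""End-to-end screen: ranking, single-drug and class-level signals, reports.

Orchestrates the full analysis on deduplicated cases: flag event cases
against the PT dictionary, build the primary-suspect drug catalog, apply
the anticoagulant/antiplatelet exclusion, rank the remaining drugs by
event-report count, compute all three disproportionality statistics per
drug and per therapeutic class, and emit the descriptive summaries
(demographics, PT distribution, annual reporting trend).

The contingency universe for every entity is the full deduplicated case
set, so ``a + c`` (total event cases) is identical across entities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dedup import CaseRecord, deduplicate
from .drugs import (
    DrugMention,
    apply_exclusions,
    default_atc_map,
    default_exclusion_list,
    default_synonym_map,
    filter_role,
    resolve_mentions,
)
from .events import PTEntry, ReactionMention, default_pt_dictionary, flag_event_cases, pt_distribution, round_half_away
from .io import assemble_cases, read_package
from .stats import (
    DEFAULT_IC_DRAWS,
    DEFAULT_IC_SEED,
    SignalResult,
    Thresholds,
    build_table,
    compute_signal,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "ScreenOutput",
    "percent",
    "ps_case_sets",
    "rank_top_drugs",
    "screen_single_drugs",
    "screen_groups",
    "demographic_summary",
    "annual_trend",
    "results_to_frame",
    "run_screen",
]

OUTCOME_LABELS = {
    "DE": "Death",
    "HO": "Hospitalization or prolongation of hospitalization",
    "LT": "Life-threatening",
    "DS": "Disability",
    "CA": "Congenital anomaly",
}
OTHER_OUTCOME = "Others or unknown"


@dataclass
class ScreenConfig:
    top_n: int = 30
    pt_dictionary: list[PTEntry] | None = None
    exclusion_list: dict[str, str] | None = None
    atc_map: dict[str, str] | None = None
    synonym_map: dict[str, str] | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_draws: int = DEFAULT_IC_DRAWS
    seed: int = DEFAULT_IC_SEED

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.pt_dictionary is None:
            self.pt_dictionary = default_pt_dictionary()
        if self.exclusion_list is None:
            self.exclusion_list = default_exclusion_list()
        if self.atc_map is None:
            self.atc_map = default_atc_map()
        if self.synonym_map is None:
            self.synonym_map = default_synonym_map()


def percent(x: float, total: float, ndigits: int = 1) -> float:
    """Report percentage, rounded half away from zero."""
    return round_half_away(100.0 * x / total, ndigits)


def ps_case_sets(cases: list[CaseRecord], config: ScreenConfig) -> dict[str, set[str]]:
    """Ingredient -> set of caseids with that ingredient as primary suspect.

    Names are normalised first; a case mentioning the same PS ingredient
    twice counts once.
    """
    mentions: list[DrugMention] = [m for c in cases for m in c.drugs]
    resolved, _ = resolve_mentions(mentions, config.synonym_map, config.atc_map)
    ps = filter_role(resolved, "PS")
    out: dict[str, set[str]] = {}
    for m in ps:
        out.setdefault(m.ingredient, set()).add(m.caseid)
    return out


def event_flags(cases: list[CaseRecord], config: ScreenConfig) -> dict[str, set[PTEntry]]:
    reactions: list[ReactionMention] = [r for c in cases for r in c.reactions]
    return flag_event_cases(reactions, config.pt_dictionary)


def rank_top_drugs(
    event_cases: set[str],
    drug_cases: dict[str, set[str]],
    config: ScreenConfig,
) -> list[str]:
    """Top-N drugs by event-report count ``a``, after exclusions.

    Exclusions are applied before truncation, so an excluded drug can never
    occupy a ranking slot.  Ties break alphabetically.
    """
    entities, excluded = apply_exclusions(sorted(drug_cases), config.exclusion_list)
    if excluded:
        logger.info("excluded from ranking: %s", ", ".join(e for e, _ in excluded))
    ranked = sorted(entities, key=lambda e: (-len(drug_cases[e] & event_cases), e))
    if len(ranked) < config.top_n:
        logger.info("only %d entities available for top_n=%d", len(ranked), config.top_n)
    return ranked[: config.top_n]


def screen_single_drugs(
    ranked: list[str],
    event_cases: set[str],
    drug_cases: dict[str, set[str]],
    universe: set[str],
    config: ScreenConfig,
) -> list[SignalResult]:
    """One SignalResult per ranked drug over the full-case universe.

    Per-entity statistical failures (e.g. a zero margin) are recorded on the
    result's ``error`` field without aborting the batch.
    """
    results = []
    for entity in ranked:
        t = build_table(event_cases, drug_cases[entity], universe)
        try:
            r = compute_signal(entity, t, n_draws=config.n_draws, seed=config.seed,
                               thresholds=config.thresholds)
        except ValueError as exc:
            r = SignalResult(entity=entity, table=t, error=str(exc))
            logger.warning("%s: %s", entity, exc)
        results.append(r)
    return results


def screen_groups(
    class_members: dict[str, list[str]],
    event_cases: set[str],
    drug_cases: dict[str, set[str]],
    universe: set[str],
    config: ScreenConfig,
) -> list[SignalResult]:
    """Class-level signals: member case sets are unioned (a case with two
    member drugs counts once), results ranked by ROR descending."""
    results = []
    for label, members in class_members.items():
        cases: set[str] = set()
        for m in members:
            cases |= drug_cases.get(m, set())
        if not cases:
            logger.info("class %s has no cases; skipped", label)
            continue
        t = build_table(event_cases, cases, universe)
        try:
            r = compute_signal(label, t, n_draws=config.n_draws, seed=config.seed,
                               thresholds=config.thresholds)
        except ValueError as exc:
            r = SignalResult(entity=label, table=t, error=str(exc))
        results.append(r)
    results.sort(key=lambda r: (-(r.ror if r.ror == r.ror else float("-inf")), r.entity))
    return results


def group_members(drug_cases: dict[str, set[str]], config: ScreenConfig) -> dict[str, list[str]]:
    """Therapeutic class -> member ingredients present in the catalog."""
    members: dict[str, list[str]] = {}
    for ingredient in sorted(drug_cases):
        label = config.atc_map.get(ingredient.upper(), "Unknown")
        if label != "Unknown":
            members.setdefault(label, []).append(ingredient)
    return members


def demographic_summary(cases: list[CaseRecord], top_countries: int = 5) -> pd.DataFrame:
    """Stratified count/percent table over sex, age band, country, outcome.

    Country keeps the ``top_countries`` largest reporters and pools the rest
    (with unknowns) into "Others or unknown".  A case can carry several
    outcomes, so outcome counts may sum above the case total; percentages
    are always over the total case count, 1 decimal.
    """
    total = len(cases)
    if total == 0:
        return pd.DataFrame(columns=["dimension", "category", "count", "percent"])
    rows: list[dict] = []

    def _dim(name: str, counts: dict[str, int], order: list[str]) -> None:
        for cat in order:
            rows.append({"dimension": name, "category": cat,
                         "count": counts.get(cat, 0),
                         "percent": percent(counts.get(cat, 0), total)})

    sex_counts: dict[str, int] = {}
    age_counts: dict[str, int] = {}
    country_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    for c in cases:
        sex_counts[c.sex] = sex_counts.get(c.sex, 0) + 1
        age_counts[c.age_band] = age_counts.get(c.age_band, 0) + 1
        country_counts[c.country] = country_counts.get(c.country, 0) + 1
        labels = {OUTCOME_LABELS[o] for o in c.outcomes if o in OUTCOME_LABELS}
        if not labels:
            labels = {OTHER_OUTCOME}
        for lab in labels:
            outcome_counts[lab] = outcome_counts.get(lab, 0) + 1

    _dim("sex", sex_counts, ["Male", "Female", "Unknown"])
    _dim("age_band", age_counts, ["<18", "18-64.9", "65-85", ">85", "Unknown"])
    named = {k: v for k, v in country_counts.items() if k != "Unknown"}
    top = sorted(named, key=lambda k: (-named[k], k))[:top_countries]
    pooled = total - sum(named[k] for k in top)
    country_final = {k: named[k] for k in top}
    country_final[OTHER_OUTCOME] = pooled
    _dim("country", country_final, top + [OTHER_OUTCOME])
    _dim("outcome", outcome_counts,
         list(OUTCOME_LABELS.values()) + [OTHER_OUTCOME])
    return pd.DataFrame(rows)


def annual_trend(cases: list[CaseRecord]) -> pd.DataFrame:
    """Event-case count per FDA-receipt year, gaps zero-filled."""
    years = []
    for c in cases:
        if c.fda_dt and len(str(c.fda_dt)) >= 4 and str(c.fda_dt)[:4].isdigit():
            years.append(int(str(c.fda_dt)[:4]))
    if not years:
        return pd.DataFrame(columns=["year", "count"])
    counts = pd.Series(years).value_counts()
    full = range(min(years), max(years) + 1)
    return pd.DataFrame({"year": list(full),
                         "count": [int(counts.get(y, 0)) for y in full]})


def results_to_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Delimited-report form of a result batch; statistics to 2 decimals."""
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "entity": r.entity, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ROR": round_half_away(r.ror, 2), "ROR_lo": round_half_away(r.ror_lo, 2),
            "ROR_hi": round_half_away(r.ror_hi, 2),
            "PRR": round_half_away(r.prr, 2), "chi2": round_half_away(r.chi2, 2),
            "IC": round_half_away(r.ic, 2), "IC025": round_half_away(r.ic025, 2),
            "IC975": round_half_away(r.ic975, 2),
            "flag_ror": r.flag_ror, "flag_prr": r.flag_prr, "flag_bcpnn": r.flag_bcpnn,
            "positive": r.positive, "corrected": r.corrected,
            "error": r.error or "",
        })
    return pd.DataFrame(rows)


@dataclass
class ScreenOutput:
    cases: list[CaseRecord]
    event_cases: set[str]
    drug_cases: dict[str, set[str]]
    ranked: list[str]
    signals: list[SignalResult]
    group_signals: list[SignalResult]
    demographics: pd.DataFrame
    pt_dist: pd.DataFrame
    trend: pd.DataFrame


def screen_cases(cases: list[CaseRecord], config: ScreenConfig | None = None) -> ScreenOutput:
    """Run the whole screen on already-deduplicated cases."""
    if config is None:
        config = ScreenConfig()
    flags = event_flags(cases, config)
    event_set = set(flags)
    universe = {c.caseid for c in cases}
    drug_cases = ps_case_sets(cases, config)
    ranked = rank_top_drugs(event_set, drug_cases, config)
    signals = screen_single_drugs(ranked, event_set, drug_cases, universe, config)
    groups = screen_groups(group_members(drug_cases, config), event_set, drug_cases,
                           universe, config)
    event_records = [c for c in cases if c.caseid in event_set]
    return ScreenOutput(
        cases=cases,
        event_cases=event_set,
        drug_cases=drug_cases,
        ranked=ranked,
        signals=signals,
        group_signals=groups,
        demographics=demographic_summary(event_records),
        pt_dist=pt_distribution(flags),
        trend=annual_trend(event_records),
    )


def run_screen(
    input_dir: str | Path,
    out_dir: str | Path,
    config: ScreenConfig | None = None,
) -> ScreenOutput:
    """Ingest a directory of quarterly packages, deduplicate, screen, write.

    Outputs under ``out_dir``: signals.csv, groups.csv, demographics.csv,
    pt_distribution.csv, trend.csv and run_metadata.json.  A fixed input
    directory, configuration and seed give byte-identical outputs.
    """
    if config is None:
        config = ScreenConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = read_package(input_dir)
    assembly = assemble_cases(tables)
    cases, dedup_report = deduplicate(assembly.cases)
    result = screen_cases(cases, config)
    results_to_frame(result.signals).to_csv(out / "signals.csv", index=False)
    results_to_frame(result.group_signals).to_csv(out / "groups.csv", index=False)
    result.demographics.to_csv(out / "demographics.csv", index=False)
    result.pt_dist.to_csv(out / "pt_distribution.csv", index=False)
    result.trend.to_csv(out / "trend.csv", index=False)
    meta = {
        "pvsignal_version": __version__,
        "input_dir": str(input_dir),
        "n_reports_in": dedup_report.n_input,
        "n_cases": dedup_report.n_kept,
        "n_event_cases": len(result.event_cases),
        "top_n": config.top_n,
        "thresholds": vars(config.thresholds),
        "ic_n_draws": config.n_draws,
        "ic_seed": config.seed,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return result
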