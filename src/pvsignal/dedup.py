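"""Collapse follow-up reports into one record per case.

A spontaneous-report case (``caseid``) accrues follow-up reports
(``primaryid``) over time; counting each report would inflate every
statistic.  The rule applied here: keep the report with the latest FDA
receipt date (``fda_dt``); if receipt dates tie, keep the larger
``primaryid``; a final pass removes any residual exact ``primaryid``
duplicates, keeping the first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CaseRecord", "DedupReport", "deduplicate"]


@dataclass
class CaseRecord:
    """One safety report; after deduplication, one per case."""

    primaryid: str
    caseid: str
    fda_dt: str | None = None
    sex: str = "Unknown"
    age_band: str = "Unknown"
    country: str = "Unknown"
    event_year: int | None = None
    outcomes: set[str] = field(default_factory=set)
    drugs: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    incomplete: bool = False


@dataclass
class DedupReport:
    n_input: int
    n_kept: int
    n_dropped_followup: int
    n_dropped_exact: int


def _date_key(fda_dt: str | None) -> int:
    """Unparseable or missing dates sort before every valid date."""
    if fda_dt is None:
        return -1
    s = str(fda_dt).strip()
    if len(s) == 8 and s.isdigit():
        return int(s)
    return -1


def _id_key(primaryid: str) -> tuple[int, int | str]:
    """Numeric comparison when the id parses as an integer, else lexicographic."""
    s = str(primaryid).strip()
    if s.isdigit():
        return (1, int(s))
    return (0, s)


def deduplicate(cases: list[CaseRecord]) -> tuple[list[CaseRecord], DedupReport]:
    """Return one record per caseid plus kept/dropped counts.

    Selection per caseid: latest ``fda_dt`` wins; ties broken by the larger
    ``primaryid`` (numeric when both ids are numeric).  Input order of the
    surviving records is preserved, so the operation is idempotent and
    deterministic.
    """
    # second pass first in spirit: an exact primaryid seen before is a
    # residual duplicate regardless of its caseid
    seen_primary: set[str] = set()
    n_exact = 0
    unique: list[CaseRecord] = []
    for rec in cases:
        if rec.primaryid in seen_primary:
            n_exact += 1
            continue
        seen_primary.add(rec.primaryid)
        unique.append(rec)

    best: dict[str, CaseRecord] = {}
    for rec in unique:
        cur = best.get(rec.caseid)
        if cur is None:
            best[rec.caseid] = rec
            continue
        key_new = (_date_key(rec.fda_dt), _id_key(rec.primaryid))
        key_cur = (_date_key(cur.fda_dt), _id_key(cur.primaryid))
        if key_new > key_cur:
            best[rec.caseid] = rec
    kept_ids = {id(rec) for rec in best.values()}
    kept = [rec for rec in unique if id(rec) in kept_ids]
    report = DedupReport(
        n_input=len(cases),
        n_kept=len(kept),
        n_dropped_followup=len(unique) - len(kept),
        n_dropped_exact=n_exact,
    )
    return kept, report
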