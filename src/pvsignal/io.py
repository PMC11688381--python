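"""Reading and writing FAERS-style quarterly ASCII data packages.

A quarterly package is a directory of ``$``-delimited text tables (no
quoting, UTF-8): DEMO (demographics and administration), DRUG (drug rows
with role codes), REAC (MedDRA PT reactions), OUTC (patient outcomes), plus
THER/INDI/RPSR.  Rows are joined on ``primaryid``, the per-report
identifier; ``caseid`` groups follow-up reports of the same case.

Legacy packages (before 2012 Q4) name the identifiers ISR/CASE and the sex
column GNDR_COD; a built-in alias table maps them onto the modern schema so
both eras read identically.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dedup import CaseRecord
from .drugs import DrugMention
from .events import ReactionMention

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_KINDS",
    "read_table",
    "write_table",
    "read_package",
    "assemble_cases",
    "AssemblyResult",
]

DELIMITER = "$"
TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

#: Canonical column order used when writing each table.
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "occr_country", "reporter_country",
    ),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "REAC": ("primaryid", "caseid", "pt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
    "INDI": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "RPSR": ("primaryid", "caseid", "rpsr_cod"),
}

#: Legacy (pre-2012Q4) column names mapped onto the modern schema.
LEGACY_ALIASES = {"isr": "primaryid", "case": "caseid", "gndr_cod": "sex"}

VALID_ROLE_CODES = frozenset({"PS", "SS", "C", "I"})


class SchemaError(ValueError):
    """A mandatory column is missing from a table file."""


class ParseError(ValueError):
    """A data line does not match the header's field count."""


def read_table(path: str | Path, kind: str, *, strict: bool = True) -> pd.DataFrame:
    """Read one ``$``-delimited FAERS table into a string DataFrame.

    Columns are matched by header name (order-independent); legacy ISR/CASE
    headers are renamed via the alias table; unknown columns are kept.
    Empty fields become ``pd.NA``.  Lines whose field count disagrees with
    the header raise :class:`ParseError` when ``strict``, otherwise they are
    skipped with a log message.
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, no header")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    header = [LEGACY_ALIASES.get(h, h) for h in header]
    if "primaryid" not in header:
        raise SchemaError(f"{path}: mandatory column 'primaryid' missing from {kind} header")
    n_fields = len(header)
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split(DELIMITER)
        if len(parts) != n_fields:
            msg = f"{path}:{lineno}: expected {n_fields} fields, found {len(parts)}"
            if strict:
                raise ParseError(msg)
            logger.warning("skipping malformed line — %s", msg)
            continue
        rows.append(parts)
    df = pd.DataFrame(rows, columns=header, dtype="object")
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in header})
    return df.replace("", pd.NA)


def write_table(rows: pd.DataFrame, path: str | Path, kind: str) -> Path:
    """Write a table in the ``$``-delimited dialect (no quoting).

    Known columns come first in canonical order, any extras after; missing
    values are written as empty fields.  Because the dialect has no quoting,
    any field containing the delimiter is rejected.
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    known = [c for c in TABLE_COLUMNS[kind] if c in rows.columns]
    extra = [c for c in rows.columns if c not in known]
    cols = known + extra
    out = rows[cols].astype("object")
    for col in cols:
        bad = out[col].dropna().astype(str).str.contains(DELIMITER, regex=False)
        if bad.any():
            raise ValueError(
                f"{kind}.{col}: field contains the {DELIMITER!r} delimiter; dialect has no quoting"
            )
    out.to_csv(
        path, sep=DELIMITER, index=False, na_rep="",
        quoting=csv.QUOTE_NONE, lineterminator="\n", encoding="utf-8",
    )
    return path


def read_package(directory: str | Path, *, strict: bool = True) -> dict[str, pd.DataFrame]:
    """Read every recognised table file under ``directory`` (recursively).

    Files are matched by kind name appearing in the file stem
    (``DEMO24Q1.txt``, ``demo.txt``...); multiple quarters concatenate.
    """
    directory = Path(directory)
    found: dict[str, list[pd.DataFrame]] = {k: [] for k in TABLE_KINDS}
    for f in sorted(directory.rglob("*.txt")):
        stem = f.stem.upper()
        for kind in TABLE_KINDS:
            if stem.startswith(kind):
                found[kind].append(read_table(f, kind, strict=strict))
                break
    out: dict[str, pd.DataFrame] = {}
    for kind, parts in found.items():
        if parts:
            out[kind] = pd.concat(parts, ignore_index=True)
    if "DEMO" not in out:
        raise SchemaError(f"no DEMO table found under {directory}")
    return out


@dataclass
class AssemblyResult:
    """Joined cases plus a conservation report of unmatched child rows."""

    cases: list[CaseRecord]
    attached: dict[str, int] = field(default_factory=dict)
    unmatched: dict[str, int] = field(default_factory=dict)


def _age_band(age: object, age_cod: object) -> str:
    if pd.isna(age):
        return "Unknown"
    try:
        value = float(age)
    except (TypeError, ValueError):
        return "Unknown"
    unit = (str(age_cod) if not pd.isna(age_cod) else "YR").upper()
    factor = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52, "DY": 1 / 365.25, "HR": 1 / 8766}.get(unit)
    if factor is None:
        return "Unknown"
    years = value * factor
    if years < 18:
        return "<18"
    if years < 65:
        return "18-64.9"
    if years <= 85:
        return "65-85"
    return ">85"


def _sex(value: object) -> str:
    v = "" if pd.isna(value) else str(value).strip().upper()
    return {"M": "Male", "F": "Female"}.get(v, "Unknown")


def _event_year(event_dt: object) -> int | None:
    if pd.isna(event_dt):
        return None
    s = str(event_dt)
    if len(s) >= 4 and s[:4].isdigit():
        return int(s[:4])
    return None


def assemble_cases(tables: dict[str, pd.DataFrame]) -> AssemblyResult:
    """Join the per-kind tables on ``primaryid`` into case records.

    DEMO is mandatory; child rows whose primaryid never appears in DEMO are
    counted as unmatched, never silently dropped (attached + unmatched =
    input rows for every child table).  Cases lacking any drug or reaction
    row are kept and flagged incomplete.
    """
    if "DEMO" not in tables:
        raise SchemaError("DEMO table required to assemble cases")
    demo = tables["DEMO"]
    records: dict[str, CaseRecord] = {}
    for row in demo.itertuples(index=False):
        primaryid = str(row.primaryid)
        country = getattr(row, "occr_country", pd.NA)
        if pd.isna(country):
            country = getattr(row, "reporter_country", pd.NA)
        records[primaryid] = CaseRecord(
            primaryid=primaryid,
            caseid=str(row.caseid) if not pd.isna(row.caseid) else primaryid,
            fda_dt=None if pd.isna(row.fda_dt) else str(row.fda_dt),
            sex=_sex(getattr(row, "sex", pd.NA)),
            age_band=_age_band(getattr(row, "age", pd.NA), getattr(row, "age_cod", pd.NA)),
            country="Unknown" if pd.isna(country) else str(country),
            event_year=_event_year(getattr(row, "event_dt", pd.NA)),
        )
    result = AssemblyResult(cases=[], attached={"DEMO": len(records)}, unmatched={})

    def _attach(kind: str, fn) -> None:
        if kind not in tables:
            return
        attached = unmatched = 0
        for row in tables[kind].itertuples(index=False):
            rec = records.get(str(row.primaryid))
            if rec is None:
                unmatched += 1
                continue
            fn(rec, row)
            attached += 1
        result.attached[kind] = attached
        result.unmatched[kind] = unmatched
        if unmatched:
            logger.info("%s: %d rows with unknown primaryid left unmatched", kind, unmatched)

    def _add_drug(rec: CaseRecord, row) -> None:
        rec.drugs.append(
            DrugMention(
                caseid=rec.caseid,
                drug_seq="" if pd.isna(getattr(row, "drug_seq", pd.NA)) else str(row.drug_seq),
                role_cod=str(row.role_cod) if not pd.isna(getattr(row, "role_cod", pd.NA)) else "",
                verbatim_name=str(row.drugname) if not pd.isna(getattr(row, "drugname", pd.NA)) else "",
            )
        )

    def _add_reac(rec: CaseRecord, row) -> None:
        rec.reactions.append(ReactionMention(caseid=rec.caseid, pt=str(row.pt) if not pd.isna(row.pt) else ""))

    def _add_outc(rec: CaseRecord, row) -> None:
        if not pd.isna(row.outc_cod):
            rec.outcomes.add(str(row.outc_cod))

    _attach("DRUG", _add_drug)
    _attach("REAC", _add_reac)
    _attach("OUTC", _add_outc)

    for rec in records.values():
        rec.incomplete = not rec.drugs or not rec.reactions
    result.cases = list(records.values())
    return result
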