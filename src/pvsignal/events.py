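"""The coagulopathy event definition as a set of MedDRA preferred terms.

The event under surveillance is the MedDRA high-level term "coagulopathies":
26 preferred terms (PTs) covering consumptive, inhibitory and hyper- or
hypo-coagulable disorders, from disseminated intravascular coagulation to
single-factor inhibition.  The packaged dictionary ships these 26 PTs with
their MedDRA codes; any two-column name/code file can replace it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PTEntry",
    "ReactionMention",
    "default_pt_dictionary",
    "load_pt_dictionary",
    "flag_event_cases",
    "pt_distribution",
]


@dataclass(frozen=True)
class PTEntry:
    pt_name: str
    pt_code: int


@dataclass(frozen=True)
class ReactionMention:
    """One MedDRA PT attached to a case."""

    caseid: str
    pt: str


_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    return _WS.sub(" ", name.strip()).casefold()


def _check_unique(entries: list[PTEntry]) -> list[PTEntry]:
    codes = [e.pt_code for e in entries]
    if len(set(codes)) != len(codes):
        raise ValueError("PT dictionary contains duplicate codes")
    return entries


def load_pt_dictionary(path: str | Path) -> list[PTEntry]:
    """Load a user dictionary from a two-column delimited file (name, code)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    name_col, code_col = cols.get("pt_name", df.columns[0]), cols.get("pt_code", df.columns[1])
    return _check_unique(
        [PTEntry(str(r[name_col]), int(r[code_col])) for _, r in df.iterrows()]
    )


def default_pt_dictionary() -> list[PTEntry]:
    """The packaged 26-PT coagulopathies dictionary."""
    with resources.as_file(resources.files("pvsignal.data") / "pt_dictionary.tsv") as p:
        return load_pt_dictionary(p)


def default_pt_weights() -> dict[str, float]:
    """Report-frequency weights of the packaged PTs (used by the simulator)."""
    with resources.as_file(resources.files("pvsignal.data") / "pt_dictionary.tsv") as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["pt_name"], df["weight"].astype(float)))


def flag_event_cases(
    reactions: list[ReactionMention],
    dictionary: list[PTEntry] | None = None,
) -> dict[str, set[PTEntry]]:
    """Map caseid -> set of dictionary PTs its reactions matched.

    Matching is case-insensitive after whitespace normalisation, with a
    fallback on the numeric PT code (so a reaction reported as the bare code
    still matches across MedDRA capitalisation drift).  A case appears in
    the result iff at least one reaction matched; a case may match several
    PTs.
    """
    if dictionary is None:
        dictionary = default_pt_dictionary()
    by_name = {_norm(e.pt_name): e for e in dictionary}
    by_code = {str(e.pt_code): e for e in dictionary}
    flags: dict[str, set[PTEntry]] = {}
    for r in reactions:
        pt = r.pt.strip()
        entry = by_name.get(_norm(pt)) or by_code.get(pt)
        if entry is not None:
            flags.setdefault(r.caseid, set()).add(entry)
    return flags


def pt_distribution(flags: dict[str, set[PTEntry]]) -> pd.DataFrame:
    """Per-PT match counts and percentages, sorted by count descending.

    The counting unit is the (case, matched PT) pair: a case matching k PTs
    contributes to k rows, and percentages are taken over the total number
    of pairs, so they sum to 100 up to rounding.
    """
    counts: dict[PTEntry, int] = {}
    for matched in flags.values():
        for entry in matched:
            counts[entry] = counts.get(entry, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["pt_name", "pt_code", "count", "percent"])
    total = sum(counts.values())
    rows = [
        {
            "pt_name": e.pt_name,
            "pt_code": e.pt_code,
            "count": n,
            "percent": round_half_away(100.0 * n / total, 2),
        }
        for e, n in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["count", "pt_name"], ascending=[False, True], ignore_index=True
    )
    return df


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (report convention; Python rounds half-even)."""
    import math

    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
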