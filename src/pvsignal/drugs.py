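"""Drug-name normalisation, role filtering, exclusions and ATC grouping.

FAERS drug rows carry free-text verbatim names (brand names, salt forms,
dosage suffixes, spelling variants).  The analysis unit is the canonical
ingredient: names are cleaned deterministically, mapped through a synonym
table, and combination products stay single entities.  Only primary-suspect
(PS) mentions enter the screen, and drugs whose purpose is anticoagulation
or platelet inhibition are excluded from ranking — their coagulopathy
reports reflect the indication, not an unexpected signal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DrugMention",
    "normalize_name",
    "filter_role",
    "apply_exclusions",
    "assign_group",
    "default_synonym_map",
    "default_exclusion_list",
    "default_atc_map",
]

UNRESOLVED = None

#: Dosage/form tokens stripped from the end of a cleaned name, longest first.
DEFAULT_SUFFIX_TOKENS = (
    "TABLETS", "TABLET", "CAPSULES", "CAPSULE", "INJECTION", "SOLUTION",
    "SUSPENSION", "CREAM", "OINTMENT", "GEL", "PATCH", "SPRAY", "SYRUP",
    "VIAL", "AMPOULE", "ORAL", "IV", "HCL", "HYDROCHLORIDE", "SODIUM",
    "POTASSIUM", "SULFATE", "SULPHATE", "ACETATE", "TARTRATE", "MESYLATE",
    "MALEATE", "CITRATE", "PHOSPHATE", "BESYLATE", "FUMARATE",
)

#: Names too ambiguous to resolve to an ingredient.
DEFAULT_BLOCKLIST = frozenset(
    {"UNKNOWN", "UNKNOWN DRUG", "DRUG", "MULTIPLE DRUGS", "UNSPECIFIED",
     "INVESTIGATIONAL PRODUCT", "OTC PRODUCT", "ALL OTHER THERAPEUTIC PRODUCTS"}
)

_WS = re.compile(r"\s+")
_DOSE = re.compile(r"^\d+(\.\d+)?(MG|G|MCG|UG|ML|IU|%)(/\w+)?$")


@dataclass
class DrugMention:
    """One drug row attached to a case."""

    caseid: str
    drug_seq: str
    role_cod: str
    verbatim_name: str
    ingredient: str | None = None
    atc_class: str = "Unknown"
    unmapped: bool = False


def _read_two_cols(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0].str.upper(), df.iloc[:, 1]))


def default_synonym_map() -> dict[str, str]:
    with resources.as_file(resources.files("pvsignal.data") / "synonyms.tsv") as p:
        return _read_two_cols(p)


def default_exclusion_list() -> dict[str, str]:
    """Ingredient -> category for the packaged anticoagulant/antiplatelet list."""
    with resources.as_file(resources.files("pvsignal.data") / "exclusions.tsv") as p:
        return _read_two_cols(p)


def default_atc_map() -> dict[str, str]:
    with resources.as_file(resources.files("pvsignal.data") / "atc_classes.tsv") as p:
        return _read_two_cols(p)


def _clean(verbatim: str, suffix_tokens: tuple[str, ...]) -> str:
    name = _WS.sub(" ", verbatim.strip().upper())
    tokens = name.split(" ")
    # strip trailing dose amounts and form/salt tokens, e.g. "... 1G VIAL"
    while len(tokens) > 1 and (tokens[-1] in suffix_tokens or _DOSE.match(tokens[-1])):
        tokens.pop()
    return " ".join(tokens)


def normalize_name(
    verbatim: str,
    synonym_map: dict[str, str] | None = None,
    *,
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST,
    suffix_tokens: tuple[str, ...] = DEFAULT_SUFFIX_TOKENS,
) -> tuple[str | None, bool]:
    """Resolve a verbatim drug name to a canonical ingredient.

    Deterministic pipeline: uppercase, trim, collapse whitespace, strip
    trailing dose/form tokens, then exact synonym lookup.  Returns
    ``(ingredient, unmapped)``; names absent from the synonym table pass
    through in cleaned form with ``unmapped=True``, blocklisted names return
    ``(None, True)``.  Idempotent: normalising an output is a no-op.
    """
    if synonym_map is None:
        synonym_map = default_synonym_map()
    cleaned = _clean(verbatim, suffix_tokens)
    if not cleaned or cleaned in blocklist:
        return UNRESOLVED, True
    mapped = synonym_map.get(cleaned)
    if mapped is not None:
        return mapped.upper(), False
    return cleaned, True


def resolve_mentions(
    mentions: list[DrugMention],
    synonym_map: dict[str, str] | None = None,
    atc_map: dict[str, str] | None = None,
) -> tuple[list[DrugMention], int]:
    """Fill ``ingredient`` and ``atc_class`` in place; drop unresolvable names.

    Returns the surviving mentions and the count dropped (conservation:
    kept + dropped = input).
    """
    if synonym_map is None:
        synonym_map = default_synonym_map()
    if atc_map is None:
        atc_map = default_atc_map()
    kept: list[DrugMention] = []
    dropped = 0
    for m in mentions:
        ingredient, unmapped = normalize_name(m.verbatim_name, synonym_map)
        if ingredient is UNRESOLVED:
            dropped += 1
            continue
        m.ingredient = ingredient
        m.unmapped = unmapped
        m.atc_class = assign_group(ingredient, atc_map)
        kept.append(m)
    if dropped:
        logger.info("dropped %d drug mentions with unresolvable names", dropped)
    return kept, dropped


def filter_role(mentions: list[DrugMention], role: str) -> list[DrugMention]:
    """Keep only mentions with the requested role code (PS/SS/C/I)."""
    out = [m for m in mentions if m.role_cod == role]
    logger.debug("filter_role(%s): kept %d of %d mentions", role, len(out), len(mentions))
    return out


def apply_exclusions(
    entities: list[str],
    exclusion_list: dict[str, str] | list[str] | None = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Remove excluded ingredients, preserving order.

    Returns ``(kept, excluded)`` where each excluded item is
    ``(ingredient, reason)``.  Must run before top-N ranking so an excluded
    high-count drug cannot occupy a ranking slot.
    """
    if exclusion_list is None:
        exclusion_list = default_exclusion_list()
    if not isinstance(exclusion_list, dict):
        exclusion_list = {e.upper(): "excluded by configuration" for e in exclusion_list}
    else:
        exclusion_list = {k.upper(): v for k, v in exclusion_list.items()}
    kept, excluded = [], []
    for e in entities:
        reason = exclusion_list.get(e.upper())
        if reason is None:
            kept.append(e)
        else:
            excluded.append((e, reason))
    return kept, excluded


def assign_group(ingredient: str, atc_map: dict[str, str] | None = None) -> str:
    """Therapeutic class label for an ingredient, or "Unknown"."""
    if atc_map is None:
        atc_map = default_atc_map()
    return atc_map.get(ingredient.upper(), "Unknown")
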