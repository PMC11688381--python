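"""Synthetic spontaneous-reporting-system generator with known ground truth.

Emits FAERS-format quarterly packages in which every drug-event association
is planted: each drug in the catalog carries a marginal probability of being
the primary-suspect (PS) drug of a case and a relative risk RR against the
baseline coagulopathy reporting probability p0, so the per-case event
probability given PS drug ``i`` is ``min(1, p0 * RR_i)``.  Residual PS
probability mass goes to a pool of null background drugs (RR = 1).  Cases
additionally carry 0-2 concomitant/secondary-suspect drug mentions, one or
more reaction PTs, demographics and an outcome code, and a configurable
fraction of cases is emitted twice under one caseid to exercise
deduplication.  A ground-truth manifest (per-drug RR, per-case PS drug and
event status) is produced alongside, so every downstream stage can be
checked against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .events import default_pt_weights

__all__ = ["DrugSpec", "SyntheticConfig", "SimulatedData", "simulate", "generate_database",
           "expected_contingency"]


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: PS-use probability and planted relative risk."""

    name: str
    use_prob: float
    rr: float
    atc_class: str = "Unknown"


#: Demographic category probabilities, loosely shaped like a large real
#: coagulopathy report series (slight female excess, death the most common
#: serious outcome, the US the largest reporter).
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"M": 0.441, "F": 0.462, "": 0.097},
    "age_band": {"<18": 0.091, "18-64.9": 0.408, "65-85": 0.257, ">85": 0.024, "Unknown": 0.220},
    "country": {
        "US": 0.369, "JP": 0.180, "FR": 0.046, "DE": 0.030, "ES": 0.028,
        "GB": 0.100, "IT": 0.100, "CN": 0.097, "": 0.050,
    },
    "outcome": {"DE": 0.325, "HO": 0.309, "LT": 0.112, "DS": 0.004, "CA": 0.001, "OT": 0.249},
}

_AGE_RANGES = {"<18": (1, 17), "18-64.9": (18, 64), "65-85": (65, 85), ">85": (86, 99)}


@dataclass
class SyntheticConfig:
    n_cases: int
    quarters: list[str] = field(default_factory=lambda: ["2020Q1", "2020Q2", "2020Q3", "2020Q4"])
    drug_catalog: list[DrugSpec] = field(default_factory=list)
    baseline_event_prob: float = 0.01
    pt_weights: dict[str, float] | None = None
    n_noise_pts: int = 50
    duplicate_fraction: float = 0.0
    demographic_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    n_background_drugs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not self.quarters:
            raise ValueError("at least one quarter label required")
        for q in self.quarters:
            if len(q) != 6 or not q[:4].isdigit() or q[4] != "Q" or q[5] not in "1234":
                raise ValueError(f"quarter label {q!r} is not YYYYQn")
        p0 = self.baseline_event_prob
        if not 0.0 < p0 < 1.0:
            raise ValueError("baseline_event_prob must be in (0, 1)")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        total = 0.0
        for d in self.drug_catalog:
            if not 0.0 <= d.use_prob <= 1.0:
                raise ValueError(f"use_prob for {d.name} outside [0, 1]")
            if d.rr < 0:
                raise ValueError(f"relative risk for {d.name} must be >= 0")
            total += d.use_prob
        if total > 1.0 + 1e-9:
            raise ValueError("drug use probabilities must sum to <= 1")
        if self.n_background_drugs < 1 and total < 1.0 - 1e-9:
            raise ValueError("background drugs needed to absorb residual PS probability")
        if self.n_noise_pts < 1:
            raise ValueError("n_noise_pts must be >= 1")
        if self.pt_weights is None:
            self.pt_weights = default_pt_weights()
        for dim, dist in self.demographic_distributions.items():
            s = sum(dist.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"demographic distribution {dim!r} sums to {s}, not 1")


@dataclass
class SimulatedData:
    """In-memory result of one simulation: tables plus the truth manifest."""

    tables: dict[str, pd.DataFrame]
    manifest_cases: pd.DataFrame
    manifest_drugs: pd.DataFrame
    quarter_of_case: pd.Series  # caseid -> quarter label (base cases)


def _full_catalog(config: SyntheticConfig) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    names = [d.name for d in config.drug_catalog]
    probs = [d.use_prob for d in config.drug_catalog]
    rrs = [d.rr for d in config.drug_catalog]
    classes = [d.atc_class for d in config.drug_catalog]
    residual = 1.0 - sum(probs)
    if residual > 1e-12:
        k = config.n_background_drugs
        for i in range(k):
            names.append(f"BACKGROUND DRUG {i + 1:02d}")
            probs.append(residual / k)
            rrs.append(1.0)
            classes.append("Unknown")
    p = np.asarray(probs, dtype=float)
    return names, p / p.sum(), np.asarray(rrs, dtype=float), classes


def _sample_cat(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    keys = list(dist.keys())
    p = np.asarray(list(dist.values()), dtype=float)
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p / p.sum())]


def _quarter_dates(rng: np.random.Generator, quarters: list[str], idx: np.ndarray) -> np.ndarray:
    years = np.array([int(q[:4]) for q in quarters])[idx]
    months = np.array([(int(q[5]) - 1) * 3 + 1 for q in quarters])[idx] + rng.integers(0, 3, idx.size)
    days = rng.integers(1, 29, idx.size)
    return np.array([f"{y:04d}{m:02d}{d:02d}" for y, m, d in zip(years, months, days)], dtype=object)


def simulate(config: SyntheticConfig) -> SimulatedData:
    """Draw one synthetic database in memory (deterministic in config.seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    names, probs, rrs, _classes = _full_catalog(config)
    name_arr = np.array(names, dtype=object)

    ps_idx = rng.choice(len(names), size=n, p=probs)
    event_p = np.minimum(1.0, config.baseline_event_prob * rrs[ps_idx])
    is_event = rng.random(n) < event_p

    primaryid = np.array([str(100_000_001 + i) for i in range(n)], dtype=object)
    caseid = np.array([str(50_000_001 + i) for i in range(n)], dtype=object)
    q_idx = rng.integers(0, len(config.quarters), n)
    fda_dt = _quarter_dates(rng, config.quarters, q_idx)

    sex = _sample_cat(rng, config.demographic_distributions["sex"], n)
    band = _sample_cat(rng, config.demographic_distributions["age_band"], n)
    country = _sample_cat(rng, config.demographic_distributions["country"], n)
    outcome = _sample_cat(rng, config.demographic_distributions["outcome"], n)
    age = np.full(n, "", dtype=object)
    age_cod = np.full(n, "", dtype=object)
    for b, (lo, hi) in _AGE_RANGES.items():
        mask = band == b
        age[mask] = [str(v) for v in rng.integers(lo, hi + 1, int(mask.sum()))]
        age_cod[mask] = "YR"

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt, "event_dt": fda_dt,
        "age": age, "age_cod": age_cod, "sex": sex,
        "occr_country": country, "reporter_country": country,
    })

    # drug rows: one PS mention per case plus 0-2 SS/C mentions
    n_extra = rng.integers(0, 3, n)
    extra_case = np.repeat(np.arange(n), n_extra)
    extra_drug = rng.choice(len(names), size=extra_case.size)
    extra_role = np.where(rng.random(extra_case.size) < 0.5, "SS", "C")
    drug = pd.DataFrame({
        "primaryid": np.concatenate([primaryid, primaryid[extra_case]]),
        "caseid": np.concatenate([caseid, caseid[extra_case]]),
        "drug_seq": np.concatenate([np.full(n, "1", dtype=object),
                                    np.array([str(2 + i) for i in range(extra_case.size)], dtype=object)]),
        "role_cod": np.concatenate([np.full(n, "PS", dtype=object), extra_role.astype(object)]),
        "drugname": np.concatenate([name_arr[ps_idx], name_arr[extra_drug]]),
        "prod_ai": np.concatenate([name_arr[ps_idx], name_arr[extra_drug]]),
    })

    # reactions: event cases draw one weighted event PT, everyone draws noise
    event_names = list(config.pt_weights.keys())
    w = np.asarray(list(config.pt_weights.values()), dtype=float)
    noise_names = np.array([f"NOISE PT {i + 1:03d}" for i in range(config.n_noise_pts)], dtype=object)
    ev_rows_case = np.flatnonzero(is_event)
    ev_pts = np.array(event_names, dtype=object)[rng.choice(len(event_names), ev_rows_case.size, p=w / w.sum())]
    n_noise = 1 + rng.integers(0, 2, n)
    noise_case = np.repeat(np.arange(n), n_noise)
    noise_pts = noise_names[rng.integers(0, len(noise_names), noise_case.size)]
    reac_case = np.concatenate([ev_rows_case, noise_case])
    reac = pd.DataFrame({
        "primaryid": primaryid[reac_case],
        "caseid": caseid[reac_case],
        "pt": np.concatenate([ev_pts, noise_pts]),
    })

    outc = pd.DataFrame({"primaryid": primaryid, "caseid": caseid, "outc_cod": outcome})
    ther = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "dsg_drug_seq": "1",
        "start_dt": fda_dt, "end_dt": "",
    })
    indi = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "indi_drug_seq": "1",
        "indi_pt": "Product used for unknown indication",
    })
    rpsr = pd.DataFrame({"primaryid": primaryid, "caseid": caseid, "rpsr_cod": "HP"})

    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc,
              "THER": ther, "INDI": indi, "RPSR": rpsr}

    # inject duplicate reports: same caseid, larger primaryid; alternate
    # between a later receipt date and an equal one, so both dedup branches
    # (latest fda_dt wins; date tie broken by larger primaryid) are exercised
    n_dup = int(np.floor(config.duplicate_fraction * n))
    duplicated = np.zeros(n, dtype=bool)
    if n_dup > 0:
        dup_cases = np.sort(rng.choice(n, size=n_dup, replace=False))
        duplicated[dup_cases] = True
        dup_primary = np.array([str(600_000_001 + i) for i in dup_cases], dtype=object)
        later = np.zeros(n_dup, dtype=bool)
        later[::2] = True  # half of the pairs get fda_dt + 30 days
        new_dt = fda_dt[dup_cases].copy()
        shifted = (pd.to_datetime(pd.Series(new_dt[later]), format="%Y%m%d")
                   + pd.Timedelta(days=30)).dt.strftime("%Y%m%d")
        new_dt[later] = shifted.to_numpy(dtype=object)
        id_map = dict(zip(primaryid[dup_cases], dup_primary))
        for kind, df in tables.items():
            extra = df[df["primaryid"].isin(id_map)].copy()
            extra["primaryid"] = extra["primaryid"].map(id_map)
            if kind == "DEMO":
                dt_map = dict(zip(dup_primary, new_dt))
                extra["fda_dt"] = extra["primaryid"].map(dt_map)
            tables[kind] = pd.concat([df, extra], ignore_index=True)

    manifest_cases = pd.DataFrame({
        "caseid": caseid, "primaryid": primaryid,
        "ps_drug": name_arr[ps_idx], "is_event": is_event.astype(int),
        "quarter": np.array(config.quarters, dtype=object)[q_idx],
        "duplicated": duplicated.astype(int),
    })
    manifest_drugs = pd.DataFrame({
        "name": names,
        "use_prob": probs,
        "rr": rrs,
        "atc_class": _classes,
        "is_background": [int(nm.startswith("BACKGROUND DRUG ")) for nm in names],
    })
    return SimulatedData(
        tables=tables,
        manifest_cases=manifest_cases,
        manifest_drugs=manifest_drugs,
        quarter_of_case=pd.Series(manifest_cases["quarter"].values, index=caseid),
    )


def generate_database(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write one quarterly package per configured quarter plus the manifest.

    Layout: ``<out>/<quarter>/DEMO<quarter>.txt`` (and DRUG/REAC/OUTC/THER/
    INDI/RPSR), with ``ground_truth_cases.tsv`` / ``ground_truth_drugs.tsv``
    at the top level.  Identical (config, seed) produces byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)
    cid_quarter = sim.quarter_of_case
    for q in config.quarters:
        qdir = out / q
        qdir.mkdir(exist_ok=True)
        for kind, df in sim.tables.items():
            quarter_of = df["caseid"].map(cid_quarter)
            part = df[quarter_of == q]
            fio.write_table(part, qdir / f"{kind}{q}.txt", kind)
    sim.manifest_cases.to_csv(out / "ground_truth_cases.tsv", sep="\t", index=False)
    sim.manifest_drugs.to_csv(out / "ground_truth_drugs.tsv", sep="\t", index=False)
    return out


def expected_contingency(config: SyntheticConfig, ingredient: str) -> tuple[float, float, float, float]:
    """Expected 2x2 cells (a, b, c, d) for one catalog drug under the model.

    Real-valued expectations: a = n * p_use * min(1, p0 * RR), a + b =
    n * p_use, and the event margin sums every drug's contribution
    (background pool at RR = 1).  Useful as an analytic oracle for bounding
    empirical counts.
    """
    names, probs, rrs, _ = _full_catalog(config)
    if ingredient not in names:
        raise KeyError(f"unknown ingredient {ingredient!r}")
    n = config.n_cases
    p0 = config.baseline_event_prob
    event_p = np.minimum(1.0, p0 * rrs)
    i = names.index(ingredient)
    a = n * probs[i] * event_p[i]
    b = n * probs[i] * (1.0 - event_p[i])
    total_events = float(n * np.sum(probs * event_p))
    c = total_events - a
    d = n - a - b - c
    return float(a), float(b), float(c), float(d)
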