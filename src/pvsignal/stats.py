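"""Disproportionality statistics for 2x2 drug-event contingency tables.

Spontaneous-report databases have no exposure denominator, so association is
measured by comparing how often an event is reported with a target drug
against how often it is reported with every other drug.  Three classical
screening statistics are implemented on the 2x2 table

    =============  ============  ==============
                   target event  all other AEs
    target drug         a              b
    other drugs         c              d
    =============  ============  ==============

* ROR, the reporting odds ratio ``ad/bc`` with a Woolf (log-normal) 95%
  confidence interval;
* PRR, the proportional reporting ratio ``a(c+d)/(c(a+b))`` with the
  Pearson chi-square statistic of the table;
* the BCPNN information component ``IC = log2 aN/((a+b)(a+c))`` with a
  Bayesian credible interval ``E(IC) +/- 2 sqrt(V(IC))`` whose moments are
  taken from the Dirichlet posterior of the cell probabilities.

An entity is flagged by the screening rule of each method (ROR: a>=3 and
CI lower bound > 1; PRR: a>=3, PRR>=2 and chi2>=4; BCPNN: IC025 > 0) and a
consensus ``positive`` flag is raised when any single method fires.
"""

from __future__ import annotations

import math
from collections.abc import Collection, Hashable
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "Thresholds",
    "build_table",
    "ror_with_ci",
    "prr_with_chi2",
    "ic_with_ci",
    "evaluate_criteria",
    "compute_signal",
]

#: Monte-Carlo draws used for the IC credible interval unless overridden.
DEFAULT_IC_DRAWS = 100_000
#: Seed recorded in output metadata; every IC interval is reproducible.
DEFAULT_IC_SEED = 20240101
_MIN_IC_DRAWS = 10_000


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts for one entity (drug or drug class) vs. the event.

    ``a`` target-drug reports with the event, ``b`` target-drug reports with
    other events, ``c`` other-drug reports with the event, ``d`` the rest.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if v != int(v) or v < 0:
                raise ValueError(f"cell {cell} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty contingency table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected_cells(self) -> tuple[float, float, float, float, bool]:
        """Cells used for computation: Haldane-Anscombe +0.5 if any cell is 0."""
        if self.has_zero_cell:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5, True
        return float(self.a), float(self.b), float(self.c), float(self.d), False


@dataclass(frozen=True)
class Thresholds:
    """Screening thresholds (defaults are the standard criteria)."""

    min_a: int = 3
    ror_lo: float = 1.0
    prr: float = 2.0
    chi2: float = 4.0
    ic025: float = 0.0


@dataclass
class SignalResult:
    """All statistics and screening flags for one entity."""

    entity: str
    table: ContingencyTable
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ic975: float = math.nan
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    positive: bool = False
    corrected: bool = False
    error: str | None = field(default=None)


def build_table(
    event_cases: Collection[Hashable],
    entity_cases: Collection[Hashable],
    universe: Collection[Hashable],
) -> ContingencyTable:
    """Count the 2x2 cells from case-identifier sets.

    ``universe`` is every deduplicated case in the analysis window;
    ``event_cases`` and ``entity_cases`` must be subsets of it.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    event = set(event_cases)
    entity = set(entity_cases)
    if not event <= universe or not entity <= universe:
        raise ValueError("event and entity case sets must be subsets of the universe")
    a = len(event & entity)
    b = len(entity - event)
    c = len(event - entity)
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def ror_with_ci(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio ``ad/bc`` with Woolf 95% CI.

    The CI is ``exp(ln ROR -/+ 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``.  Tables
    with a zero cell are continuity-corrected (+0.5 on every cell).
    """
    a, b, c, d, _ = t.corrected_cells()
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = math.exp(math.log(ror) - 1.96 * se)
    hi = math.exp(math.log(ror) + 1.96 * se)
    return ror, lo, hi


def prr_with_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-square of the table.

    ``PRR = a(c+d) / (c(a+b))``; ``chi2 = (ad-bc)^2 N / ((a+b)(c+d)(a+c)(b+d))``
    which is Pearson's statistic without continuity correction.  A zero margin
    on the uncorrected table is a domain error (the ratio is undefined);
    zero single cells fall back to the +0.5 correction.
    """
    for margin, name in (
        (t.a + t.b, "a+b"),
        (t.c + t.d, "c+d"),
        (t.a + t.c, "a+c"),
        (t.b + t.d, "b+d"),
    ):
        if margin == 0:
            raise ValueError(f"margin {name} is zero; PRR/chi2 undefined")
    a, b, c, d, _ = t.corrected_cells()
    n = a + b + c + d
    prr = (a * (c + d)) / (c * (a + b))
    chi2 = ((a * d - b * c) ** 2 * n) / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def ic_point(t: ContingencyTable) -> float:
    """Information component ``log2( a N / ((a+b)(a+c)) )``."""
    a, b, c, d, _ = t.corrected_cells()
    n = a + b + c + d
    return math.log2(a * n / ((a + b) * (a + c)))


def ic_with_ci(
    t: ContingencyTable,
    n_draws: int = DEFAULT_IC_DRAWS,
    seed: int = DEFAULT_IC_SEED,
) -> tuple[float, float, float]:
    """IC point estimate with a Bayesian 95% credible interval.

    The four cell probabilities get a flat Dirichlet(1,1,1,1) prior; the
    posterior after observing (a, b, c, d) is Dirichlet(a+1, b+1, c+1, d+1).
    ``E(IC)`` and ``V(IC)`` are the posterior mean and variance of
    ``log2(p11 / (p1. * p.1))``, estimated from ``n_draws`` seeded Monte-Carlo
    draws, and the interval is ``E(IC) -/+ 2 sqrt(V(IC))``.
    """
    if n_draws < _MIN_IC_DRAWS:
        raise ValueError(f"n_draws must be >= {_MIN_IC_DRAWS}, got {n_draws}")
    ic = ic_point(t)
    rng = np.random.default_rng(seed)
    alpha = np.array([t.a, t.b, t.c, t.d], dtype=float) + 1.0
    draws = rng.dirichlet(alpha, size=n_draws)
    p11 = draws[:, 0]
    p1_ = draws[:, 0] + draws[:, 1]
    p_1 = draws[:, 0] + draws[:, 2]
    ic_draws = np.log2(p11 / (p1_ * p_1))
    e_ic = float(np.mean(ic_draws))
    v_ic = float(np.var(ic_draws))
    half = 2.0 * math.sqrt(v_ic)
    return ic, e_ic - half, e_ic + half


def evaluate_criteria(r: SignalResult, thresholds: Thresholds = Thresholds()) -> SignalResult:
    """Apply the screening thresholds and the any-method consensus rule.

    The report-count condition ``a >= 3`` always uses the raw, uncorrected
    ``a``, even when statistics were computed on continuity-corrected cells.
    """
    a = r.table.a
    r.flag_ror = a >= thresholds.min_a and r.ror_lo > thresholds.ror_lo
    r.flag_prr = a >= thresholds.min_a and r.prr >= thresholds.prr and r.chi2 >= thresholds.chi2
    r.flag_bcpnn = r.ic025 > thresholds.ic025
    r.positive = r.flag_ror or r.flag_prr or r.flag_bcpnn
    return r


def compute_signal(
    entity: str,
    t: ContingencyTable,
    n_draws: int = DEFAULT_IC_DRAWS,
    seed: int = DEFAULT_IC_SEED,
    thresholds: Thresholds = Thresholds(),
) -> SignalResult:
    """Compute every statistic and flag for one entity in one call."""
    r = SignalResult(entity=entity, table=t, corrected=t.has_zero_cell)
    r.ror, r.ror_lo, r.ror_hi = ror_with_ci(t)
    r.prr, r.chi2 = prr_with_chi2(t)
    r.ic, r.ic025, r.ic975 = ic_with_ci(t, n_draws=n_draws, seed=seed)
    return evaluate_criteria(r, thresholds)
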